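"""Pooled CRISPR FACS-screen guide counting and enrichment scoring.

Reads are counted by exact 20-mer lookup: the 20-nt window at a fixed
offset of each read is hashed against the guide library, exact hits
increment that guide, everything else is discarded and tallied (no
mismatch tolerance).  Enrichment between the low-GFP and high-GFP sorted
pools is scored per guide as a log2 fold change of normalized counts,
standardized against the non-targeting-guide null, then aggregated per
gene with a size-matched random-guide-set permutation p-value and
Benjamini-Hochberg correction.  This scoring is a documented plumbing
statistic, not a MAGeCK-RRA reimplementation; the count table exports in a
MAGeCK-compatible layout for users who want the original tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GuideLibrary",
    "load_library",
    "CountColumn",
    "CountTable",
    "count_guides",
    "merge_counts",
    "normalize_counts",
    "guide_lfc",
    "gene_score",
]

NON_TARGETING = "NON_TARGETING"
GUIDE_LEN = 20
_MAD_SCALE = 1.4826  # normal-consistent MAD scaling


@dataclass
class GuideLibrary:
    """Validated sgRNA library: guide_id, gene (or NON_TARGETING), 20-nt sequence."""

    guides: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.guides
        required = {"guide_id", "gene", "sequence"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"library missing columns: {sorted(missing)}")
        df = df.copy()
        df["sequence"] = df["sequence"].str.upper()
        bad_len = df[df["sequence"].str.len() != GUIDE_LEN]
        if not bad_len.empty:
            raise ValueError(
                f"guides with sequence length != {GUIDE_LEN}: "
                f"{bad_len['guide_id'].tolist()[:5]}"
            )
        bad_alpha = df[~df["sequence"].str.fullmatch("[ACGT]+")]
        if not bad_alpha.empty:
            raise ValueError(
                f"guides with non-ACGT characters: {bad_alpha['guide_id'].tolist()[:5]}"
            )
        dups = df[df["sequence"].duplicated(keep=False)]
        if not dups.empty:
            pairs = dups.sort_values("sequence")["guide_id"].tolist()
            raise ValueError(f"duplicate guide sequences among ids: {pairs}")
        if df["guide_id"].duplicated().any():
            raise ValueError("duplicate guide ids in library")
        self.guides = df.reset_index(drop=True)
        self._lookup = dict(zip(self.guides["sequence"], self.guides["guide_id"]))

    def __len__(self) -> int:
        return len(self.guides)

    @property
    def lookup(self) -> dict[str, str]:
        """sequence -> guide_id hash used for exact-match counting."""
        return self._lookup

    @property
    def non_targeting_ids(self) -> list[str]:
        return self.guides.loc[self.guides["gene"] == NON_TARGETING, "guide_id"].tolist()


def load_library(path: str | Path) -> GuideLibrary:
    """Load a three-column TSV (guide_id, gene, sequence); lowercase accepted."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"library TSV needs 3 columns (guide_id, gene, sequence), got {df.shape[1]}")
    df = df.rename(
        columns=dict(zip(df.columns[:3], ["guide_id", "gene", "sequence"]))
    )
    return GuideLibrary(df[["guide_id", "gene", "sequence"]])


@dataclass
class CountColumn:
    """Counts for one sample, with the matched/discarded conservation tally."""

    sample: str
    counts: pd.Series  # indexed by guide_id
    matched: int
    discarded: int

    @property
    def total(self) -> int:
        return self.matched + self.discarded


def count_guides(
    fastq: str | Path,
    library: GuideLibrary,
    guide_offset: int = 0,
    offset_scan: bool = False,
    sample: str | None = None,
) -> CountColumn:
    """Count exact guide matches in one FASTQ(.gz) file.

    The 20-mer at ``guide_offset`` (and, with ``offset_scan``, at +-1 nt)
    is looked up in the library hash; reads without an exact match —
    including any single-substitution read and reads too short for the
    window — are discarded and tallied, never counted.
    """
    lookup = library.lookup
    counts: dict[str, int] = {g: 0 for g in library.guides["guide_id"]}
    matched = discarded = 0
    offsets = [guide_offset]
    if offset_scan:
        offsets += [guide_offset - 1, guide_offset + 1]
    with pysam.FastxFile(str(fastq)) as fh:
        for entry in fh:
            seq = entry.sequence.upper()
            hit = None
            for off in offsets:
                if off < 0 or off + GUIDE_LEN > len(seq):
                    continue
                hit = lookup.get(seq[off : off + GUIDE_LEN])
                if hit is not None:
                    break
            if hit is None:
                discarded += 1
            else:
                counts[hit] += 1
                matched += 1
    name = sample if sample is not None else Path(fastq).stem
    series = pd.Series(counts, name=name)
    series.index.name = "guide_id"
    return CountColumn(sample=name, counts=series, matched=matched, discarded=discarded)


@dataclass
class CountTable:
    """Guide x sample count matrix plus per-sample matched/discarded totals."""

    counts: pd.DataFrame
    totals: pd.DataFrame  # index sample, columns matched/discarded/total

    def to_mageck_tsv(self, library: GuideLibrary, path: str | Path) -> Path:
        """Export in MAGeCK layout: sgRNA, gene, then one column per sample."""
        out = self.counts.copy()
        out.insert(0, "gene", library.guides.set_index("guide_id")["gene"])
        out = out.rename_axis("sgRNA").reset_index()
        path = Path(path)
        out.to_csv(path, sep="\t", index=False)
        return path


def merge_counts(columns: Sequence[CountColumn]) -> CountTable:
    """Merge per-sample count columns into a count table."""
    counts = pd.concat([c.counts.rename(c.sample) for c in columns], axis=1)
    totals = pd.DataFrame(
        {
            "matched": [c.matched for c in columns],
            "discarded": [c.discarded for c in columns],
            "total": [c.total for c in columns],
        },
        index=[c.sample for c in columns],
    )
    return CountTable(counts=counts, totals=totals)


def normalize_counts(table: CountTable) -> pd.DataFrame:
    """Scale each sample to 1e6 matched reads (reads per million)."""
    sums = table.counts.sum(axis=0)
    zero = sums[sums == 0]
    if not zero.empty:
        raise ValueError(f"samples with zero matched reads: {zero.index.tolist()}")
    return table.counts * 1e6 / sums


def guide_lfc(
    norm: pd.DataFrame,
    low_samples: Sequence[str],
    high_samples: Sequence[str],
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-guide log2((mean low + c) / (mean high + c)) of normalized counts.

    Positive values mark guides enriched in the low-GFP pool, i.e. candidate
    positive regulators of the reporter (knockout depletes GFP).
    """
    if not low_samples or not high_samples:
        raise ValueError("need at least one sample per pool")
    low = norm[list(low_samples)].mean(axis=1)
    high = norm[list(high_samples)].mean(axis=1)
    lfc = np.log2((low + pseudocount) / (high + pseudocount))
    lfc.name = "lfc"
    return lfc


def gene_score(
    lfc: pd.Series,
    library: GuideLibrary,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Gene-level enrichment from per-guide log fold changes.

    Guide z = (lfc - median of non-targeting lfc) / scaled-MAD of
    non-targeting lfc; gene score = mean z of the gene's guides
    (non-targeting guides never aggregate into genes).  One-sided p-values
    (enrichment in the low pool) come from ``n_perm`` size-matched random
    sets drawn from all targeting guides' z values; q is Benjamini-Hochberg
    across genes.  With fewer than 10 non-targeting guides the null falls
    back to all guides (with a warning).
    """
    genes = library.guides.set_index("guide_id")["gene"]
    lfc = lfc.reindex(genes.index)
    nt_ids = library.non_targeting_ids
    null_lfc = lfc.loc[nt_ids] if len(nt_ids) >= 10 else lfc
    if len(nt_ids) < 10:
        warnings.warn(
            f"only {len(nt_ids)} non-targeting guides; falling back to all-guide null",
            stacklevel=2,
        )
    center = float(null_lfc.median())
    mad = float(np.median(np.abs(null_lfc - center))) * _MAD_SCALE
    if mad == 0:
        mad = 1.0  # degenerate null (all guides identical); z stays 0-centered
    z = (lfc - center) / mad
    z.name = "z"

    targeting = genes[genes != NON_TARGETING]
    z_t = z.loc[targeting.index].to_numpy()
    gene_groups = targeting.groupby(targeting).groups
    scores = {g: float(z.loc[idx].mean()) for g, idx in gene_groups.items()}

    rng = np.random.default_rng(seed)
    sizes = {len(idx) for idx in gene_groups.values()}
    null_means = {
        k: rng.choice(z_t, size=(n_perm, k), replace=True).mean(axis=1) for k in sizes
    }
    rows = []
    for g, idx in gene_groups.items():
        k = len(idx)
        score = scores[g]
        b = int((null_means[k] >= score).sum())
        rows.append({"gene": g, "score": score, "n_guides": k, "p": (b + 1) / (n_perm + 1)})
    table = pd.DataFrame(rows).sort_values("score", ascending=False).reset_index(drop=True)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return {"guide_z": z, "genes": table}
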