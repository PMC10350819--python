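"""Percent-spliced-in (PSI) estimation for a cassette (poison) exon.

Two estimators are provided, mirroring the two assays used to measure
poison-exon inclusion:

* :func:`gel_psi` — molar PSI from RT-PCR band intensities on an
  intercalating-dye gel, where staining is proportional to mass
  (mol x length), so each band intensity is divided by its fragment
  length before forming the inclusion fraction.
* :func:`junction_psi` — PSI from junction-spanning read counts with
  effective-length normalization, fed by
  :func:`extract_junction_counts` over spliced alignments.

Coordinates are 0-based half-open throughout; a splice junction is the
half-open gap ``(end of left exon, start of right exon)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

__all__ = [
    "GelBand",
    "GelLane",
    "SkippedExonEvent",
    "JunctionCounts",
    "PsiValue",
    "gel_psi",
    "junction_effective_length",
    "extract_junction_counts",
    "junction_psi",
    "delta_psi",
    "read_band_table",
]

INCLUSION = "inclusion"
SKIP = "skip"


@dataclass(frozen=True)
class GelBand:
    """One quantified band: a PCR product of known length and measured intensity."""

    lane_id: str
    isoform_label: str  # "inclusion" or "skip"
    isoform_name: str
    intensity: float
    length_bp: float

    def __post_init__(self) -> None:
        if self.isoform_label not in (INCLUSION, SKIP):
            raise ValueError(
                f"isoform_label must be {INCLUSION!r} or {SKIP!r}, got {self.isoform_label!r}"
            )
        if not self.intensity >= 0:
            raise ValueError(f"band intensity must be >= 0, got {self.intensity}")
        if not self.length_bp > 0:
            raise ValueError(f"band length must be > 0 bp, got {self.length_bp}")


@dataclass
class GelLane:
    """All bands of one gel lane (one sample).

    A lane may carry zero or more inclusion bands (one per PE-included
    isoform) and at most one skipped-isoform band; :func:`gel_psi`
    requires the skip band to be present.
    """

    lane_id: str
    bands: list[GelBand] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_skip = sum(1 for b in self.bands if b.isoform_label == SKIP)
        if n_skip > 1:
            raise ValueError(f"lane {self.lane_id!r} has {n_skip} skip bands; at most one allowed")

    @property
    def inclusion_bands(self) -> list[GelBand]:
        return [b for b in self.bands if b.isoform_label == INCLUSION]

    @property
    def skip_band(self) -> GelBand | None:
        for b in self.bands:
            if b.isoform_label == SKIP:
                return b
        return None


@dataclass(frozen=True)
class SkippedExonEvent:
    """A cassette-exon event: upstream exon, cassette (poison) exon, downstream exon.

    Intervals are 0-based half-open on the genomic axis and must be ordered
    and non-overlapping, with the cassette strictly between the flanks.
    """

    chrom: str
    strand: str
    upstream: tuple[int, int]
    cassette: tuple[int, int]
    downstream: tuple[int, int]
    variant: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name, (s, e) in (
            ("upstream", self.upstream),
            ("cassette", self.cassette),
            ("downstream", self.downstream),
        ):
            if not s < e:
                raise ValueError(f"{name} interval {s, e} is empty or reversed")
        if not (self.upstream[1] <= self.cassette[0] and self.cassette[1] <= self.downstream[0]):
            raise ValueError(
                "exons must be ordered upstream < cassette < downstream without overlap: "
                f"{self.upstream}, {self.cassette}, {self.downstream}"
            )

    @property
    def upstream_junction(self) -> tuple[int, int]:
        """Gap (donor end, acceptor start) of the upstream–cassette junction."""
        return (self.upstream[1], self.cassette[0])

    @property
    def downstream_junction(self) -> tuple[int, int]:
        return (self.cassette[1], self.downstream[0])

    @property
    def skip_junction(self) -> tuple[int, int]:
        return (self.upstream[1], self.downstream[0])


@dataclass
class JunctionCounts:
    """Junction-spanning read counts for one cassette-exon event."""

    i_up: int
    i_down: int
    s: int
    eff_len_inc: float
    eff_len_skip: float

    def __post_init__(self) -> None:
        for name, v in (("i_up", self.i_up), ("i_down", self.i_down), ("s", self.s)):
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if not (self.eff_len_inc > 0 and self.eff_len_skip > 0):
            raise ValueError("effective lengths must be > 0")


@dataclass
class PsiValue:
    """A PSI estimate with its provenance.

    ``psi`` is ``None`` (and ``defined`` False) when the assay carries no
    informative signal at all — an explicit flagged state, never a silent 0.
    """

    psi: float | None
    method: str
    components: dict
    defined: bool = True

    def __post_init__(self) -> None:
        if self.psi is not None and not (0.0 <= self.psi <= 1.0):
            raise ValueError(f"psi must lie in [0, 1], got {self.psi}")
        if self.psi is None:
            self.defined = False


def gel_psi(lane: GelLane) -> PsiValue:
    """Length-normalized molar PSI from gel band intensities.

    PSI = sum_i(I_inc,i / L_inc,i) / (sum_i(I_inc,i / L_inc,i) + I_skip / L_skip)

    Intensity on an intercalating-dye gel scales with mass (mol x bp), so
    dividing by fragment length converts band intensity to a molar signal;
    the formula then reduces to the molar inclusion fraction.  With one or
    two inclusion isoforms this is exactly the one- and two-band formula
    used for RT-PCR quantification of the poison exon.
    """
    skip = lane.skip_band
    if skip is None:
        raise ValueError(f"lane {lane.lane_id!r} has no skip band; gel PSI is undefined without it")
    inc = lane.inclusion_bands
    num = sum(b.intensity / b.length_bp for b in inc)
    den = num + skip.intensity / skip.length_bp
    components = {
        "inclusion_intensities": [b.intensity for b in inc],
        "inclusion_lengths": [b.length_bp for b in inc],
        "skip_intensity": skip.intensity,
        "skip_length": skip.length_bp,
    }
    if den == 0:
        return PsiValue(psi=None, method="gel", components=components, defined=False)
    return PsiValue(psi=num / den, method="gel", components=components)


def junction_effective_length(read_length: int, min_anchor: int) -> int:
    """Effective length of a single junction: read_length - 2*(min_anchor - 1)."""
    eff = read_length - 2 * (min_anchor - 1)
    if eff <= 0:
        raise ValueError(
            f"read_length {read_length} too short for min_anchor {min_anchor}"
        )
    return eff


def _gaps_with_anchors(read: pysam.AlignedSegment) -> list[tuple[int, int, int, int]]:
    """Yield (gap_start, gap_end, left_anchor, right_anchor) for each N in the CIGAR.

    Anchors are the reference-aligned lengths of the read segments flanking
    the gap (up to the next gap on either side).
    """
    out: list[tuple[int, int, int, int]] = []
    pos = read.reference_start
    # segment lengths of reference-aligned blocks between N operations
    seg_lens: list[int] = [0]
    gaps: list[tuple[int, int]] = []
    for op, length in read.cigartuples or []:
        if op == 3:  # N
            gaps.append((pos, pos + length))
            pos += length
            seg_lens.append(0)
        elif op in (0, 2, 7, 8):  # M, D, =, X consume reference
            seg_lens[-1] += length
            pos += length
        # I, S, H, P do not consume reference
    for i, (gs, ge) in enumerate(gaps):
        out.append((gs, ge, seg_lens[i], seg_lens[i + 1]))
    return out


def extract_junction_counts(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    event: SkippedExonEvent,
    min_anchor: int = 6,
    read_length: int | None = None,
    stranded: bool = False,
) -> JunctionCounts:
    """Count junction-spanning reads supporting inclusion or skipping of the cassette.

    A read supports a junction iff its alignment contains an N-gap whose
    donor/acceptor coordinates match the event's junction exactly and it
    aligns at least ``min_anchor`` nt on both sides of the gap.  Each read is
    counted at most once per junction; secondary and supplementary records
    are ignored.  With ``stranded`` the read's mapped strand must match the
    event's strand (single-end sense convention).

    ``read_length`` sets the effective-length normalization used downstream;
    when None it is taken from the first counted read.
    """
    own_handle = False
    if isinstance(alignments, (str, Path)):
        alignments = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        own_handle = True
    if isinstance(alignments, pysam.AlignmentFile):
        refs = list(alignments.references)
        if refs and event.chrom not in refs:
            if own_handle:
                alignments.close()
            raise ValueError(
                f"event reference {event.chrom!r} not among alignment references {refs}"
            )

    up_j, down_j, skip_j = event.upstream_junction, event.downstream_junction, event.skip_junction
    i_up = i_down = s = 0
    rl = read_length
    try:
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != event.chrom:
                continue
            if stranded and (("-" if read.is_reverse else "+") != event.strand):
                continue
            hit_up = hit_down = hit_skip = False
            for gs, ge, la, ra in _gaps_with_anchors(read):
                if la < min_anchor or ra < min_anchor:
                    continue
                gap = (gs, ge)
                if gap == up_j:
                    hit_up = True
                elif gap == down_j:
                    hit_down = True
                elif gap == skip_j:
                    hit_skip = True
            if hit_up or hit_down or hit_skip:
                if rl is None:
                    rl = read.query_length or read.infer_query_length()
            i_up += hit_up
            i_down += hit_down
            s += hit_skip
    finally:
        if own_handle:
            alignments.close()  # type: ignore[union-attr]

    if rl is None:
        rl = 100  # no informative read seen; nominal read length for the lengths
    ell = junction_effective_length(int(rl), min_anchor)
    return JunctionCounts(i_up=i_up, i_down=i_down, s=s, eff_len_inc=2 * ell, eff_len_skip=ell)


def junction_psi(counts: JunctionCounts) -> PsiValue:
    """Effective-length-normalized PSI from junction read counts.

    PSI = ((I_up + I_down) / eff_len_inc) / ((I_up + I_down) / eff_len_inc + S / eff_len_skip)

    With the default effective lengths (inclusion = 2 junctions, skipping =
    1 junction, each of length read_length - 2*(min_anchor - 1)) this is the
    junction-count inclusion level of a skipped-exon event.
    """
    inc = (counts.i_up + counts.i_down) / counts.eff_len_inc
    skp = counts.s / counts.eff_len_skip
    components = {
        "i_up": counts.i_up,
        "i_down": counts.i_down,
        "s": counts.s,
        "eff_len_inc": counts.eff_len_inc,
        "eff_len_skip": counts.eff_len_skip,
    }
    if inc + skp == 0:
        return PsiValue(psi=None, method="junction", components=components, defined=False)
    return PsiValue(psi=inc / (inc + skp), method="junction", components=components)


def _as_floats(values: Sequence[float | PsiValue]) -> np.ndarray:
    out = []
    for v in values:
        if isinstance(v, PsiValue):
            if not v.defined:
                raise ValueError("cannot compare undefined PSI values")
            out.append(v.psi)
        else:
            out.append(float(v))
    return np.asarray(out, dtype=float)


def delta_psi(
    group_a: Sequence[float | PsiValue],
    group_b: Sequence[float | PsiValue],
    n_perm: int = 10_000,
    seed: int = 0,
    max_exhaustive: int = 20_000,
) -> dict:
    """Group PSI difference with a two-sided label-permutation p-value.

    effect = mean(a) - mean(b).  All label assignments are enumerated when
    C(n_a + n_b, n_a) <= max_exhaustive, otherwise ``n_perm`` random
    assignments are drawn.  p = (b + 1) / (m + 1) where b counts permuted
    |effect| >= |observed effect|.  With fewer than 2 replicates in either
    group only the effect is returned and p is flagged absent (None).
    """
    a = _as_floats(group_a)
    b = _as_floats(group_b)
    effect = float(a.mean() - b.mean())
    if len(a) < 2 or len(b) < 2:
        return {"effect": effect, "p": None, "n_perm": 0, "exhaustive": False}

    pooled = np.concatenate([a, b])
    n, k = len(pooled), len(a)
    tol = 1e-12
    obs = abs(effect)
    if math.comb(n, k) <= max_exhaustive:
        stats = [
            abs(pooled[list(idx)].mean() - np.delete(pooled, list(idx)).mean())
            for idx in itertools.combinations(range(n), k)
        ]
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        stats = []
        for _ in range(n_perm):
            perm = rng.permutation(n)
            stats.append(abs(pooled[perm[:k]].mean() - pooled[perm[k:]].mean()))
        exhaustive = False
    m = len(stats)
    hits = sum(1 for t in stats if t >= obs - tol)
    return {
        "effect": effect,
        "p": (hits + 1) / (m + 1),
        "n_perm": m,
        "exhaustive": exhaustive,
    }


def read_band_table(path: str | Path) -> list[GelLane]:
    """Read a band-intensity CSV (lane_id,isoform_label,isoform_name,intensity,length_bp)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"lane_id", "isoform_label", "isoform_name", "intensity", "length_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"band table missing columns: {sorted(missing)}")
    lanes = []
    for lane_id, grp in df.groupby("lane_id", sort=False):
        bands = [
            GelBand(
                lane_id=str(lane_id),
                isoform_label=str(r.isoform_label),
                isoform_name=str(r.isoform_name),
                intensity=float(r.intensity),
                length_bp=float(r.length_bp),
            )
            for r in grp.itertuples()
        ]
        lanes.append(GelLane(lane_id=str(lane_id), bands=bands))
    return lanes
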