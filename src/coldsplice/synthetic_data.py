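"""Ground-truth-labelled synthetic inputs for every pipeline stage.

Each generator emits the standard format its downstream stage consumes
(SAM with N-gapped alignments, FASTQ, CSV tables, multi-channel images)
together with the ground truth used to draw it, so parameter recovery —
not external downloads — is the test surface.

The splicing generator models the poison-exon life cycle explicitly:
molecules include the cassette exon with probability ``psi_true`` at
synthesis, PE-included molecules then survive nonsense-mediated decay with
probability ``nmd_survival``, and junction reads are sampled from the
surviving pool position-uniformly, i.e. proportionally to each isoform's
junction effective length (two junctions for inclusion, one for skipping).
The steady-state (post-decay) inclusion fraction therefore follows the
decay algebra  psi' = p*nu / (p*nu + 1 - p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .splice_psi import INCLUSION, SKIP, GelBand, GelLane, SkippedExonEvent

__all__ = [
    "SpliceSimParams",
    "JunctionSimResult",
    "post_decay_inclusion",
    "sim_molecule_counts",
    "sim_junction_counts",
    "sim_junction_reads",
    "sim_gel",
    "sim_ct_table",
    "ScreenSimParams",
    "ScreenSimResult",
    "sim_screen_fastq",
    "CellImageSimParams",
    "CellImageSimResult",
    "sim_cell_image",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# splicing: junction reads
# ---------------------------------------------------------------------------


@dataclass
class SpliceSimParams:
    """Parameters of the cassette-exon read simulator.

    psi_true
        Probability that a molecule includes the poison exon at synthesis.
    nmd_survival
        Probability that a PE-included molecule survives NMD (1 = NMD off,
        e.g. SMG1-inhibitor conditions).
    n_reads
        Number of molecules synthesized; each surviving molecule yields one
        junction read, so emitted depth equals the surviving pool size.
    """

    psi_true: float
    n_reads: int
    nmd_survival: float = 1.0
    read_length: int = 100
    min_anchor: int = 6
    upstream_len: int = 150
    intron1_len: int = 300
    cassette_len: int = 100
    intron2_len: int = 300
    downstream_len: int = 150
    chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi_true <= 1.0:
            raise ValueError(f"psi_true must lie in [0, 1], got {self.psi_true}")
        if not 0.0 < self.nmd_survival <= 1.0:
            raise ValueError(f"nmd_survival must lie in (0, 1], got {self.nmd_survival}")
        if self.n_reads < 0 or int(self.n_reads) != self.n_reads:
            raise ValueError(f"n_reads must be a non-negative integer, got {self.n_reads}")
        if self.read_length < 2 * self.min_anchor:
            raise ValueError("read_length must allow min_anchor on both sides of a junction")

    @property
    def event(self) -> SkippedExonEvent:
        u0, u1 = 0, self.upstream_len
        c0 = u1 + self.intron1_len
        c1 = c0 + self.cassette_len
        d0 = c1 + self.intron2_len
        d1 = d0 + self.downstream_len
        return SkippedExonEvent(
            chrom=self.chrom, strand="+", upstream=(u0, u1), cassette=(c0, c1), downstream=(d0, d1)
        )

    @property
    def ref_length(self) -> int:
        return self.event.downstream[1]


def post_decay_inclusion(psi_true: float, nmd_survival: float) -> float:
    """Steady-state inclusion fraction after NMD: p*nu / (p*nu + 1 - p)."""
    num = psi_true * nmd_survival
    den = num + (1.0 - psi_true)
    return num / den if den > 0 else float("nan")


def sim_molecule_counts(
    psi_true: float, nmd_survival: float, n: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Draw (n_included_synthesized, n_included_surviving, n_skipped) molecules."""
    n_inc = int(rng.binomial(n, psi_true))
    n_surv = int(rng.binomial(n_inc, nmd_survival))
    return n_inc, n_surv, n - n_inc


def sim_junction_counts(
    params: SpliceSimParams, rng: np.random.Generator | None = None
) -> tuple[int, int, int, dict]:
    """Fast count-level simulation: (i_up, i_down, s) junction reads plus truth.

    Reads are emitted one per surviving molecule and assigned to junctions
    proportionally to effective lengths: an included molecule exposes two
    junctions, a skipped molecule one, so the probability that a read is an
    inclusion read is 2*psi' / (1 + psi') where psi' is the realized
    surviving inclusion fraction.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_inc, n_surv, n_skip = sim_molecule_counts(
        params.psi_true, params.nmd_survival, params.n_reads, rng
    )
    n_out = n_surv + n_skip
    if n_out == 0:
        truth = _truth_dict(params, n_inc, n_surv, n_skip)
        return 0, 0, 0, truth
    p_inc_read = 2.0 * n_surv / (2.0 * n_surv + n_skip)
    n_inc_reads = int(rng.binomial(n_out, p_inc_read))
    i_up = int(rng.binomial(n_inc_reads, 0.5))
    i_down = n_inc_reads - i_up
    s = n_out - n_inc_reads
    return i_up, i_down, s, _truth_dict(params, n_inc, n_surv, n_skip)


def _truth_dict(params: SpliceSimParams, n_inc: int, n_surv: int, n_skip: int) -> dict:
    n_out = n_surv + n_skip
    return {
        "psi_true": params.psi_true,
        "nmd_survival": params.nmd_survival,
        "n_molecules": params.n_reads,
        "n_included_synthesized": n_inc,
        "n_included_surviving": n_surv,
        "n_skipped": n_skip,
        "psi_post_decay": (n_surv / n_out) if n_out else float("nan"),
        "psi_post_decay_expected": post_decay_inclusion(params.psi_true, params.nmd_survival),
    }


@dataclass
class JunctionSimResult:
    """Simulated spliced alignments plus per-read and summary ground truth."""

    header: pysam.AlignmentHeader
    records: list[pysam.AlignedSegment]
    event: SkippedExonEvent
    reference: str
    truth_reads: pd.DataFrame
    truth: dict
    sam_path: Path | None = None

    def write_sam(self, path: str | Path) -> Path:
        path = Path(path)
        with pysam.AlignmentFile(str(path), "w", header=self.header) as fh:
            for rec in self.records:
                fh.write(rec)
        self.sam_path = path
        return path


def sim_junction_reads(
    params: SpliceSimParams, out_sam: str | Path | None = None
) -> JunctionSimResult:
    """Simulate junction-spanning reads of a cassette-exon event as SAM records.

    Every emitted read spans exactly one junction with at least
    ``params.min_anchor`` aligned nucleotides on both sides, encoded as an
    M-N-M CIGAR; the ground-truth junction of each read is returned in
    ``truth_reads``.
    """
    rng = np.random.default_rng(params.seed)
    ref = "".join(rng.choice(_BASES, size=params.ref_length))
    event = params.event
    i_up, i_down, s, truth = sim_junction_counts(params, rng)

    junctions = {
        "upstream_inclusion": event.upstream_junction,
        "downstream_inclusion": event.downstream_junction,
        "skip": event.skip_junction,
    }
    labels = (
        ["upstream_inclusion"] * i_up + ["downstream_inclusion"] * i_down + ["skip"] * s
    )
    order = rng.permutation(len(labels))

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": params.chrom, "LN": params.ref_length}],
        }
    )
    rl, anc = params.read_length, params.min_anchor
    records: list[pysam.AlignedSegment] = []
    rows = []
    qual = pysam.qualitystring_to_array("?" * rl)  # constant Q30 placeholder
    for i, idx in enumerate(order):
        label = labels[idx]
        gap_start, gap_end = junctions[label]
        left = int(rng.integers(anc, rl - anc + 1))  # aligned nt left of the gap
        right = rl - left
        start = gap_start - left
        seq = ref[start:gap_start] + ref[gap_end : gap_end + right]
        a = pysam.AlignedSegment(header)
        a.query_name = f"simread_{i}"
        a.query_sequence = seq
        a.flag = 0
        a.reference_id = 0
        a.reference_start = start
        a.mapping_quality = 60
        a.cigartuples = [(0, left), (3, gap_end - gap_start), (0, right)]
        a.query_qualities = qual
        records.append(a)
        rows.append({"read_name": a.query_name, "junction": label, "start": start})

    truth_reads = pd.DataFrame(rows, columns=["read_name", "junction", "start"])
    result = JunctionSimResult(
        header=header,
        records=records,
        event=event,
        reference=ref,
        truth_reads=truth_reads,
        truth=truth,
    )
    if out_sam is not None:
        result.write_sam(out_sam)
    return result


# ---------------------------------------------------------------------------
# gels
# ---------------------------------------------------------------------------


def sim_gel(
    molar_amounts: Mapping[str, float],
    lengths: Mapping[str, float],
    skip_isoform: str,
    noise_sd: float = 0.0,
    gain: float = 1.0,
    seed: int = 0,
    lane_id: str = "lane1",
) -> GelLane:
    """Simulate one gel lane under the intercalating-dye (mass) staining model.

    Band intensity = molar_amount x length x gain + Gaussian noise, truncated
    at 0.  Because staining is mass-proportional, dividing band intensity by
    fragment length (as :func:`coldsplice.splice_psi.gel_psi` does) recovers
    the molar fraction exactly in the noiseless case.
    """
    if set(molar_amounts) != set(lengths):
        raise ValueError("molar_amounts and lengths must cover the same isoforms")
    for name, amt in molar_amounts.items():
        if amt < 0:
            raise ValueError(f"molar amount of {name!r} must be >= 0, got {amt}")
    for name, ln in lengths.items():
        if ln <= 0:
            raise ValueError(f"length of {name!r} must be > 0, got {ln}")
    rng = np.random.default_rng(seed)
    bands = []
    for name in molar_amounts:
        intensity = molar_amounts[name] * lengths[name] * gain
        if noise_sd > 0:
            intensity += rng.normal(0.0, noise_sd)
        bands.append(
            GelBand(
                lane_id=lane_id,
                isoform_label=SKIP if name == skip_isoform else INCLUSION,
                isoform_name=name,
                intensity=max(0.0, float(intensity)),
                length_bp=float(lengths[name]),
            )
        )
    return GelLane(lane_id=lane_id, bands=bands)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def sim_ct_table(
    true_rel_expr: pd.DataFrame,
    ct_ref: float = 15.0,
    noise_sd: float = 0.0,
    n_technical: int = 4,
    reference_amplicon: str = "18S",
    efficiency: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table from true relative expression levels.

    ``true_rel_expr`` needs columns sample_id, condition, amplicon,
    expression (relative to the reference amplicon, > 0).  Per technical
    replicate, Ct = ct_ref - log_eff(expression) + noise; the reference
    amplicon is added automatically with expression 1 in every sample.
    """
    required = {"sample_id", "condition", "amplicon", "expression"}
    missing = required - set(true_rel_expr.columns)
    if missing:
        raise ValueError(f"true_rel_expr missing columns: {sorted(missing)}")
    if (true_rel_expr["expression"] <= 0).any():
        bad = true_rel_expr.loc[true_rel_expr["expression"] <= 0]
        raise ValueError(f"expressions must be > 0; offending rows:\n{bad}")
    rng = np.random.default_rng(seed)
    log_eff = math.log(efficiency)
    rows = []
    samples = true_rel_expr[["sample_id", "condition"]].drop_duplicates()
    ref_rows = samples.assign(amplicon=reference_amplicon, expression=1.0)
    full = pd.concat([true_rel_expr, ref_rows], ignore_index=True)
    for r in full.itertuples():
        base_ct = ct_ref - math.log(r.expression) / log_eff
        for rep in range(1, n_technical + 1):
            ct = base_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {
                    "sample_id": r.sample_id,
                    "condition": r.condition,
                    "amplicon": r.amplicon,
                    "replicate": rep,
                    "ct": ct,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CRISPR screen FASTQ
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimParams:
    """Parameters of the sorted-pool screen read simulator.

    Guide counts are negative-binomial around library-proportional means
    (``dispersion`` is the NB alpha: variance = mu + alpha*mu^2; 0 gives
    Poisson).  ``enriched_guides`` maps guide ids to effect multipliers
    applied to their mean in ``enriched_sample`` — emulating guides enriched
    in the low-GFP sorted pool.  Reads are single-end of ``read_length`` nt
    with the exact 20-nt guide at ``guide_offset``; ``mutation_fraction`` of
    reads get one random substitution inside the guide 20-mer to exercise
    the exact-match discard rule.
    """

    library: "object"  # GuideLibrary; duck-typed to avoid a circular import
    n_reads: int
    samples: tuple[str, ...] = ("low", "high")
    enriched_sample: str = "low"
    enriched_guides: Mapping[str, float] = field(default_factory=dict)
    dispersion: float = 0.1
    guide_offset: int = 0
    read_length: int = 21
    mutation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        ids = set(self.library.guides["guide_id"])
        unknown = set(self.enriched_guides) - ids
        if unknown:
            raise ValueError(f"enriched_guides not in library: {sorted(unknown)[:5]}")
        if any(m <= 0 for m in self.enriched_guides.values()):
            raise ValueError("effect multipliers must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.guide_offset + 20 > self.read_length:
            raise ValueError(
                f"guide_offset {self.guide_offset} + 20 exceeds read length {self.read_length}"
            )
        if not 0.0 <= self.mutation_fraction <= 1.0:
            raise ValueError("mutation_fraction must lie in [0, 1]")


@dataclass
class ScreenSimResult:
    fastq_paths: dict[str, Path]
    truth_counts: pd.DataFrame  # guide_id x sample drawn counts (pre-mutation)
    truth_mutated: pd.DataFrame  # guide_id x sample counts of reads carrying a substitution


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mu * alpha)
    return rng.poisson(lam)


def sim_screen_fastq(params: ScreenSimParams, outdir: str | Path) -> ScreenSimResult:
    """Simulate per-sample screen FASTQ files with ground-truth guide counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    lib = params.library.guides
    n_guides = len(lib)
    base_mu = np.full(n_guides, params.n_reads / n_guides)
    idx_of = {g: i for i, g in enumerate(lib["guide_id"])}

    qline = "?" * params.read_length  # constant Q30 placeholder (Sanger encoding)
    prefix = "T" * params.guide_offset
    suffix_len = params.read_length - params.guide_offset - 20

    counts = {}
    mutated = {}
    paths = {}
    for sample in params.samples:
        mu = base_mu.copy()
        if sample == params.enriched_sample:
            for gid, eff in params.enriched_guides.items():
                mu[idx_of[gid]] *= eff
        drawn = _nb_draw(rng, mu, params.dispersion).astype(int)
        n_mut = (
            rng.binomial(drawn, params.mutation_fraction)
            if params.mutation_fraction > 0
            else np.zeros(n_guides, dtype=int)
        )
        counts[sample] = drawn
        mutated[sample] = n_mut
        path = outdir / f"{sample}.fastq"
        with open(path, "w") as fh:
            read_i = 0
            for gi, (gid, seq) in enumerate(zip(lib["guide_id"], lib["sequence"])):
                for j in range(drawn[gi]):
                    g = seq
                    if j < n_mut[gi]:
                        pos = int(rng.integers(0, 20))
                        alts = [b for b in "ACGT" if b != g[pos]]
                        g = g[:pos] + alts[int(rng.integers(0, 3))] + g[pos + 1 :]
                    read = prefix + g + ("A" * suffix_len)
                    fh.write(f"@{sample}_read{read_i}_{gid}\n{read}\n+\n{qline}\n")
                    read_i += 1
        paths[sample] = path

    truth_counts = pd.DataFrame(counts, index=lib["guide_id"].to_numpy())
    truth_counts.index.name = "guide_id"
    truth_mut = pd.DataFrame(mutated, index=lib["guide_id"].to_numpy())
    truth_mut.index.name = "guide_id"
    return ScreenSimResult(fastq_paths=paths, truth_counts=truth_counts, truth_mutated=truth_mut)


# ---------------------------------------------------------------------------
# cell images
# ---------------------------------------------------------------------------


@dataclass
class CellImageSimParams:
    """Parameters of the single-cell image simulator.

    One soma disk with a nucleus disk strictly inside it; per channel, each
    compartment has a true mean intensity, on top of a background level with
    an optional linear gradient, plus Gaussian noise.  ``channel_means``
    maps channel name -> {"nucleus": mean, "cytoplasm": mean}; a channel
    missing a compartment contributes 0 there (e.g. a nuclear stain with no
    cytoplasmic signal).
    """

    shape: tuple[int, int] = (96, 96)
    soma_center: tuple[float, float] = (48.0, 48.0)
    soma_radius: float = 34.0
    nucleus_center: tuple[float, float] = (48.0, 48.0)
    nucleus_radius: float = 16.0
    channel_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "nuclear_stain": {"nucleus": 150.0, "cytoplasm": 0.0},
            "reporter": {"nucleus": 200.0, "cytoplasm": 100.0},
        }
    )
    background: float = 10.0
    gradient: tuple[float, float] = (0.0, 0.0)  # max added along rows / cols
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        dy = self.nucleus_center[0] - self.soma_center[0]
        dx = self.nucleus_center[1] - self.soma_center[1]
        if math.hypot(dy, dx) + self.nucleus_radius >= self.soma_radius:
            raise ValueError("nucleus disk must lie strictly inside the soma disk")
        for ch, comp in self.channel_means.items():
            for name, v in comp.items():
                if v < 0:
                    raise ValueError(f"intensity of {ch}/{name} must be >= 0, got {v}")
        if self.background < 0 or self.noise_sd < 0:
            raise ValueError("background and noise_sd must be >= 0")


@dataclass
class CellImageSimResult:
    channels: dict[str, np.ndarray]
    nucleus_mask: np.ndarray
    soma_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    params: CellImageSimParams

    def write_tiff(self, path: str | Path) -> Path:
        """Write channels as a multi-page TIFF (one page per channel, sorted names)."""
        import tifffile

        path = Path(path)
        names = sorted(self.channels)
        stack = np.stack([self.channels[n] for n in names]).astype(np.float32)
        tifffile.imwrite(str(path), stack, metadata={"channels": names})
        return path


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def sim_cell_image(params: CellImageSimParams) -> CellImageSimResult:
    """Render a single-cell multi-channel image plus ground-truth masks.

    Pass an empty ``channel_means`` entry ({}) or zero means to render a
    background-only channel (degenerate no-cell input).
    """
    rng = np.random.default_rng(params.seed)
    soma = _disk_mask(params.shape, params.soma_center, params.soma_radius)
    nucleus = _disk_mask(params.shape, params.nucleus_center, params.nucleus_radius)
    cytoplasm = soma & ~nucleus
    h, w = params.shape
    yy, xx = np.mgrid[0:h, 0:w]
    bg = (
        params.background
        + params.gradient[0] * yy / max(h - 1, 1)
        + params.gradient[1] * xx / max(w - 1, 1)
    )
    channels = {}
    for ch, means in params.channel_means.items():
        img = bg.copy().astype(float)
        img[cytoplasm] += means.get("cytoplasm", 0.0)
        img[nucleus] += means.get("nucleus", 0.0)
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, size=img.shape)
        channels[ch] = np.clip(img, 0.0, None)
    return CellImageSimResult(
        channels=channels,
        nucleus_mask=nucleus,
        soma_mask=soma,
        cytoplasm_mask=cytoplasm,
        params=params,
    )
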