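"""Run configuration, stage dispatch, manifests, and the end-to-end demo.

``run_pipeline`` executes one named stage from a validated
:class:`RunConfig` and writes a manifest (package and library versions,
parameters, seed, input checksums, outputs) alongside the stage outputs,
so every output directory is reproducible byte-for-byte from config +
seed.  ``demo_cold_induction`` is the synthetic end-to-end analogue of the
cold-repression experiment: paired 37°C/32°C junction data, gels and Ct
tables are simulated from one shared ground truth and all three PSI
estimators are run on them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clip_g4, imagequant, qpcr_rip, screen_counts, splice_psi
from . import synthetic_data as sd

__all__ = ["RunConfig", "run_pipeline", "demo_cold_induction", "STAGES"]

logger = logging.getLogger("coldsplice")

_CONFIG_KEYS = {"stage", "inputs", "params", "seed", "outdir"}


@dataclass
class RunConfig:
    """One pipeline run: a stage, its inputs, parameter overrides, seed, outdir."""

    stage: str
    outdir: str | Path
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; known: {sorted(STAGES)}")
        for path in self.inputs.values():
            if not Path(path).exists():
                raise FileNotFoundError(f"input does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _event_from_params(params: dict) -> splice_psi.SkippedExonEvent:
    ev = params["event"]
    return splice_psi.SkippedExonEvent(
        chrom=ev["chrom"], strand=ev.get("strand", "+"),
        upstream=tuple(ev["upstream"]), cassette=tuple(ev["cassette"]),
        downstream=tuple(ev["downstream"]), variant=ev.get("variant", ""),
    )


# --- stage runners ---------------------------------------------------------


def _stage_simulate_splice(cfg: RunConfig, out: Path) -> dict:
    params = sd.SpliceSimParams(seed=cfg.seed, **cfg.params)
    res = sd.sim_junction_reads(params, out_sam=out / "reads.sam")
    res.truth_reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(res.truth, indent=1))
    return {"outputs": ["reads.sam", "truth_reads.tsv", "truth.json"],
            "records_written": len(res.records)}


def _stage_simulate_gel(cfg: RunConfig, out: Path) -> dict:
    lane = sd.sim_gel(seed=cfg.seed, **cfg.params)
    rows = [
        {"lane_id": b.lane_id, "isoform_label": b.isoform_label,
         "isoform_name": b.isoform_name, "intensity": b.intensity, "length_bp": b.length_bp}
        for b in lane.bands
    ]
    pd.DataFrame(rows).to_csv(out / "bands.csv", index=False)
    return {"outputs": ["bands.csv"], "records_written": len(rows)}


def _stage_simulate_ct(cfg: RunConfig, out: Path) -> dict:
    params = dict(cfg.params)
    expr = pd.DataFrame(params.pop("true_rel_expr"))
    table = sd.sim_ct_table(expr, seed=cfg.seed, **params)
    table.to_csv(out / "ct.csv", index=False)
    return {"outputs": ["ct.csv"], "records_written": len(table)}


def _stage_simulate_screen(cfg: RunConfig, out: Path) -> dict:
    library = screen_counts.load_library(cfg.inputs["library"])
    params = sd.ScreenSimParams(library=library, seed=cfg.seed, **cfg.params)
    res = sd.sim_screen_fastq(params, out)
    res.truth_counts.to_csv(out / "truth_counts.tsv", sep="\t")
    return {"outputs": [p.name for p in res.fastq_paths.values()] + ["truth_counts.tsv"],
            "records_written": int(res.truth_counts.to_numpy().sum())}


def _stage_simulate_image(cfg: RunConfig, out: Path) -> dict:
    params = sd.CellImageSimParams(seed=cfg.seed, **cfg.params)
    res = sd.sim_cell_image(params)
    res.write_tiff(out / "cell.tif")
    np.savez(out / "truth_masks.npz", nucleus=res.nucleus_mask,
             soma=res.soma_mask, cytoplasm=res.cytoplasm_mask)
    return {"outputs": ["cell.tif", "truth_masks.npz"]}


def _stage_gel_psi(cfg: RunConfig, out: Path) -> dict:
    lanes = splice_psi.read_band_table(cfg.inputs["bands"])
    rows = []
    for lane in lanes:
        psi = splice_psi.gel_psi(lane)
        rows.append({"lane_id": lane.lane_id, "psi": psi.psi, "defined": psi.defined})
    pd.DataFrame(rows).to_csv(out / "gel_psi.csv", index=False)
    return {"outputs": ["gel_psi.csv"], "records_read": len(lanes)}


def _stage_junction_psi(cfg: RunConfig, out: Path) -> dict:
    event = _event_from_params(cfg.params)
    counts = splice_psi.extract_junction_counts(
        cfg.inputs["alignments"], event,
        min_anchor=cfg.params.get("min_anchor", 6),
        stranded=cfg.params.get("stranded", False),
    )
    psi = splice_psi.junction_psi(counts)
    (out / "junction_psi.json").write_text(
        json.dumps({"psi": psi.psi, "defined": psi.defined, **psi.components}, indent=1)
    )
    return {"outputs": ["junction_psi.json"],
            "records_read": counts.i_up + counts.i_down + counts.s}


def _stage_qpcr(cfg: RunConfig, out: Path) -> dict:
    ct = qpcr_rip.read_ct_csv(cfg.inputs["ct"])
    expr = qpcr_rip.relative_expression(
        ct, reference_amplicon=cfg.params.get("reference_amplicon", "18S"),
        efficiency=cfg.params.get("efficiency", 2.0),
    )
    expr.to_csv(out / "relative_expression.csv", index=False)
    outputs = ["relative_expression.csv"]
    if "pe_amplicon" in cfg.params:
        ratios = qpcr_rip.pe_inclusion_ratio(
            expr, pe_amplicon=cfg.params["pe_amplicon"],
            constitutive_amplicons=cfg.params["constitutive_amplicons"],
            mode=cfg.params.get("mode", "geometric_mean"),
        )
        ratios.to_csv(out / "pe_inclusion.csv", index=False)
        outputs.append("pe_inclusion.csv")
    return {"outputs": outputs, "records_read": len(ct)}


def _stage_rip(cfg: RunConfig, out: Path) -> dict:
    table = pd.read_csv(cfg.inputs["rip"])
    fc = qpcr_rip.rip_fold_changes(table)
    fc.to_csv(out / "rip_fold_change.csv", index=False)
    return {"outputs": ["rip_fold_change.csv"], "records_read": len(table)}


def _stage_screen_count(cfg: RunConfig, out: Path) -> dict:
    library = screen_counts.load_library(cfg.inputs["library"])
    fastqs = {k: v for k, v in cfg.inputs.items() if k != "library"}
    cols = [
        screen_counts.count_guides(
            path, library, guide_offset=cfg.params.get("guide_offset", 0),
            offset_scan=cfg.params.get("offset_scan", False), sample=name,
        )
        for name, path in fastqs.items()
    ]
    table = screen_counts.merge_counts(cols)
    table.to_mageck_tsv(library, out / "counts.tsv")
    table.totals.rename_axis("sample").to_csv(out / "totals.csv")
    return {"outputs": ["counts.tsv", "totals.csv"],
            "records_read": int(table.totals["total"].sum()),
            "records_discarded": int(table.totals["discarded"].sum())}


def _stage_screen_score(cfg: RunConfig, out: Path) -> dict:
    library = screen_counts.load_library(cfg.inputs["library"])
    raw = pd.read_csv(cfg.inputs["counts"], sep="\t").set_index("sgRNA")
    counts = raw.drop(columns=["gene"])
    low = cfg.params["low_samples"]
    high = cfg.params["high_samples"]
    table = screen_counts.CountTable(
        counts=counts,
        totals=pd.DataFrame({"matched": counts.sum(), "discarded": 0,
                             "total": counts.sum()}),
    )
    norm = screen_counts.normalize_counts(table)
    lfc = screen_counts.guide_lfc(norm, low, high,
                                  pseudocount=cfg.params.get("pseudocount", 0.5))
    res = screen_counts.gene_score(lfc, library,
                                   n_perm=cfg.params.get("n_perm", 10_000), seed=cfg.seed)
    res["genes"].to_csv(out / "gene_scores.csv", index=False)
    res["guide_z"].rename_axis("guide_id").to_csv(out / "guide_z.csv")
    return {"outputs": ["gene_scores.csv", "guide_z.csv"], "records_read": len(counts)}


def _stage_imagequant(cfg: RunConfig, out: Path) -> dict:
    names = cfg.params.get("channels", ["nuclear_stain", "reporter"])
    rows = []
    for cell_id, path in cfg.inputs.items():
        img = imagequant.read_tiff(path, channel_names=sorted(names))
        masks = imagequant.segment_cell(
            img, nucleus_source=cfg.params.get("nucleus_source", "nuclear_stain"),
            soma_source=cfg.params.get("soma_source", "reporter"),
        )
        for ch in img.channels:
            corrected = imagequant.remove_background(img[ch]).corrected
            meas = imagequant.measure_compartments(corrected, masks, name=ch)
            for comp in imagequant.COMPARTMENTS:
                rows.append({"cell_id": cell_id, "channel": ch, "compartment": comp,
                             "mean_intensity": meas.means[comp], "area_px": meas.areas[comp]})
    pd.DataFrame(rows).to_csv(out / "compartments.csv", index=False)
    return {"outputs": ["compartments.csv"], "records_read": len(cfg.inputs)}


def _stage_clip(cfg: RunConfig, out: Path) -> dict:
    p = cfg.params
    track = clip_g4.read_bedgraph(
        cfg.inputs["bedgraph"], chrom=p["chrom"], start=p["start"], end=p["end"],
        strand=p.get("strand", "+"), library_size=p["library_size"],
    )
    cpm = clip_g4.normalize_track(track)
    smoothed = clip_g4.smooth_track(cpm, window=p.get("window", 5))
    clip_g4.write_bedgraph(track, out / "normalized.bedgraph", values=cpm)
    clip_g4.write_bedgraph(track, out / "smoothed.bedgraph", values=smoothed)
    return {"outputs": ["normalized.bedgraph", "smoothed.bedgraph"],
            "records_read": int((track.counts != 0).sum())}


def _stage_g4scan(cfg: RunConfig, out: Path) -> dict:
    from Bio import SeqIO

    frames = []
    for rec in SeqIO.parse(cfg.inputs["fasta"], "fasta"):
        motifs = clip_g4.scan_g4(
            str(rec.seq), min_tract=cfg.params.get("min_tract", 2),
            max_len=cfg.params.get("max_len", 30), max_loop=cfg.params.get("max_loop", 36),
        )
        frame = clip_g4.motifs_to_frame(motifs)
        frame.insert(0, "sequence_id", rec.id)
        frames.append(frame)
    result = pd.concat(frames, ignore_index=True) if frames else clip_g4.motifs_to_frame([])
    with open(out / "g4_motifs.tsv", "w") as fh:
        fh.write("# QGRS-style scoring variant: 100*tract_length - 2*loop_spread - total_loop\n")
        result.to_csv(fh, sep="\t", index=False)
    return {"outputs": ["g4_motifs.tsv"], "records_written": len(result)}


def _stage_demo(cfg: RunConfig, out: Path) -> dict:
    report = demo_cold_induction(seed=cfg.seed, **cfg.params)
    report["replicates"].to_csv(out / "demo_replicates.csv", index=False)
    payload = {k: v for k, v in report.items() if k != "replicates"}
    (out / "demo_report.json").write_text(json.dumps(payload, indent=1))
    return {"outputs": ["demo_replicates.csv", "demo_report.json"]}


STAGES = {
    "simulate-splice": _stage_simulate_splice,
    "simulate-gel": _stage_simulate_gel,
    "simulate-ct": _stage_simulate_ct,
    "simulate-screen": _stage_simulate_screen,
    "simulate-image": _stage_simulate_image,
    "gel-psi": _stage_gel_psi,
    "junction-psi": _stage_junction_psi,
    "qpcr": _stage_qpcr,
    "rip": _stage_rip,
    "screen-count": _stage_screen_count,
    "screen-score": _stage_screen_score,
    "imagequant": _stage_imagequant,
    "clip": _stage_clip,
    "g4scan": _stage_g4scan,
    "demo": _stage_demo,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute one stage and write its manifest; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage=%s seed=%d outdir=%s", config.stage, config.seed, out)
    result = STAGES[config.stage](config, out)
    manifest = {
        "stage": config.stage,
        "coldsplice_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "params": config.params,
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in config.inputs.items()},
        **result,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("stage=%s done: %s", config.stage, result)
    return manifest


# --- end-to-end demo -------------------------------------------------------

# Steady-state PSI regimes of the cassette exon at each temperature: the
# long (3a-L) and short (3a-S) splice-site variants, warm vs cooled.
DEMO_PSI = {
    "3a-L": {"37C": 0.023, "32C": 0.002},
    "3a-S": {"37C": 0.015, "32C": 0.001},
}
_GEL_LEN_INC = 401.0  # bp of the PE-included RT-PCR product
_GEL_LEN_SKIP = 301.0


def demo_cold_induction(
    seed: int = 0,
    depth: int = 100_000,
    n_replicates: int = 4,
    variant: str = "3a-L",
    nmd_survival_off: float = 0.3,
) -> dict:
    """Synthetic cold-repression experiment with three concordant PSI assays.

    Per replicate and temperature, one shared pool of molecules is drawn at
    the steady-state inclusion level (printed PSI values are post-NMD, so
    the pool is drawn at that level directly); junction reads, a gel lane
    and a Ct table are then derived from the same pool and each assay's PSI
    estimator is applied.  A separate arm contrasts NMD on
    (survival = ``nmd_survival_off``) with NMD off (survival 1) at a fixed
    synthesis-level inclusion, mirroring the SMG1-inhibitor comparison:
    blocking decay raises the apparent PE fraction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for condition, psi_true in DEMO_PSI[variant].items():
        for rep in range(1, n_replicates + 1):
            n_inc, n_surv, n_skip = sd.sim_molecule_counts(psi_true, 1.0, depth, rng)
            # junction reads from the surviving pool
            n_out = n_surv + n_skip
            p_inc = 2.0 * n_surv / (2.0 * n_surv + n_skip)
            n_inc_reads = int(rng.binomial(n_out, p_inc))
            i_up = int(rng.binomial(n_inc_reads, 0.5))
            ell = splice_psi.junction_effective_length(100, 6)
            counts = splice_psi.JunctionCounts(
                i_up=i_up, i_down=n_inc_reads - i_up, s=n_out - n_inc_reads,
                eff_len_inc=2 * ell, eff_len_skip=ell,
            )
            psi_junction = splice_psi.junction_psi(counts).psi
            # gel lane: band intensity = molecules x product length (+ noise)
            lane = sd.sim_gel(
                molar_amounts={"PE-included": n_surv, "PE-skipped": n_skip},
                lengths={"PE-included": _GEL_LEN_INC, "PE-skipped": _GEL_LEN_SKIP},
                skip_isoform="PE-skipped", noise_sd=50.0,
                seed=int(rng.integers(2**31)), lane_id=f"{condition}_rep{rep}",
            )
            psi_gel = splice_psi.gel_psi(lane).psi
            # qPCR: PE amplicon sees included molecules, constitutive amplicons all
            psi_pool = n_surv / n_out
            expr = pd.DataFrame(
                [
                    {"sample_id": f"{condition}_rep{rep}", "condition": condition,
                     "amplicon": "RBM3_Exon3a", "expression": max(psi_pool, 1e-9)},
                    {"sample_id": f"{condition}_rep{rep}", "condition": condition,
                     "amplicon": "RBM3_Exon3", "expression": 1.0},
                    {"sample_id": f"{condition}_rep{rep}", "condition": condition,
                     "amplicon": "RBM3_Exon4_5", "expression": 1.0},
                ]
            )
            ct = sd.sim_ct_table(expr, noise_sd=0.05, n_technical=4,
                                 seed=int(rng.integers(2**31)))
            rel = qpcr_rip.relative_expression(ct, reference_amplicon="18S")
            ratio = qpcr_rip.pe_inclusion_ratio(
                rel, pe_amplicon="RBM3_Exon3a",
                constitutive_amplicons=["RBM3_Exon3", "RBM3_Exon4_5"],
                mode="geometric_mean",
            )
            psi_qpcr = float(ratio["value"].iloc[0])
            rows.append({
                "condition": condition, "replicate": rep, "psi_true": psi_true,
                "psi_pool": psi_pool, "psi_junction": psi_junction,
                "psi_gel": psi_gel, "psi_qpcr": psi_qpcr,
            })
    replicates = pd.DataFrame(rows)

    warm = replicates.loc[replicates["condition"] == "37C", "psi_junction"].tolist()
    cold = replicates.loc[replicates["condition"] == "32C", "psi_junction"].tolist()
    delta = splice_psi.delta_psi(cold, warm, seed=seed)

    # NMD arm: same synthesis-level inclusion, decay on vs off
    psi_synth = 0.05
    nmd = {}
    for label, nu in (("nmd_on", nmd_survival_off), ("nmd_off", 1.0)):
        params = sd.SpliceSimParams(
            psi_true=psi_synth, n_reads=depth, nmd_survival=nu,
            seed=int(rng.integers(2**31)),
        )
        i_up, i_down, s, truth = sd.sim_junction_counts(params)
        ell = splice_psi.junction_effective_length(params.read_length, params.min_anchor)
        psi_est = splice_psi.junction_psi(
            splice_psi.JunctionCounts(i_up=i_up, i_down=i_down, s=s,
                                      eff_len_inc=2 * ell, eff_len_skip=ell)
        ).psi
        nmd[label] = {
            "nmd_survival": nu, "psi_synthesis": psi_synth, "psi_estimated": psi_est,
            "psi_expected": sd.post_decay_inclusion(psi_synth, nu),
        }

    return {
        "variant": variant,
        "depth": depth,
        "replicates": replicates,
        "cooling_effect": delta,
        "cooling_represses_pe": bool(delta["effect"] < 0),
        "nmd_arm": nmd,
        "nmd_block_raises_inclusion": bool(
            nmd["nmd_off"]["psi_estimated"] > nmd["nmd_on"]["psi_estimated"]
        ),
    }
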