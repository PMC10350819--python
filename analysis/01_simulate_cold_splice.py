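#!/usr/bin/env python
"""Simulate the paired warm/cold splicing experiment that the later drivers analyse.

One shared ground-truth molecule pool per replicate and temperature drives
three parallel assay simulations — junction-spanning reads (SAM), a gel
lane (band CSV) and a qPCR Ct table (CSV) — at the steady-state poison-exon
inclusion levels of the warm (PSI 0.023) and cooled (PSI 0.002) states.
Outputs go to results/simulated/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from coldsplice import synthetic_data as sd

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
PSI = {"37C": 0.023, "32C": 0.002}
DEPTH = 100_000
REPLICATES = 4


def main(seed: int) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    band_rows, truth_rows, expr_rows = [], [], []
    for cond, psi in PSI.items():
        for rep in range(1, REPLICATES + 1):
            run_seed = seed * 10_000 + hash(cond) % 97 + rep
            params = sd.SpliceSimParams(psi_true=psi, n_reads=DEPTH, seed=run_seed % 2**31)
            res = sd.sim_junction_reads(params, out_sam=OUT / f"{cond}_rep{rep}.sam")
            truth = res.truth
            n_surv, n_skip = truth["n_included_surviving"], truth["n_skipped"]
            lane = sd.sim_gel(
                {"PE-included": n_surv, "PE-skipped": n_skip},
                {"PE-included": 401.0, "PE-skipped": 301.0},
                "PE-skipped", noise_sd=50.0, seed=run_seed % 2**31,
                lane_id=f"{cond}_rep{rep}",
            )
            band_rows += [
                {"lane_id": b.lane_id, "isoform_label": b.isoform_label,
                 "isoform_name": b.isoform_name, "intensity": b.intensity,
                 "length_bp": b.length_bp}
                for b in lane.bands
            ]
            expr_rows += [
                {"sample_id": f"{cond}_rep{rep}", "condition": cond,
                 "amplicon": "RBM3_Exon3a", "expression": max(truth["psi_post_decay"], 1e-9)},
                {"sample_id": f"{cond}_rep{rep}", "condition": cond,
                 "amplicon": "RBM3_Exon3", "expression": 1.0},
                {"sample_id": f"{cond}_rep{rep}", "condition": cond,
                 "amplicon": "RBM3_Exon4_5", "expression": 1.0},
            ]
            truth_rows.append({"condition": cond, "replicate": rep, **truth})
    pd.DataFrame(band_rows).to_csv(OUT / "gel_bands.csv", index=False)
    ct = sd.sim_ct_table(pd.DataFrame(expr_rows), noise_sd=0.05, seed=seed)
    ct.to_csv(OUT / "ct_table.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(OUT / "truth.csv", index=False)
    event = sd.SpliceSimParams(psi_true=0.5, n_reads=1).event
    (OUT / "event.json").write_text(json.dumps({
        "chrom": event.chrom, "strand": event.strand,
        "upstream": event.upstream, "cassette": event.cassette,
        "downstream": event.downstream}))
    print(f"wrote {2 * REPLICATES} SAM replicates at depth {DEPTH}, gel bands, "
          f"Ct table and ground truth to {OUT}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
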