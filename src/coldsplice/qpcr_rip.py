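"""qPCR relative quantification, relative poison-exon inclusion, and RIP normalization.

Relative expression follows the delta-Ct convention with an assumed
amplification efficiency of 2 (perfect doubling per cycle), configurable:
value = efficiency ** (Ct_reference - Ct_target) after collapsing technical
replicates by mean Ct.  Relative PE inclusion is the ratio of the PE
amplicon's relative expression to a constitutive amplicon (or a mean of
several).  The RIP fold change on cooling divides out both the change of
total (input) target mRNA and the immunoprecipitation efficiency of the
pulled-down protein, so only the binding change remains.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_ct_csv",
    "relative_expression",
    "fold_change",
    "pe_inclusion_ratio",
    "RipMeasurement",
    "rip_fold_change",
    "rip_fold_changes",
]

CT_COLUMNS = ["sample_id", "condition", "amplicon", "replicate", "ct"]


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Read a Ct table CSV with columns sample_id,condition,amplicon,replicate,ct."""
    df = pd.read_csv(path)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        raise ValueError("all Ct values must be finite and > 0")
    return df


def _collapse_technical(
    ct: pd.DataFrame, drop_outliers: bool, outlier_cycles: float
) -> pd.DataFrame:
    df = ct.copy()
    if drop_outliers:
        med = df.groupby(["sample_id", "amplicon"])["ct"].transform("median")
        df = df[(df["ct"] - med).abs() <= outlier_cycles]
    # mean Ct over technical replicates, per sample x amplicon
    return (
        df.groupby(["sample_id", "condition", "amplicon"], as_index=False)["ct"]
        .mean()
        .rename(columns={"ct": "mean_ct"})
    )


def relative_expression(
    ct: pd.DataFrame,
    reference_amplicon: str,
    efficiency: float = 2.0,
    drop_outliers: bool = False,
    outlier_cycles: float = 0.5,
) -> pd.DataFrame:
    """Reference-normalized relative expression per sample x amplicon.

    value = efficiency ** (mean Ct of reference - mean Ct of target), within
    each sample.  Technical replicates are collapsed by arithmetic mean of
    Ct before exponentiation; with ``drop_outliers`` replicates more than
    ``outlier_cycles`` from their replicate median are discarded first.
    """
    if efficiency <= 1.0:
        raise ValueError(f"amplification efficiency must be > 1, got {efficiency}")
    collapsed = _collapse_technical(ct, drop_outliers, outlier_cycles)
    ref = collapsed[collapsed["amplicon"] == reference_amplicon].set_index("sample_id")["mean_ct"]
    rows = []
    for r in collapsed.itertuples():
        if r.amplicon == reference_amplicon:
            continue
        if r.sample_id not in ref.index:
            raise ValueError(
                f"reference amplicon {reference_amplicon!r} missing in sample {r.sample_id!r}"
            )
        value = efficiency ** (ref.loc[r.sample_id] - r.mean_ct)
        rows.append(
            {
                "sample_id": r.sample_id,
                "condition": r.condition,
                "amplicon": r.amplicon,
                "value": float(value),
            }
        )
    if not rows:
        missing = set(ct["sample_id"]) - set(ref.index)
        if missing:
            raise ValueError(
                f"reference amplicon {reference_amplicon!r} missing in samples {sorted(missing)}"
            )
    return pd.DataFrame(rows, columns=["sample_id", "condition", "amplicon", "value"])


def fold_change(expr: pd.DataFrame, baseline_condition: str) -> pd.DataFrame:
    """Per-condition, per-amplicon fold change over the baseline condition mean."""
    base = expr[expr["condition"] == baseline_condition]
    if base.empty:
        raise ValueError(f"baseline condition {baseline_condition!r} has no samples")
    base_mean = base.groupby("amplicon")["value"].mean()
    rows = []
    for (cond, amp), grp in expr.groupby(["condition", "amplicon"]):
        if amp not in base_mean.index:
            raise ValueError(f"amplicon {amp!r} absent from baseline condition")
        rows.append(
            {
                "condition": cond,
                "amplicon": amp,
                "fold_change": grp["value"].mean() / base_mean.loc[amp],
                "n": len(grp),
            }
        )
    return pd.DataFrame(rows, columns=["condition", "amplicon", "fold_change", "n"])


def pe_inclusion_ratio(
    expr: pd.DataFrame,
    pe_amplicon: str,
    constitutive_amplicons: Sequence[str],
    mode: str,
) -> pd.DataFrame:
    """Relative PE inclusion per sample: relexpr(PE) / denominator(constitutives).

    ``mode`` is required and explicit: "single" (exactly one constitutive
    amplicon), "geometric_mean" or "arithmetic_mean" over several.  A zero
    or absent denominator flags the value as undefined (NaN, defined=False)
    rather than raising.
    """
    modes = ("single", "geometric_mean", "arithmetic_mean")
    if mode not in modes:
        raise ValueError(f"mode must be one of {modes}, got {mode!r}")
    if mode == "single" and len(constitutive_amplicons) != 1:
        raise ValueError("mode 'single' requires exactly one constitutive amplicon")
    if not constitutive_amplicons:
        raise ValueError("at least one constitutive amplicon required")

    wide = expr.pivot_table(index="sample_id", columns="amplicon", values="value")
    conditions = expr.drop_duplicates("sample_id").set_index("sample_id")["condition"]
    rows = []
    for sample_id, row in wide.iterrows():
        pe = row.get(pe_amplicon, np.nan)
        consts = np.array([row.get(a, np.nan) for a in constitutive_amplicons], dtype=float)
        if np.isnan(pe) or np.isnan(consts).any():
            value, defined = np.nan, False
        else:
            if mode == "geometric_mean":
                denom = float(np.exp(np.mean(np.log(consts)))) if (consts > 0).all() else 0.0
            else:  # single or arithmetic_mean
                denom = float(np.mean(consts))
            if denom <= 0:
                value, defined = np.nan, False
            else:
                value, defined = float(pe / denom), True
        rows.append(
            {
                "sample_id": sample_id,
                "condition": conditions.get(sample_id),
                "value": value,
                "defined": defined,
                "mode": mode,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "condition", "value", "defined", "mode"])


@dataclass(frozen=True)
class RipMeasurement:
    """One RIP replicate at one temperature: RNA quantities and protein densitometry."""

    replicate: str
    temperature: str
    rbm3_input_rna: float
    rbm3_ip_rna: float
    hnrnph1_input_protein: float
    hnrnph1_ip_protein: float

    def __post_init__(self) -> None:
        for name in (
            "rbm3_input_rna",
            "rbm3_ip_rna",
            "hnrnph1_input_protein",
            "hnrnph1_ip_protein",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def ip_efficiency(self) -> float:
        """Immunoprecipitation efficiency: protein pulled down over protein input."""
        return self.hnrnph1_ip_protein / self.hnrnph1_input_protein


def rip_fold_change(m37: RipMeasurement, m32: RipMeasurement) -> float:
    """Normalized RIP fold change on cooling for one paired replicate.

    FC = (ip32/ip37) / (input32/input37) / (eff32/eff37)

    where eff = pulled-down protein / input protein.  Dividing by the input
    RNA change removes target-mRNA abundance shifts, and by the efficiency
    change removes pulldown variability, leaving the binding change.
    """
    if m37.replicate != m32.replicate:
        raise ValueError(
            f"measurements are not a pair: replicates {m37.replicate!r} vs {m32.replicate!r}"
        )
    rna_fc = m32.rbm3_ip_rna / m37.rbm3_ip_rna
    input_fc = m32.rbm3_input_rna / m37.rbm3_input_rna
    eff_fc = m32.ip_efficiency / m37.ip_efficiency
    return rna_fc / input_fc / eff_fc


def rip_fold_changes(table: pd.DataFrame) -> pd.DataFrame:
    """Paired RIP fold changes from a long table.

    Requires columns replicate, temperature (37C/32C), rbm3_input_rna,
    rbm3_ip_rna, hnrnph1_input_protein, hnrnph1_ip_protein; each replicate
    must appear at both temperatures.
    """
    required = {
        "replicate",
        "temperature",
        "rbm3_input_rna",
        "rbm3_ip_rna",
        "hnrnph1_input_protein",
        "hnrnph1_ip_protein",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"RIP table missing columns: {sorted(missing)}")
    rows = []
    for rep, grp in table.groupby("replicate"):
        by_temp = {str(r.temperature): r for r in grp.itertuples()}
        if not {"37C", "32C"} <= set(by_temp):
            raise ValueError(f"replicate {rep!r} lacks a 37C/32C pair")
        ms = {
            t: RipMeasurement(
                replicate=str(rep),
                temperature=t,
                rbm3_input_rna=by_temp[t].rbm3_input_rna,
                rbm3_ip_rna=by_temp[t].rbm3_ip_rna,
                hnrnph1_input_protein=by_temp[t].hnrnph1_input_protein,
                hnrnph1_ip_protein=by_temp[t].hnrnph1_ip_protein,
            )
            for t in ("37C", "32C")
        }
        rows.append({"replicate": rep, "fold_change": rip_fold_change(ms["37C"], ms["32C"])})
    return pd.DataFrame(rows, columns=["replicate", "fold_change"])
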