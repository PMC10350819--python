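"""qPCR relative quantification, PE inclusion ratios, RIP normalization."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldsplice import qpcr_rip as qr
from coldsplice import synthetic_data as sd


def ct_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "condition", "amplicon", "replicate", "ct"])


def simple_ct(target_ct, ref_ct=20.0, amplicon="PE", sample="s1"):
    return ct_frame(
        [
            (sample, "c", amplicon, 1, target_ct),
            (sample, "c", "18S", 1, ref_ct),
        ]
    )


class TestRelativeExpression:
    def test_equal_ct_gives_unit_expression(self):
        expr = qr.relative_expression(simple_ct(20.0), "18S")
        assert expr["value"].iloc[0] == pytest.approx(1.0)

    def test_two_cycles_above_reference_gives_quarter(self):
        expr = qr.relative_expression(simple_ct(22.0), "18S")
        assert expr["value"].iloc[0] == pytest.approx(0.25)

    def test_recovers_simulated_expression(self):
        truth = pd.DataFrame(
            [{"sample_id": "s1", "condition": "c", "amplicon": "PE", "expression": 0.02}]
        )
        ct = sd.sim_ct_table(truth, noise_sd=0.0)
        expr = qr.relative_expression(ct, "18S")
        assert expr["value"].iloc[0] == pytest.approx(0.02)

    def test_missing_reference_names_sample(self):
        ct = ct_frame([("s9", "c", "PE", 1, 20.0)])
        with pytest.raises(ValueError, match="s9"):
            qr.relative_expression(ct, "18S")

    @settings(derandomize=True, max_examples=30)
    @given(offset=st.floats(-5, 5), ct=st.floats(10, 30))
    def test_plate_offset_invariance(self, offset, ct):
        base = qr.relative_expression(simple_ct(ct), "18S")["value"].iloc[0]
        shifted = qr.relative_expression(
            simple_ct(ct + offset, ref_ct=20.0 + offset), "18S"
        )["value"].iloc[0]
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_technical_replicates_collapsed_by_mean_ct(self):
        ct = ct_frame(
            [("s1", "c", "PE", 1, 21.0), ("s1", "c", "PE", 2, 23.0), ("s1", "c", "18S", 1, 20.0)]
        )
        expr = qr.relative_expression(ct, "18S")
        assert expr["value"].iloc[0] == pytest.approx(2.0 ** (20.0 - 22.0))

    def test_outlier_replicate_dropped_when_enabled(self):
        ct = ct_frame(
            [("s1", "c", "PE", i, v) for i, v in enumerate([20.0, 20.1, 19.9, 25.0])]
            + [("s1", "c", "18S", 1, 20.0)]
        )
        loose = qr.relative_expression(ct, "18S")["value"].iloc[0]
        strict = qr.relative_expression(ct, "18S", drop_outliers=True)["value"].iloc[0]
        assert strict == pytest.approx(2.0 ** (20.0 - 20.0), rel=1e-3)
        assert loose < strict


class TestFoldChange:
    def _expr(self, values, conditions):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(values))],
                "condition": conditions,
                "amplicon": "RBM3",
                "value": values,
            }
        )

    def test_baseline_is_unity(self):
        expr = self._expr([1.0, 1.2], ["37C", "37C"])
        fc = qr.fold_change(expr, "37C")
        assert fc["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_fourfold_induction(self):
        expr = self._expr([1.0, 1.0, 4.0, 4.0], ["37C", "37C", "32C", "32C"])
        fc = qr.fold_change(expr, "37C").set_index("condition")
        assert fc.loc["32C", "fold_change"] == pytest.approx(4.0)

    def test_empty_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            qr.fold_change(self._expr([1.0], ["32C"]), "37C")

    def test_recovery_of_simulated_induction(self):
        truth = pd.DataFrame(
            [
                {"sample_id": f"{c}_{i}", "condition": c, "amplicon": "RBM3",
                 "expression": e}
                for c, e in (("37C", 1.0), ("32C", 4.0))
                for i in range(3)
            ]
        )
        ct = sd.sim_ct_table(truth, noise_sd=0.05, seed=8)
        expr = qr.relative_expression(ct, "18S")
        fc = qr.fold_change(expr, "37C").set_index("condition")
        assert fc.loc["32C", "fold_change"] == pytest.approx(4.0, rel=0.15)


class TestPeInclusionRatio:
    def _expr(self, pe, consts):
        rows = [{"sample_id": "s1", "condition": "c", "amplicon": "PE", "value": pe}]
        rows += [
            {"sample_id": "s1", "condition": "c", "amplicon": f"E{i}", "value": v}
            for i, v in enumerate(consts)
        ]
        return pd.DataFrame(rows)

    def test_single_mode(self):
        out = qr.pe_inclusion_ratio(self._expr(0.02, [1.0]), "PE", ["E0"], "single")
        assert out["value"].iloc[0] == pytest.approx(0.02)

    def test_geometric_mean_denominator(self):
        out = qr.pe_inclusion_ratio(
            self._expr(0.02, [0.9, 1.1]), "PE", ["E0", "E1"], "geometric_mean"
        )
        assert out["value"].iloc[0] == pytest.approx(0.02 / math.sqrt(0.99))

    def test_modes_agree_for_equal_constitutives(self):
        expr = self._expr(0.05, [1.3, 1.3])
        geo = qr.pe_inclusion_ratio(expr, "PE", ["E0", "E1"], "geometric_mean")
        ari = qr.pe_inclusion_ratio(expr, "PE", ["E0", "E1"], "arithmetic_mean")
        assert geo["value"].iloc[0] == pytest.approx(ari["value"].iloc[0])

    def test_geometric_mode_equals_geometric_mean_of_single_ratios(self):
        expr = self._expr(0.04, [0.8, 1.2])
        geo = qr.pe_inclusion_ratio(expr, "PE", ["E0", "E1"], "geometric_mean")["value"].iloc[0]
        r0 = qr.pe_inclusion_ratio(expr, "PE", ["E0"], "single")["value"].iloc[0]
        r1 = qr.pe_inclusion_ratio(expr, "PE", ["E1"], "single")["value"].iloc[0]
        assert geo == pytest.approx(math.sqrt(r0 * r1))

    def test_absent_denominator_flagged_undefined(self):
        out = qr.pe_inclusion_ratio(self._expr(0.02, [1.0]), "PE", ["MISSING"], "single")
        assert not out["defined"].iloc[0]
        assert np.isnan(out["value"].iloc[0])

    def test_mode_is_required_and_validated(self):
        with pytest.raises(ValueError, match="mode"):
            qr.pe_inclusion_ratio(self._expr(0.02, [1.0]), "PE", ["E0"], "median")


def make_rip(rep="r1", temp="37C", input_rna=1.0, ip_rna=1.0, input_prot=1.0, ip_prot=0.5):
    return qr.RipMeasurement(
        replicate=rep, temperature=temp, rbm3_input_rna=input_rna, rbm3_ip_rna=ip_rna,
        hnrnph1_input_protein=input_prot, hnrnph1_ip_protein=ip_prot,
    )


class TestRipFoldChange:
    def test_identity(self):
        assert qr.rip_fold_change(make_rip(), make_rip(temp="32C")) == pytest.approx(1.0)

    def test_pure_ip_doubling(self):
        m32 = make_rip(temp="32C", ip_rna=2.0)
        assert qr.rip_fold_change(make_rip(), m32) == pytest.approx(2.0)

    def test_confound_cancellation(self):
        # IP RNA doubles AND pulldown efficiency doubles -> no binding change
        m32 = make_rip(temp="32C", ip_rna=2.0, ip_prot=1.0)
        assert qr.rip_fold_change(make_rip(), m32) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=30)
    @given(rna_scale=st.floats(0.01, 100), prot_scale=st.floats(0.01, 100))
    def test_unit_rescaling_invariance(self, rna_scale, prot_scale):
        m37 = make_rip(ip_rna=1.4, input_rna=0.9, ip_prot=0.6, input_prot=1.1)
        m32 = make_rip(temp="32C", ip_rna=2.8, input_rna=1.0, ip_prot=0.5, input_prot=1.0)
        base = qr.rip_fold_change(m37, m32)
        scaled = qr.rip_fold_change(
            make_rip(ip_rna=1.4 * rna_scale, input_rna=0.9 * rna_scale,
                     ip_prot=0.6 * prot_scale, input_prot=1.1 * prot_scale),
            make_rip(temp="32C", ip_rna=2.8 * rna_scale, input_rna=1.0 * rna_scale,
                     ip_prot=0.5 * prot_scale, input_prot=1.0 * prot_scale),
        )
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_unpaired_replicates_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            qr.rip_fold_change(make_rip(rep="r1"), make_rip(rep="r2", temp="32C"))

    def test_table_wrapper_pairs_by_replicate(self):
        table = pd.DataFrame(
            [
                {"replicate": "r1", "temperature": "37C", "rbm3_input_rna": 1.0,
                 "rbm3_ip_rna": 1.0, "hnrnph1_input_protein": 1.0, "hnrnph1_ip_protein": 0.5},
                {"replicate": "r1", "temperature": "32C", "rbm3_input_rna": 1.0,
                 "rbm3_ip_rna": 3.0, "hnrnph1_input_protein": 1.0, "hnrnph1_ip_protein": 0.5},
            ]
        )
        fc = qr.rip_fold_changes(table)
        assert fc["fold_change"].iloc[0] == pytest.approx(3.0)
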