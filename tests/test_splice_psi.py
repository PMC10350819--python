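"""Gel and junction PSI estimators: exact formulas, boundaries, invariants."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldsplice import splice_psi as sp
from coldsplice import synthetic_data as sd


def make_lane(inc, skip, inc_len=(401.0,), skip_len=301.0):
    bands = [
        sp.GelBand("L", sp.INCLUSION, f"inc{i}", v, inc_len[i]) for i, v in enumerate(inc)
    ]
    bands.append(sp.GelBand("L", sp.SKIP, "skip", skip, skip_len))
    return sp.GelLane("L", bands)


class TestGelPsi:
    @pytest.mark.parametrize(
        "inc, skip, expected",
        [
            ((0.0,), 100.0, 0.0),  # no inclusion band signal
            ((100.0,), 0.0, 1.0),  # no skip signal
        ],
    )
    def test_boundaries(self, inc, skip, expected):
        assert sp.gel_psi(make_lane(inc, skip)).psi == pytest.approx(expected)

    def test_one_band_formula_exact(self):
        # I_inc=100 @ 300 bp, I_skip=200 @ 250 bp -> (1/3)/(1/3+4/5) = 5/17
        lane = make_lane((100.0,), 200.0, inc_len=(300.0,), skip_len=250.0)
        assert sp.gel_psi(lane).psi == pytest.approx(5 / 17, abs=1e-15)

    def test_two_band_formula_sums_length_normalized_intensities(self):
        lane = sp.GelLane(
            "L",
            [
                sp.GelBand("L", sp.INCLUSION, "3a-L", 60.0, 300.0),
                sp.GelBand("L", sp.INCLUSION, "3a-S", 40.0, 280.0),
                sp.GelBand("L", sp.SKIP, "skip", 200.0, 250.0),
            ],
        )
        num = 60 / 300 + 40 / 280
        assert sp.gel_psi(lane).psi == pytest.approx(num / (num + 200 / 250), abs=1e-15)

    def test_all_zero_intensities_flagged_undefined(self):
        psi = sp.gel_psi(make_lane((0.0,), 0.0))
        assert psi.psi is None and not psi.defined

    def test_missing_skip_band_errors(self):
        lane = sp.GelLane("L", [sp.GelBand("L", sp.INCLUSION, "inc", 10.0, 300.0)])
        with pytest.raises(ValueError, match="skip band"):
            sp.gel_psi(lane)

    @settings(derandomize=True, max_examples=50)
    @given(
        inc=st.floats(0.01, 1e4),
        skip=st.floats(0.01, 1e4),
        gain=st.floats(1e-3, 1e3),
    )
    def test_gain_invariance(self, inc, skip, gain):
        base = sp.gel_psi(make_lane((inc,), skip)).psi
        scaled = sp.gel_psi(make_lane((inc * gain,), skip * gain)).psi
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_noiseless_mass_proportional_gel_recovers_molar_fraction(self):
        lane = sd.sim_gel(
            {"inc": 3.0, "skip": 5.0}, {"inc": 401.0, "skip": 301.0}, "skip", noise_sd=0.0
        )
        assert sp.gel_psi(lane).psi == pytest.approx(3 / 8, abs=1e-12)


class TestJunctionPsi:
    def test_equal_counts_with_default_lengths(self):
        ell = sp.junction_effective_length(100, 6)
        counts = sp.JunctionCounts(10, 10, 10, eff_len_inc=2 * ell, eff_len_skip=ell)
        assert sp.junction_psi(counts).psi == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "i_up, i_down, s, expected", [(5, 7, 0, 1.0), (0, 0, 9, 0.0)]
    )
    def test_boundaries(self, i_up, i_down, s, expected):
        counts = sp.JunctionCounts(i_up, i_down, s, eff_len_inc=180, eff_len_skip=90)
        assert sp.junction_psi(counts).psi == pytest.approx(expected)

    def test_all_zero_counts_flagged_undefined(self):
        psi = sp.junction_psi(sp.JunctionCounts(0, 0, 0, 180, 90))
        assert psi.psi is None and not psi.defined

    def test_equal_effective_lengths_reduce_to_count_fraction(self):
        counts = sp.JunctionCounts(12, 8, 30, eff_len_inc=90, eff_len_skip=90)
        assert sp.junction_psi(counts).psi == pytest.approx(20 / 50)

    @settings(derandomize=True, max_examples=40)
    @given(
        i=st.integers(1, 500), s=st.integers(0, 500), extra=st.integers(1, 50)
    )
    def test_monotonicity(self, i, s, extra):
        base = sp.junction_psi(sp.JunctionCounts(i, i, s + 1, 180, 90)).psi
        more_inc = sp.junction_psi(sp.JunctionCounts(i + extra, i, s + 1, 180, 90)).psi
        more_skip = sp.junction_psi(sp.JunctionCounts(i, i, s + 1 + extra, 180, 90)).psi
        assert more_inc > base
        assert more_skip < base


class TestExtractJunctionCounts:
    def test_empty_alignments(self):
        params = sd.SpliceSimParams(psi_true=0.5, n_reads=0, seed=0)
        res = sd.sim_junction_reads(params)
        counts = sp.extract_junction_counts(res.records, res.event)
        assert (counts.i_up, counts.i_down, counts.s) == (0, 0, 0)

    def test_single_constructed_read_counts_upstream_junction(self, tmp_path):
        params = sd.SpliceSimParams(psi_true=1.0, n_reads=1, read_length=20, min_anchor=10, seed=5)
        res = sd.sim_junction_reads(params, out_sam=tmp_path / "one.sam")
        counts = sp.extract_junction_counts(tmp_path / "one.sam", res.event, min_anchor=6)
        assert counts.i_up + counts.i_down == 1
        assert counts.s == 0

    def test_round_trip_matches_truth_labels(self, tmp_path):
        params = sd.SpliceSimParams(psi_true=0.4, n_reads=2000, seed=11)
        res = sd.sim_junction_reads(params, out_sam=tmp_path / "reads.sam")
        counts = sp.extract_junction_counts(tmp_path / "reads.sam", res.event)
        truth = res.truth_reads["junction"].value_counts()
        assert counts.i_up == truth.get("upstream_inclusion", 0)
        assert counts.i_down == truth.get("downstream_inclusion", 0)
        assert counts.s == truth.get("skip", 0)

    def test_simulation_recovery_within_3se(self):
        params = sd.SpliceSimParams(psi_true=0.5, n_reads=10_000, seed=2)
        res = sd.sim_junction_reads(params)
        psi = sp.junction_psi(sp.extract_junction_counts(res.records, res.event))
        se = np.sqrt(0.5 * 0.5 / params.n_reads)
        assert abs(psi.psi - 0.5) < 3 * se * 1.5  # two-stage sampling inflates SE slightly

    def test_reference_mismatch_names_both(self, tmp_path):
        params = sd.SpliceSimParams(psi_true=0.5, n_reads=10, seed=0)
        res = sd.sim_junction_reads(params, out_sam=tmp_path / "r.sam")
        event = sd.SpliceSimParams(psi_true=0.5, n_reads=10, chrom="chrOther").event
        with pytest.raises(ValueError, match="chrOther"):
            sp.extract_junction_counts(tmp_path / "r.sam", event)

    def test_secondary_records_ignored(self):
        params = sd.SpliceSimParams(psi_true=1.0, n_reads=50, seed=7)
        res = sd.sim_junction_reads(params)
        for rec in res.records:
            rec.flag |= 0x100  # mark everything secondary
        counts = sp.extract_junction_counts(res.records, res.event)
        assert (counts.i_up, counts.i_down, counts.s) == (0, 0, 0)

    def test_min_anchor_filters_short_overhangs(self):
        params = sd.SpliceSimParams(psi_true=0.0, n_reads=300, read_length=100, min_anchor=6, seed=3)
        res = sd.sim_junction_reads(params)
        # reads were emitted with >= 6 nt anchors; demanding 60 nt drops most
        loose = sp.extract_junction_counts(res.records, res.event, min_anchor=6)
        strict = sp.extract_junction_counts(res.records, res.event, min_anchor=45)
        assert strict.s < loose.s


class TestDeltaPsi:
    def test_identical_groups(self):
        out = sp.delta_psi([0.5, 0.5], [0.5, 0.5])
        assert out["effect"] == 0.0
        assert out["p"] == 1.0

    def test_exhaustive_permutation_p(self):
        # pooled {0.9, 0.9, 0.1, 0.1}: 6 assignments, 2 reach |effect| = 0.8
        out = sp.delta_psi([0.9, 0.9], [0.1, 0.1])
        assert out["exhaustive"]
        assert out["n_perm"] == 6
        assert out["p"] == pytest.approx((2 + 1) / (6 + 1))

    def test_label_swap_negates_effect(self):
        a, b = [0.7, 0.8, 0.75], [0.2, 0.25, 0.3]
        assert sp.delta_psi(a, b)["effect"] == pytest.approx(-sp.delta_psi(b, a)["effect"])

    def test_insufficient_replicates_flags_p_absent(self):
        out = sp.delta_psi([0.9], [0.1, 0.2])
        assert out["p"] is None
        assert out["effect"] == pytest.approx(0.9 - 0.15)
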