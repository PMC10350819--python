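"""Guide counting by exact 20-mer match and enrichment scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coldsplice import screen_counts as sc
from coldsplice import synthetic_data as sd


class TestLibrary:
    def test_valid_library_loads(self, tmp_path):
        path = tmp_path / "lib.tsv"
        path.write_text(
            "guide_id\tgene\tsequence\n"
            "g1\tGENE1\tACGTACGTACGTACGTACGT\n"
            "g2\tGENE1\tTTTTACGTACGTACGTACGT\n"
            "g3\tNON_TARGETING\tGGGGACGTACGTACGTACGT\n"
        )
        lib = sc.load_library(path)
        assert len(lib) == 3
        assert lib.non_targeting_ids == ["g3"]

    def test_duplicate_sequence_errors_listing_ids(self, tmp_path):
        path = tmp_path / "lib.tsv"
        path.write_text(
            "guide_id\tgene\tsequence\n"
            "g1\tA\tACGTACGTACGTACGTACGT\n"
            "g2\tB\tACGTACGTACGTACGTACGT\n"
        )
        with pytest.raises(ValueError, match="g1.*g2"):
            sc.load_library(path)

    def test_lowercase_canonicalized(self, tmp_path):
        path = tmp_path / "lib.tsv"
        path.write_text("guide_id\tgene\tsequence\ng1\tA\tacgtacgtacgtacgtacgt\n")
        lib = sc.load_library(path)
        assert lib.guides["sequence"].iloc[0] == "ACGTACGTACGTACGTACGT"

    def test_wrong_length_errors(self, tmp_path):
        path = tmp_path / "lib.tsv"
        path.write_text("guide_id\tgene\tsequence\ng1\tA\tACGT\n")
        with pytest.raises(ValueError, match="length"):
            sc.load_library(path)


class TestCountGuides:
    def write_fastq(self, path, reads):
        with open(path, "w") as fh:
            for i, r in enumerate(reads):
                fh.write(f"@r{i}\n{r}\n+\n{'?' * len(r)}\n")

    def test_guide_plus_extra_base_counted(self, small_guide_library, tmp_path):
        seq = small_guide_library.guides["sequence"].iloc[0]
        gid = small_guide_library.guides["guide_id"].iloc[0]
        path = tmp_path / "r.fastq"
        self.write_fastq(path, [seq + "A"])
        col = sc.count_guides(path, small_guide_library)
        assert col.counts[gid] == 1 and col.matched == 1 and col.discarded == 0

    def test_single_substitution_discarded(self, small_guide_library, tmp_path):
        seq = small_guide_library.guides["sequence"].iloc[0]
        mutated = ("A" if seq[10] != "A" else "C") .join([seq[:10], seq[11:]])
        path = tmp_path / "r.fastq"
        self.write_fastq(path, [mutated + "A"])
        col = sc.count_guides(path, small_guide_library)
        assert col.matched == 0 and col.discarded == 1

    def test_truncated_read_discarded_not_fatal(self, small_guide_library, tmp_path):
        path = tmp_path / "r.fastq"
        self.write_fastq(path, ["ACGTACGT"])
        col = sc.count_guides(path, small_guide_library)
        assert col.discarded == 1

    def test_round_trip_recovers_drawn_counts_exactly(self, small_guide_library, tmp_path):
        params = sd.ScreenSimParams(
            library=small_guide_library, n_reads=5000, mutation_fraction=0.0, seed=2
        )
        res = sd.sim_screen_fastq(params, tmp_path)
        for sample, path in res.fastq_paths.items():
            col = sc.count_guides(path, small_guide_library, sample=sample)
            assert (col.counts.values == res.truth_counts[sample].values).all()
            assert col.discarded == 0

    def test_all_mutated_reads_discarded(self, small_guide_library, tmp_path):
        params = sd.ScreenSimParams(
            library=small_guide_library, n_reads=2000, mutation_fraction=1.0, seed=2
        )
        res = sd.sim_screen_fastq(params, tmp_path)
        col = sc.count_guides(res.fastq_paths["low"], small_guide_library)
        assert col.matched == 0
        assert col.discarded == int(res.truth_counts["low"].sum())

    def test_conservation_matched_plus_discarded(self, small_guide_library, tmp_path):
        params = sd.ScreenSimParams(
            library=small_guide_library, n_reads=3000, mutation_fraction=0.3, seed=4
        )
        res = sd.sim_screen_fastq(params, tmp_path)
        for sample, path in res.fastq_paths.items():
            col = sc.count_guides(path, small_guide_library, sample=sample)
            assert col.matched + col.discarded == int(res.truth_counts[sample].sum())

    def test_offset_scan_recovers_shifted_guides(self, small_guide_library, tmp_path):
        seq = small_guide_library.guides["sequence"].iloc[1]
        gid = small_guide_library.guides["guide_id"].iloc[1]
        path = tmp_path / "r.fastq"
        self.write_fastq(path, ["T" + seq])  # guide shifted to offset 1
        strict = sc.count_guides(path, small_guide_library, guide_offset=0)
        scanned = sc.count_guides(path, small_guide_library, guide_offset=0, offset_scan=True)
        assert strict.matched == 0
        assert scanned.counts[gid] == 1


class TestNormalizeAndScore:
    def _table(self, counts_dict):
        cols = [
            sc.CountColumn(sample=s, counts=pd.Series(v), matched=int(sum(v.values())),
                           discarded=0)
            for s, v in counts_dict.items()
        ]
        return sc.merge_counts(cols)

    def test_columns_sum_to_one_million(self):
        t = self._table({"low": {"g1": 10, "g2": 30}, "high": {"g1": 5, "g2": 5}})
        norm = sc.normalize_counts(t)
        assert norm.sum(axis=0).tolist() == pytest.approx([1e6, 1e6])

    def test_scaling_invariance(self):
        t1 = self._table({"low": {"g1": 10, "g2": 30}})
        t2 = self._table({"low": {"g1": 20, "g2": 60}})
        pd.testing.assert_frame_equal(sc.normalize_counts(t1), sc.normalize_counts(t2))

    def test_zero_total_errors(self):
        t = self._table({"low": {"g1": 0, "g2": 0}})
        with pytest.raises(ValueError, match="zero matched"):
            sc.normalize_counts(t)

    def test_lfc_zero_for_equal_means_and_finite_for_zeros(self):
        norm = pd.DataFrame({"low": [100.0, 0.0], "high": [100.0, 50.0]}, index=["g1", "g2"])
        lfc = sc.guide_lfc(norm, ["low"], ["high"])
        assert lfc["g1"] == 0.0
        assert np.isfinite(lfc["g2"])

    def test_lfc_doubling_near_one(self):
        norm = pd.DataFrame({"low": [2000.0], "high": [1000.0]}, index=["g1"])
        assert sc.guide_lfc(norm, ["low"], ["high"])["g1"] == pytest.approx(1.0, abs=1e-3)

    def test_identical_lfc_gives_zero_z_and_unit_p(self, guide_library):
        lfc = pd.Series(0.7, index=guide_library.guides["guide_id"])
        out = sc.gene_score(lfc, guide_library, n_perm=200, seed=0)
        assert (out["guide_z"] == 0).all()
        assert (out["genes"]["p"] == 1.0).all()

    def test_few_non_targeting_guides_warns_and_falls_back(self, small_guide_library):
        lib = sc.GuideLibrary(
            small_guide_library.guides.assign(
                gene=["NON_TARGETING"] * 2
                + ["GENE%d" % (i // 5) for i in range(len(small_guide_library) - 2)]
            )
        )
        lfc = pd.Series(
            np.random.default_rng(0).normal(size=len(lib)), index=lib.guides["guide_id"]
        )
        with pytest.warns(UserWarning, match="non-targeting"):
            sc.gene_score(lfc, lib, n_perm=100, seed=0)

    def test_mageck_export_layout(self, small_guide_library, tmp_path):
        t = self._table(
            {
                "low": dict.fromkeys(small_guide_library.guides["guide_id"], 5),
                "high": dict.fromkeys(small_guide_library.guides["guide_id"], 7),
            }
        )
        path = t.to_mageck_tsv(small_guide_library, tmp_path / "counts.tsv")
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["sgRNA", "gene", "low", "high"]
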