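"""Marker filtering, bin construction, testcross deduction and map estimation."""

import numpy as np
import pandas as pd
import pytest

import heteroqtl as hq
from heteroqtl.genotypes import LinkageError

from conftest import make_matrix


def _random_hom_column(rng, n):
    return rng.choice([0, 2], size=n)


class TestFilterMarkers:
    def _fixture(self):
        """10 markers, 100 lines; m7 monomorphic, m8 rare allele, m9 25% missing."""
        rng = np.random.default_rng(42)
        n = 100
        cols = [_random_hom_column(rng, n) for _ in range(7)]
        cols.append(np.zeros(n, dtype=int))              # monomorphic
        rare = np.zeros(n, dtype=int)
        rare[0] = 1                                      # single het -> MAF 0.005
        cols.append(rare)
        missing = _random_hom_column(rng, n)
        missing[:25] = -9                                # 25% missing
        cols.append(missing)
        codes = np.column_stack(cols)
        return make_matrix(codes, ["c1"] * 10, list(range(0, 100, 10)))

    def test_three_violating_markers_removed(self):
        m = self._fixture()
        kept = hq.filter_markers(m)
        assert kept.n_markers == 7
        assert {"m7", "m8", "m9"}.isdisjoint(kept.marker_ids)

    def test_monomorphic_removed(self):
        m = make_matrix(np.zeros((50, 2), dtype=int) + [[0, 0]], ["c1"] * 2, [0, 10])
        g = m.genotypes.copy()
        g["m1"] = np.random.default_rng(1).choice([0, 2], 50)
        m = hq.MarkerMatrix(g, m.marker_map)
        kept = hq.filter_markers(m, het_max=None)
        assert list(kept.marker_ids) == ["m1"]

    def test_all_removed_raises_with_thresholds(self):
        m = make_matrix(np.zeros((40, 2), dtype=int), ["c1"] * 2, [0, 10])
        with pytest.raises(ValueError, match="maf_min"):
            hq.filter_markers(m)


class TestBinMarkers:
    def test_identical_adjacent_markers_form_one_bin(self):
        rng = np.random.default_rng(7)
        col = _random_hom_column(rng, 40)
        codes = np.column_stack([col] * 5)
        m = make_matrix(codes, ["c1"] * 5, [0, 1, 2, 3, 4])
        binmap, binned = hq.bin_markers(m)
        assert binmap.n_bins == 1
        assert len(binmap.bins.iloc[0]["members"]) == 5
        assert binned.n_markers == 1

    def test_discordant_marker_breaks_adjacency(self):
        rng = np.random.default_rng(8)
        a = _random_hom_column(rng, 40)
        b = 2 - a  # everywhere different
        codes = np.column_stack([a, b, a])
        m = make_matrix(codes, ["c1"] * 3, [0, 1, 2])
        binmap, _ = hq.bin_markers(m)
        assert binmap.n_bins == 3

    def test_representative_has_min_missing_rate(self):
        rng = np.random.default_rng(9)
        a = _random_hom_column(rng, 60)
        a2 = a.copy()
        a2[:5] = -9
        codes = np.column_stack([a2, a])
        m = make_matrix(codes, ["c1"] * 2, [0, 1])
        binmap, binned = hq.bin_markers(m)
        assert binmap.n_bins == 1
        assert binmap.bins.iloc[0]["representative"] == "m1"

    def test_binning_is_idempotent(self, ril_300):
        _, binned = hq.bin_markers(ril_300)
        binmap2, binned2 = hq.bin_markers(binned)
        assert binmap2.n_bins == binned.n_markers
        pd.testing.assert_frame_equal(binned.genotypes, binned2.genotypes)

    def test_binned_matrix_preserves_per_line_recombination_events(self):
        """Collapsing redundant columns loses no crossover interval: each
        line's run-length-collapsed genotype sequence is unchanged."""
        ms = hq.GeneticMapSpec([hq.ChromosomeSpec("c1", 180.0, 5000)])
        cfg = hq.SimConfig(n_lines=1000, seed=77)
        rils = hq.simulate_ril_genotypes(ms, cfg)
        _, binned = hq.bin_markers(rils)
        g_full = rils.genotypes.to_numpy()
        g_bin = binned.genotypes.to_numpy()

        def collapse(row):
            return row[np.insert(row[1:] != row[:-1], 0, True)]

        for i in range(0, 1000, 37):
            assert np.array_equal(collapse(g_full[i]), collapse(g_bin[i]))


class TestDeduceBC1F1:
    @pytest.mark.parametrize(
        "ril_code,rec,expected",
        [
            (0, 0, 0),     # same homozygote as recurrent parent
            (2, 0, 1),     # opposite homozygote -> heterozygote
            (1, 0, -9),    # heterozygous RIL -> missing
            (-9, 0, -9),   # missing stays missing
            (2, 2, 2),
            (0, 2, 1),
            (1, 2, -9),
            (-9, 2, -9),
        ],
    )
    def test_truth_table(self, ril_code, rec, expected):
        m = make_matrix([[ril_code]], ["c1"], [0.0])
        out = hq.deduce_bc1f1_genotypes(m, np.array([rec]))
        assert out.genotypes.iloc[0, 0] == expected

    def test_heterozygous_recurrent_parent_rejected(self):
        m = make_matrix([[0]], ["c1"], [0.0])
        with pytest.raises(ValueError, match="homozygous"):
            hq.deduce_bc1f1_genotypes(m, np.array([1]))

    def test_no_donor_homozygotes_created(self, ril_300):
        out = hq.deduce_bc1f1_genotypes(ril_300)
        assert not (out.genotypes.to_numpy() == hq.HOM_DONOR).any()

    def test_deduction_matches_simulated_testcross_at_homozygous_loci(self, ril_300):
        cfg = hq.SimConfig(n_lines=300, seed=20240301)
        bc_true = hq.cross_to_bc1f1(ril_300, cfg)
        deduced = hq.deduce_bc1f1_genotypes(ril_300)
        hom = np.isin(ril_300.genotypes.to_numpy(), (0, 2))
        assert np.array_equal(
            bc_true.genotypes.to_numpy()[hom], deduced.genotypes.to_numpy()[hom]
        )


class TestLinkageMapEstimation:
    def test_zero_discordance_zero_distance(self):
        rng = np.random.default_rng(10)
        col = _random_hom_column(rng, 100)
        m = make_matrix(np.column_stack([col, col]), ["c1"] * 2, [0, 5])
        est = hq.estimate_linkage_map(m)
        assert est["cm"].tolist() == [0.0, 0.0]

    def test_closed_form_distance_at_discordance_04(self):
        """R = 0.4 -> r = 1/3 -> d = -50 ln(1/3) = 54.93 cM."""
        n = 1000
        a = np.array([0, 2] * (n // 2))
        b = a.copy()
        b[: int(0.4 * n)] = 2 - b[: int(0.4 * n)]  # exactly 40% discordant
        m = make_matrix(np.column_stack([a, b]), ["c1"] * 2, [0, 5])
        est = hq.estimate_linkage_map(m)
        assert est["cm"].iloc[1] == pytest.approx(54.93, abs=0.01)

    def test_unlinked_pair_raises_listing_markers(self):
        n = 400
        a = np.array([0, 2] * (n // 2))
        b = 2 - a
        m = make_matrix(np.column_stack([a, b]), ["c1"] * 2, [0, 5])
        with pytest.raises(LinkageError, match="m0--m1"):
            hq.estimate_linkage_map(m)

    def test_simulated_map_round_trip(self):
        """10 cM true spacing recovered within 1.5 cM at n = 5,000."""
        ms = hq.GeneticMapSpec([hq.ChromosomeSpec("c1", 90.0, 10)])
        cfg = hq.SimConfig(n_lines=5000, seed=14)
        rils = hq.simulate_ril_genotypes(ms, cfg)
        est = hq.estimate_linkage_map(rils)
        spacings = np.diff(est["cm"].to_numpy())
        assert np.abs(spacings - 10.0).max() < 1.5
        # cumulative positions are additive and non-negative by construction
        assert (np.diff(est["cm"]) >= 0).all()


class TestBinmapSummary:
    def _uniform_binmap(self, n_bins, span):
        pos = np.linspace(0.0, span, n_bins)
        bins = pd.DataFrame(
            {
                "chrom": "c1",
                "start_bp": (pos * 1000 + 1).astype(int),
                "end_bp": (pos * 1000 + 1).astype(int),
                "start_cm": pos,
                "end_cm": pos,
                "representative": [f"b{i}" for i in range(n_bins)],
                "members": [(f"b{i}",) for i in range(n_bins)],
            }
        )
        return hq.BinMap(bins)

    def test_study_scale_spacing(self):
        s = hq.summarize_binmap(self._uniform_binmap(855, 2268.0))
        assert s["mean_spacing_cm"] == 2.65

    def test_single_bin_spacing_zero(self):
        s = hq.summarize_binmap(self._uniform_binmap(1, 0.0))
        assert s["mean_spacing_cm"] == 0.0

    def test_ten_bins_over_90_cm(self):
        s = hq.summarize_binmap(self._uniform_binmap(10, 90.0))
        assert s["mean_spacing_cm"] == 9.00


class TestVCFIngestion:
    def test_biallelic_sites_mapped_to_parental_codes(self, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tREC\tDON\tL1\tL2\tL3\n"
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t1/1\t0/0\t0/1\t1/1\n"
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/0\t1/1\t./.\t0/0\n"
            "chr1\t300\t.\tG\tC\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\t0/0\t0/0\n"  # het parent: skipped
        )
        from heteroqtl.genotypes import read_vcf

        m = read_vcf(str(vcf), "REC", "DON", lines=["L1", "L2", "L3"])
        assert m.n_markers == 2  # the het-parent site is dropped
        # site 1: donor allele is ALT; site 2: donor allele is REF
        assert m.genotypes["chr1_100"].tolist() == [0, 1, 2]
        assert m.genotypes["chr1_200"].tolist() == [0, -9, 2]
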