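"""Cofactor selection, interval-scan likelihood, peak calling and the 2-D scan."""

import numpy as np
import pandas as pd
import pytest

import heteroqtl as hq
from heteroqtl.scan import (
    CofactorModel,
    ScanConfig,
    adjust_phenotype,
    encode_genotypes,
)

from conftest import make_matrix, strip_heterozygotes


def _ril(map_spec, n, seed):
    return hq.simulate_ril_genotypes(map_spec, hq.SimConfig(n_lines=n, seed=seed))


def _line_series(m, values):
    return pd.Series(np.asarray(values, dtype=float), index=m.line_ids)


class TestCofactorSelection:
    def test_null_trait_rarely_selects(self, ril_300):
        """Expected false entries ~ p_markers * PIN; the mean count over many
        null traits stays well below 1.5."""
        rng = np.random.default_rng(31)
        cfg = ScanConfig(design="RIL", pin=1e-3)
        counts = []
        for _ in range(200):
            y = _line_series(ril_300, rng.normal(size=ril_300.n_lines))
            counts.append(len(hq.select_cofactors(ril_300, y, cfg).markers))
        assert np.mean(counts) <= 1.5

    def test_planted_marker_always_selected(self, five_chrom_map):
        rng = np.random.default_rng(32)
        m = _ril(five_chrom_map, 1000, 33)
        X, _ = encode_genotypes(m, "RIL")
        k = 30
        y = _line_series(m, 3.0 * X[:, k] + rng.normal(size=1000))
        sel = hq.select_cofactors(m, y, ScanConfig(design="RIL"))
        target_cm = m.marker_map["cm"].iloc[k]
        target_chrom = m.marker_map["chrom"].iloc[k]
        assert any(
            m.marker_map.loc[mk, "chrom"] == target_chrom
            and abs(m.marker_map.loc[mk, "cm"] - target_cm) <= 2.5
            for mk in sel.markers
        )

    def test_empty_marker_set_selects_nothing(self):
        m = make_matrix(np.empty((40, 0), dtype=int), [], [])
        y = pd.Series(np.random.default_rng(0).normal(size=40), index=m.line_ids)
        assert hq.select_cofactors(m, y, ScanConfig()).markers == []


class TestAdjustPhenotype:
    def test_no_cofactors_leaves_y_unchanged(self, ril_300):
        y = _line_series(ril_300, np.arange(300, dtype=float))
        model = CofactorModel([], [], np.empty(0), np.empty((300, 0)), float(y.mean()))
        assert (adjust_phenotype(y, model) == y).all()

    def test_excluding_own_interval_leaves_y_unchanged(self, ril_300):
        rng = np.random.default_rng(34)
        X, _ = encode_genotypes(ril_300, "RIL")
        y = _line_series(ril_300, 2.0 * X[:, 10] + rng.normal(size=300))
        model = hq.select_cofactors(ril_300, y, ScanConfig(design="RIL"))
        adj = adjust_phenotype(y, model, exclude_markers=set(model.markers))
        assert np.allclose(adj, y)

    def test_other_chromosome_cofactor_residualized(self, ril_300):
        """After adjustment, the cofactor marker's regression slope is ~0."""
        rng = np.random.default_rng(35)
        X, _ = encode_genotypes(ril_300, "RIL")
        k = 5  # chr1 marker
        y = _line_series(ril_300, 1.5 * X[:, k] + rng.normal(size=300))
        model = hq.select_cofactors(ril_300, y, ScanConfig(design="RIL"))
        assert model.markers  # the planted marker is selected
        adj = adjust_phenotype(y, model).to_numpy()
        x = X[:, k] - X[:, k].mean()
        slope = float(x @ (adj - adj.mean())) / float(x @ x)
        assert abs(slope) < 0.05


class TestIntervalScan:
    def test_em_equals_marker_regression_at_informative_bins(self, ril_300_informative):
        """At a fully informative bin the mixture collapses to exact two-class
        regression; LOD agreement to 1e-6."""
        m = ril_300_informative
        rng = np.random.default_rng(36)
        X, _ = encode_genotypes(m, "RIL")
        y = _line_series(m, 0.8 * X[:, 47] + rng.normal(size=300))
        cfg = ScanConfig(design="RIL")
        res = hq.scan_additive(m, y, cfg)
        model = hq.select_cofactors(m, y, cfg)
        yv = y.to_numpy()
        mm = m.marker_map
        for mk in list(m.marker_ids)[::7]:
            ch, cm = mm.loc[mk, "chrom"], mm.loc[mk, "cm"]
            excl = {
                c for c in model.markers
                if mm.loc[c, "chrom"] == ch and abs(mm.loc[c, "cm"] - cm) < 1e-9
            }
            ya = model.adjust(yv, excl)
            x = X[:, list(m.marker_ids).index(mk)]
            D = np.column_stack([np.ones(len(ya)), x])
            b, *_ = np.linalg.lstsq(D, ya, rcond=None)
            rss1 = float(((ya - D @ b) ** 2).sum())
            rss0 = float(((ya - ya.mean()) ** 2).sum())
            lod_oracle = 0.5 * len(ya) * np.log10(rss0 / rss1)
            row = res[(res["chrom"] == ch) & (np.abs(res["cm"] - cm) < 1e-9)]
            assert float(row["lod"].iloc[0]) == pytest.approx(lod_oracle, abs=1e-6)

    def test_planted_qtl_recovered_within_5cm(self, five_chrom_map):
        hits = 0
        for rep in range(10):
            cfg_sim = hq.SimConfig(
                n_lines=1000, seed=4000 + rep,
                trait_means={"T": 0.0}, residual_sd={"T": 1.0}, replicates=1,
            )
            rils = hq.simulate_ril_genotypes(five_chrom_map, cfg_sim)
            ph = hq.simulate_phenotypes(rils, [hq.QTLSpec("chr2", 37.0, "T", a=0.25)], [], cfg_sim)
            y = ph.groupby("line")["value"].mean()
            res = hq.scan_additive(rils, y, ScanConfig(design="RIL"))
            calls = hq.call_qtl(res, 3.0, rils.marker_map)
            ok = (
                (calls["chrom"] == "chr2") & (np.abs(calls["peak_cm"] - 37.0) <= 5.0)
            ).any()
            hits += bool(ok)
        assert hits >= 9

    def test_lod_invariant_under_affine_phenotype_transform(self, ril_300):
        rng = np.random.default_rng(37)
        X, _ = encode_genotypes(ril_300, "RIL")
        y = _line_series(ril_300, 0.5 * X[:, 60] + rng.normal(size=300))
        cfg = ScanConfig(design="RIL")
        res1 = hq.scan_additive(ril_300, y, cfg)
        res2 = hq.scan_additive(ril_300, 3.0 * y + 7.0, cfg)
        np.testing.assert_allclose(res1["lod"], res2["lod"], atol=1e-5)
        assert (res1["pve"] <= 100).all() and (res1["pve"] >= 0).all()

    def test_hmp_scan_effect_sign_matches_dominance(self, five_chrom_map):
        """Scanning heterosis values with the testcross coding estimates d
        with the planted sign."""
        signs = []
        for rep, d in enumerate([1.0, -1.0, 1.2, -1.2]):
            cfg_sim = hq.SimConfig(
                n_lines=800, seed=4100 + rep,
                trait_means={"T": 20.0}, residual_sd={"T": 0.8}, replicates=2,
            )
            rils = hq.simulate_ril_genotypes(five_chrom_map, cfg_sim)
            bc = hq.cross_to_bc1f1(rils, cfg_sim)
            q = [hq.QTLSpec("chr3", 50.0, "T", a=0.5, d=d)]
            ph_ril = hq.simulate_phenotypes(rils, q, [], cfg_sim, rng_stage="pr")
            ph_bc = hq.simulate_phenotypes(bc, q, [], cfg_sim, rng_stage="pb")
            het = hq.heterosis_table(ph_bc, ph_ril, {"T": {"E1": 20.0 - 0.5}})
            y = het.set_index("line")["hmp_pct"]
            res = hq.scan_additive(
                hq.deduce_bc1f1_genotypes(rils), y, ScanConfig(design="HMP")
            )
            peak = res.loc[res[res["chrom"] == "chr3"]["lod"].idxmax()]
            signs.append(np.sign(peak["effect"]) == np.sign(d))
        assert sum(signs) >= 3


class TestPermutationThreshold:
    def test_quantile_edges_and_monotonicity(self, ril_300):
        rng = np.random.default_rng(38)
        y = _line_series(ril_300, rng.normal(size=300))
        t_100 = hq.permutation_threshold(
            ril_300, y, ScanConfig(design="RIL", alpha=1.0), seed=5, n_permutations=20
        )
        t_05 = hq.permutation_threshold(
            ril_300, y, ScanConfig(design="RIL", alpha=0.05), seed=5, n_permutations=20
        )
        t_10 = hq.permutation_threshold(
            ril_300, y, ScanConfig(design="RIL", alpha=0.10), seed=5, n_permutations=20
        )
        assert t_100 <= t_10 <= t_05


class TestCallQTL:
    def _scan_df(self, cms, lods, chrom="c1"):
        return pd.DataFrame(
            {
                "chrom": chrom,
                "cm": cms,
                "lod": lods,
                "effect": 1.0,
                "pve": 5.0,
                "left_marker": "mL",
                "right_marker": "mR",
            }
        )

    _map = pd.DataFrame(
        {"chrom": ["c1", "c1"], "cm": [0.0, 50.0], "bp": [1, 5_000_000]},
        index=["mL", "mR"],
    )

    def test_flat_scan_empty(self):
        scan = self._scan_df(np.arange(0, 50.0), np.full(50, 1.0))
        assert hq.call_qtl(scan, 3.0, self._map).empty

    def test_close_peaks_merged(self):
        cms = np.arange(0, 21.0)
        lods = np.full(21, 0.5)
        lods[8] = 5.0
        lods[12] = 6.0  # 4 cM away -> merged into the higher peak
        calls = hq.call_qtl(self._scan_df(cms, lods), 3.0, self._map)
        assert len(calls) == 1
        assert calls["peak_cm"].iloc[0] == 12.0

    def test_two_distant_planted_qtl_give_two_calls(self, five_chrom_map):
        cfg_sim = hq.SimConfig(
            n_lines=1000, seed=41, trait_means={"T": 0.0},
            residual_sd={"T": 1.0}, replicates=1,
        )
        rils = hq.simulate_ril_genotypes(five_chrom_map, cfg_sim)
        qtl = [hq.QTLSpec("chr1", 20.0, "T", a=0.5), hq.QTLSpec("chr1", 80.0, "T", a=0.5)]
        ph = hq.simulate_phenotypes(rils, qtl, [], cfg_sim)
        y = ph.groupby("line")["value"].mean()
        res = hq.scan_additive(rils, y, ScanConfig(design="RIL"))
        calls = hq.call_qtl(res, 3.0, rils.marker_map)
        chr1 = calls[calls["chrom"] == "chr1"]
        assert len(chr1) == 2
        assert (chr1["ci_lo_cm"] <= chr1["peak_cm"]).all()
        assert (chr1["peak_cm"] <= chr1["ci_hi_cm"]).all()


class TestEpistasisScan:
    _map3 = hq.GeneticMapSpec([hq.ChromosomeSpec(f"c{i}", 100.0, 21) for i in (1, 2, 3)])

    def test_planted_interaction_found_near_true_loci(self):
        found = 0
        for rep in range(6):
            cfg_sim = hq.SimConfig(
                n_lines=1000, seed=4200 + rep,
                trait_means={"T": 0.0}, residual_sd={"T": 1.0}, replicates=1,
            )
            rils = hq.simulate_ril_genotypes(self._map3, cfg_sim)
            epi = [hq.EpistasisSpec(("c1", 40.0), ("c2", 65.0), "T", aa=0.8)]
            ph = hq.simulate_phenotypes(rils, [], epi, cfg_sim)
            y = ph.groupby("line")["value"].mean()
            pairs = hq.scan_epistasis(rils, y, ScanConfig.for_epistasis("RIL"))
            ok = any(
                r["chrom1"] == "c1" and abs(r["cm1"] - 40.0) <= 5.0
                and r["chrom2"] == "c2" and abs(r["cm2"] - 65.0) <= 5.0
                for _, r in pairs.iterrows()
            )
            found += bool(ok)
        assert found >= 5

    def test_additive_only_trait_yields_no_pairs(self):
        clean = 0
        for rep in range(6):
            cfg_sim = hq.SimConfig(
                n_lines=1000, seed=4300 + rep,
                trait_means={"T": 0.0}, residual_sd={"T": 1.0}, replicates=1,
            )
            rils = hq.simulate_ril_genotypes(self._map3, cfg_sim)
            qtl = [hq.QTLSpec("c3", 50.0, "T", a=0.5)]
            ph = hq.simulate_phenotypes(rils, qtl, [], cfg_sim)
            y = ph.groupby("line")["value"].mean()
            pairs = hq.scan_epistasis(rils, y, ScanConfig.for_epistasis("RIL"))
            clean += len(pairs) == 0
        assert clean >= 5

    def test_fully_correlated_loci_skipped(self):
        rng = np.random.default_rng(43)
        col = rng.choice([0, 2], size=200)
        codes = np.column_stack([col, col])
        m = make_matrix(codes, ["c1", "c2"], [0.0, 0.0])
        y = pd.Series(rng.normal(size=200), index=m.line_ids)
        pairs = hq.scan_epistasis(m, y, ScanConfig.for_epistasis("RIL"))
        assert pairs.empty
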