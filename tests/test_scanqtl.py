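"""Haley-Knott scan machinery against explicit least-squares oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ailqtl import genoprob, scanqtl, simcross
from ailqtl.genoprob import calc_genoprob, genotype_scores
from ailqtl.scanqtl import (build_covariates, family_pcs, fit_multiqtl,
                            lod_interval, permutation_thresholds, power_detect,
                            scan_one, scan_two, merge_regions, ScanResult)


@pytest.fixture(scope="module")
def fixture20():
    """A 20-individual cross with one modest planted locus."""
    cfg = simcross.default_config(seed=42, n_final=20, n_probesets=0)
    cfg = simcross.SimConfig(**{**simcross.asdict_shallow(cfg),
                                "chrom_lengths_cm": (80.0, 60.0),
                                "markers_per_chrom": 5, "missing_rate": 0.02,
                                "traits": (simcross.TraitSpec("w42", 460.0, 60.0, 40.0),
                                           simcross.TraitSpec("w112", 1200.0, 150.0, 180.0)),
                                "trait_qtl": (simcross.QtlSpec("w112", "1", 40.0, a=80.0),),
                                "epistasis": (), "causal_genes": ()})
    study = simcross.simulate_study(cfg, with_expression=False)
    cross = study.cross
    gp = calc_genoprob(cross, step_cm=10.0)
    return cross, gp


def _oracle_lod(y, Z, xa, xd, extra=()):
    """Normal-equations least squares, independent of the scan path."""
    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)
    X0 = Z
    X1 = np.column_stack([Z, xa, xd, *extra])
    return 0.5 * len(y) * np.log10(rss(X0) / rss(X1))


class TestScanOneOracle:
    @pytest.mark.parametrize("trait", ["w42", "w112"])
    @pytest.mark.parametrize("sex_interaction", [False, True])
    def test_lod_matches_least_squares_oracle(self, fixture20, trait,
                                              sex_interaction):
        cross, gp = fixture20
        cov = build_covariates(cross)
        scan = scan_one(cross, gp, trait, cov, sex_interaction=sex_interaction,
                        min_n=10)
        ids = cross.pheno[trait].dropna().index
        y = cross.pheno.loc[ids, trait].to_numpy()
        Z = np.column_stack([np.ones(len(ids)),
                             cov.additive.loc[ids].to_numpy(float)])
        sex = cov.additive.loc[ids, "sex"].to_numpy()
        pos_of = gp.individuals.get_indexer(ids)
        x_a, x_d = genotype_scores(gp)
        for k in range(len(gp.grid)):
            xa, xd = x_a[pos_of, k], x_d[pos_of, k]
            extra = (sex * xa, sex * xd) if sex_interaction else ()
            expect = max(_oracle_lod(y, Z, xa, xd, extra), 0.0)
            assert scan.lod[k] == pytest.approx(expect, abs=1e-8)

    def test_missing_trait_dropped_listwise(self, fixture20):
        cross, gp = fixture20
        trait = "w42"
        n_obs = int(cross.pheno[trait].notna().sum())
        scan = scan_one(cross, gp, trait, min_n=5)
        assert scan.n == n_obs

    def test_too_few_individuals_raises(self, fixture20):
        cross, gp = fixture20
        with pytest.raises(ValueError, match="phenotyped"):
            scan_one(cross, gp, "w42", min_n=1000)


class TestPermutationThresholds:
    def test_alpha_one_is_minimum_of_null(self, fixture20):
        cross, gp = fixture20
        thr = permutation_thresholds(cross, gp, "w112", n_perm=100,
                                     alphas=(1.0,), seed=0)
        assert thr.thresholds[1.0] == pytest.approx(thr.null_max.min())

    def test_seed_reproducible(self, fixture20):
        cross, gp = fixture20
        t1 = permutation_thresholds(cross, gp, "w112", n_perm=120, seed=9)
        t2 = permutation_thresholds(cross, gp, "w112", n_perm=120, seed=9)
        np.testing.assert_array_equal(t1.null_max, t2.null_max)

    def test_significant_at_least_suggestive(self, fixture20):
        cross, gp = fixture20
        thr = permutation_thresholds(cross, gp, "w112", n_perm=200, seed=1)
        assert thr.significant >= thr.suggestive > 0

    def test_threshold_stable_across_seeds(self, small_cross):
        gp = calc_genoprob(small_cross, step_cm=5.0)
        vals = [permutation_thresholds(small_cross, gp, "w112", n_perm=1000,
                                       seed=s).significant for s in (1, 2)]
        assert abs(vals[0] - vals[1]) < 0.15

    def test_small_n_perm_rejected(self, fixture20):
        cross, gp = fixture20
        with pytest.raises(ValueError):
            permutation_thresholds(cross, gp, "w112", n_perm=50)


class TestScanTwoOracle:
    def test_five_statistics_match_direct_regression(self, fixture20):
        cross, gp = fixture20
        cov = build_covariates(cross)
        s2 = scan_two(cross, gp, "w112", cov, step_cm=25.0)
        ids = cross.pheno["w112"].dropna().index
        y = cross.pheno.loc[ids, "w112"].to_numpy()
        Z = np.column_stack([np.ones(len(ids)),
                             cov.additive.loc[ids].to_numpy(float)])
        pos_of = gp.individuals.get_indexer(ids)
        x_a, x_d = genotype_scores(gp)
        sel = [int(np.flatnonzero((gp.grid["name"] == nm).to_numpy())[0])
               for nm in s2.grid["name"]]

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        n = len(y)
        rss0 = rss(Z)
        for i in range(len(sel)):
            for j in range(i + 1, len(sel)):
                a1, d1 = x_a[pos_of, sel[i]], x_d[pos_of, sel[i]]
                a2, d2 = x_a[pos_of, sel[j]], x_d[pos_of, sel[j]]
                add = np.column_stack([Z, a1, d1, a2, d2])
                full = np.column_stack([add, a1 * a2, a1 * d2, d1 * a2, d1 * d2])
                lod_full = max(0.5 * n * np.log10(rss0 / rss(full)), 0.0)
                lod_add = max(0.5 * n * np.log10(rss0 / rss(add)), 0.0)
                assert s2.lod_full[i, j] == pytest.approx(lod_full, abs=1e-8)
                assert s2.lod_add[i, j] == pytest.approx(lod_add, abs=1e-8)
                assert s2.lod_int[i, j] == pytest.approx(lod_full - lod_add,
                                                         abs=1e-8)
                best1 = max(s2.lod_one[i], s2.lod_one[j])
                assert s2.lod_fv1[i, j] == pytest.approx(lod_full - best1,
                                                         abs=1e-8)
                assert s2.lod_av1[i, j] == pytest.approx(lod_add - best1,
                                                         abs=1e-8)

    def test_planted_epistatic_pair_yields_interaction_lod(self):
        """XOR-like pair with no marginal effect: interaction statistic large
        while single-locus scans stay flat."""
        cfg = simcross.default_config(seed=6, n_final=400, n_probesets=0)
        epi = simcross.EpistasisSpec("t", "1", 100.0, "2", 100.0, aa=80.0)
        cfg = simcross.SimConfig(**{**simcross.asdict_shallow(cfg),
                                    "chrom_lengths_cm": (200.0, 200.0),
                                    "markers_per_chrom": 5,
                                    "frac_partial": 0.0, "missing_rate": 0.0,
                                    "traits": (simcross.TraitSpec("t", 0.0, 30.0, 10.0),),
                                    "trait_qtl": (), "epistasis": (epi,),
                                    "causal_genes": ()})
        study = simcross.simulate_study(cfg, with_expression=False)
        gp = calc_genoprob(study.cross, step_cm=0.0)
        s1 = scan_one(study.cross, gp, "t")
        s2 = scan_two(study.cross, gp, "t", step_cm=25.0)
        assert s2.lod_int.max() > 7.0
        assert s2.lod_int.max() > s1.lod.max()

    def test_additive_pair_has_no_interaction_lod(self):
        cfg = simcross.default_config(seed=8, n_final=400, n_probesets=0)
        a = simcross.additive_effect_for_variance_fraction(0.15, 30.0)
        cfg = simcross.SimConfig(**{**simcross.asdict_shallow(cfg),
                                    "chrom_lengths_cm": (200.0, 200.0),
                                    "markers_per_chrom": 5,
                                    "frac_partial": 0.0, "missing_rate": 0.0,
                                    "traits": (simcross.TraitSpec("t", 0.0, 30.0, 0.0),),
                                    "trait_qtl": (simcross.QtlSpec("t", "1", 100.0, a=a),
                                                  simcross.QtlSpec("t", "2", 100.0, a=a)),
                                    "epistasis": (), "causal_genes": ()})
        study = simcross.simulate_study(cfg, with_expression=False)
        gp = calc_genoprob(study.cross, step_cm=0.0)
        s2 = scan_two(study.cross, gp, "t", step_cm=25.0)
        i, j = np.unravel_index(np.argmax(s2.lod_add), s2.lod_add.shape)
        assert s2.lod_av1[i, j] > 3.0
        # interaction statistic stays well under its declaration threshold
        assert s2.lod_int[i, j] < 4.0


class TestLodInterval:
    def _triangle_scan(self):
        grid = pd.DataFrame({"chrom": "1", "pos_cm": np.arange(11, dtype=float),
                             "name": [f"p{i}" for i in range(11)],
                             "is_marker": True})
        lod = np.array([0, 1, 2, 3, 4, 5, 4, 3, 2, 1, 0.0])
        return ScanResult(grid, lod, "t", 100, False, [])

    def test_triangular_curve_interval_by_hand(self, toy_cross):
        scan = self._triangle_scan()
        # LOD >= 5 - 1.8 = 3.2 holds on positions 4..6; expand one each side
        iv = lod_interval(scan, toy_cross, "1", drop=1.8)
        assert (iv.lo_cm, iv.peak_cm, iv.hi_cm) == (3.0, 5.0, 7.0)
        assert not iv.whole_chromosome

    def test_flat_curve_flags_whole_chromosome(self, toy_cross):
        grid = pd.DataFrame({"chrom": "1", "pos_cm": np.arange(5, dtype=float),
                             "name": [f"p{i}" for i in range(5)],
                             "is_marker": True})
        scan = ScanResult(grid, np.full(5, 4.0), "t", 100, False, [])
        iv = lod_interval(scan, toy_cross, "1")
        assert iv.whole_chromosome

    def test_wider_drop_nests_narrower(self, small_cross):
        gp = calc_genoprob(small_cross, step_cm=2.0)
        scan = scan_one(small_cross, gp, "w112")
        iv18 = lod_interval(scan, small_cross, "1", drop=1.8)
        iv30 = lod_interval(scan, small_cross, "1", drop=3.0)
        assert iv30.lo_cm <= iv18.lo_cm and iv30.hi_cm >= iv18.hi_cm

    def test_merge_regions_collapses_overlaps(self):
        ivals = pd.DataFrame({"chrom": ["1", "1", "1", "2"],
                              "lo_mb": [0.0, 1.5, 5.0, 0.0],
                              "hi_mb": [2.0, 3.0, 6.0, 1.0]})
        merged = merge_regions(ivals)
        assert len(merged) == 3
        assert merged.iloc[0]["n_members"] == 2


class TestFamilyPcs:
    def test_trait_equal_to_pc_is_retained(self, small_cross):
        from sklearn.decomposition import PCA
        x = small_cross.additive_coded_genotypes()
        scores = PCA(n_components=10, svd_solver="full").fit_transform(
            x.to_numpy() - x.to_numpy().mean(axis=0))
        rigged = small_cross.subset(small_cross.geno.index)
        rng = np.random.default_rng(0)
        rigged.pheno["fake"] = scores[:, 2] + rng.normal(
            0, 0.1 * scores[:, 2].std(), len(scores))
        pcs = family_pcs(rigged, "fake")
        assert "PC3" in pcs.columns

    def test_null_trait_retains_few_pcs(self):
        retained = 0
        for seed in range(10):
            cfg = simcross.default_config(seed=100 + seed, n_final=120,
                                          n_probesets=0)
            study = simcross.simulate_study(cfg, with_expression=False)
            cross = study.cross
            rng = np.random.default_rng(seed)
            cross.pheno["null"] = rng.normal(size=len(cross.pheno))
            retained += len(family_pcs(cross, "null").columns)
        # 10 PCs x 10 replicates at a 5% false-positive rate each
        assert retained <= 15

    def test_too_many_components_raises(self, fixture20):
        cross, _ = fixture20
        with pytest.raises(ValueError):
            family_pcs(cross, "w42", k=50)


class TestFitMultiqtl:
    def test_two_linked_qtl_separated(self):
        """Two strong loci 80 cM apart are both retained with distinct peaks."""
        cfg = simcross.default_config(seed=3, n_final=400, n_probesets=0)
        a = simcross.additive_effect_for_variance_fraction(0.18, 40.0)
        cfg = simcross.SimConfig(**{**simcross.asdict_shallow(cfg),
                                    "chrom_lengths_cm": (300.0,),
                                    "markers_per_chrom": 16,
                                    "frac_partial": 0.0, "missing_rate": 0.0,
                                    "traits": (simcross.TraitSpec("t", 0.0, 40.0, 10.0),),
                                    "trait_qtl": (simcross.QtlSpec("t", "1", 100.0, a=a),
                                                  simcross.QtlSpec("t", "1", 180.0, a=a)),
                                    "epistasis": (), "causal_genes": ()})
        study = simcross.simulate_study(cfg, with_expression=False)
        gp = calc_genoprob(study.cross, step_cm=2.0)
        scan = scan_one(study.cross, gp, "t")
        # candidates: the two local maxima around the planted loci
        cands = pd.DataFrame({"chrom": ["1", "1"], "pos_cm": [100.0, 180.0],
                              "lod": [scan.lod.max(), scan.lod.max() - 1]})
        fit = fit_multiqtl(study.cross, gp, "t", cands, drop_one_threshold=3.0)
        assert len(fit.loci) == 2
        assert abs(fit.loci["cm"].iloc[0] - fit.loci["cm"].iloc[1]) > 40.0

    def test_empty_candidates_raise(self, fixture20):
        cross, gp = fixture20
        with pytest.raises(ValueError):
            fit_multiqtl(cross, gp, "w112", pd.DataFrame(columns=["chrom", "pos_cm", "lod"]))

    def test_variance_explained_bounds(self, small_cross):
        gp = calc_genoprob(small_cross, step_cm=5.0)
        scan = scan_one(small_cross, gp, "w112")
        peaks = scan.chrom_peaks(3.5)
        fit = fit_multiqtl(small_cross, gp, "w112", peaks, drop_one_threshold=3.5)
        assert (fit.loci["var_explained_pct"] >= 0).all()
        assert fit.model_var_explained_pct <= 100.0


class TestPowerDetect:
    def test_zero_effect_limit_is_alpha_tail(self):
        thr = 3.0
        near_zero = power_detect(500, 1e-9, thr)
        assert near_zero == pytest.approx(
            stats.chi2.sf(2 * np.log(10) * thr, 2), rel=1e-3)

    def test_monotone_in_n_and_effect(self):
        p = [power_detect(n, 0.05, 4.0) for n in (100, 200, 400, 800)]
        assert np.all(np.diff(p) > 0)
        p = [power_detect(200, f, 4.0) for f in (0.02, 0.05, 0.1, 0.2)]
        assert np.all(np.diff(p) > 0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            power_detect(100, 0.0, 4.0)
        with pytest.raises(ValueError):
            power_detect(100, 1.0, 4.0)

    def test_matches_simulation_at_16pct_n130(self):
        """Monte-Carlo scan power at the planted locus vs the analytic value."""
        a16 = simcross.additive_effect_for_variance_fraction(0.16, 1.0)
        hits, reps = 0, 40
        for seed in range(reps):
            cfg = simcross.default_config(seed=seed)
            cfg = simcross.SimConfig(**{**simcross.asdict_shallow(cfg),
                                        "chrom_lengths_cm": (200.0,),
                                        "markers_per_chrom": 10,
                                        "n_final": 130, "n_probesets": 0,
                                        "traits": (simcross.TraitSpec("e", 0.0, 1.0, 0.0),),
                                        "trait_qtl": (simcross.QtlSpec("e", "1", 100.0, a=a16),),
                                        "epistasis": (), "causal_genes": ()})
            study = simcross.simulate_study(cfg, with_expression=False)
            gp = calc_genoprob(study.cross, step_cm=2.0)
            scan = scan_one(study.cross, gp, "e")
            w = (np.abs(gp.grid["pos_cm"] - 100.0) <= 50).to_numpy()
            hits += scan.lod[w].max() >= 4.0
        analytic = power_detect(130, 0.16, 4.0)
        se = np.sqrt(analytic * (1 - analytic) / reps)
        assert hits / reps == pytest.approx(analytic, abs=3 * se + 0.02)
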