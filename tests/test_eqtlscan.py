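"""Expression preprocessing and eQTL scanning."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from ailqtl import eqtlscan, genoprob, simcross
from ailqtl.eqtlscan import (adjust_batch, effect_direction_summary,
                             expression_cross, local_window_mask,
                             median_polish, median_polish_summarize,
                             quantile_normalize, scan_all_probesets,
                             scan_probeset, subsampled_thresholds)
from ailqtl.genoprob import calc_genoprob
from ailqtl.scanqtl import build_covariates


def _run_r(script: str) -> str:
    import tempfile
    with tempfile.NamedTemporaryFile("w", suffix=".R", delete=False) as fh:
        fh.write(script)
        path = fh.name
    out = subprocess.run(["Rscript", path], capture_output=True,
                         text=True, timeout=120)
    assert out.returncode == 0, out.stderr
    return out.stdout


class TestQuantileNormalize:
    def test_identically_distributed_columns_unchanged(self):
        col = np.array([1.0, 3.0, 2.0, 5.0])
        m = pd.DataFrame({"a": col, "b": col[::-1], "c": np.roll(col, 1)})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy())

    def test_hand_computed_3x3(self):
        # sorted columns: (1,2,3), (2,4,6), (0,3,9); row means (1, 3, 6)
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [2.0, 6.0, 4.0],
                          "c": [9.0, 0.0, 3.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["a"], [6.0, 1.0, 3.0])
        np.testing.assert_allclose(out["b"], [1.0, 6.0, 3.0])
        np.testing.assert_allclose(out["c"], [6.0, 1.0, 3.0])

    def test_sorted_columns_identical_after(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(50, 6)))
        out = quantile_normalize(m).to_numpy()
        s = np.sort(out, axis=0)
        np.testing.assert_allclose(s, s[:, [0]] @ np.ones((1, 6)), atol=1e-12)

    def test_matches_limma_oracle(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(20, 4)))
        csv = m.to_csv(index=False, header=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv(text='{csv.strip()}', header=FALSE))
            out <- normalizeQuantiles(x)
            write.csv(round(out, 10), row.names=FALSE)
        """)
        oracle = pd.read_csv(pd.io.common.StringIO(_run_r(script)))
        np.testing.assert_allclose(quantile_normalize(m).to_numpy(),
                                   oracle.to_numpy(), atol=1e-8)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestMedianPolish:
    def test_single_probe_identity(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p1"], columns=list("abc"))
        out = median_polish_summarize(m, pd.Series({"p1": "ps1"}))
        np.testing.assert_allclose(out.loc["ps1"], [1.0, 2.0, 3.0])

    def test_matches_r_medpolish_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3, 6))
        csv = pd.DataFrame(x).to_csv(index=False, header=False)
        script = textwrap.dedent(f"""
            x <- as.matrix(read.csv(text='{csv.strip()}', header=FALSE))
            mp <- medpolish(x, eps=1e-9, maxiter=50, trace.iter=FALSE)
            cat(mp$overall + mp$col, sep=',')
        """)
        expect = np.array([float(v) for v in _run_r(script).split(",")])
        overall, _, col, _ = median_polish(x, tol=1e-9, max_iter=50)
        np.testing.assert_allclose(overall + col, expect, atol=1e-6)

    def test_sample_shift_equivariance(self):
        rng = np.random.default_rng(7)
        probes = pd.DataFrame(rng.normal(size=(3, 5)),
                              index=["p1", "p2", "p3"])
        groups = pd.Series("ps1", index=probes.index)
        base = median_polish_summarize(probes, groups)
        shifted = probes.copy()
        shifted[2] = shifted[2] + 1.5
        out = median_polish_summarize(shifted, groups)
        # equivariance is exact up to median re-splits on small matrices
        np.testing.assert_allclose(out.loc["ps1", 2] - base.loc["ps1", 2], 1.5,
                                   atol=0.05)
        np.testing.assert_allclose(out.loc["ps1"].drop(2),
                                   base.loc["ps1"].drop(2), atol=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_polish_summarize(pd.DataFrame(), pd.Series(dtype=object))


class TestAdjustBatch:
    def _toy(self, offset):
        rng = np.random.default_rng(11)
        X = rng.normal(8.0, 1.0, size=(40, 24))
        batch = pd.Series(["x"] * 12 + ["y"] * 12,
                          index=[f"s{i}" for i in range(24)])
        X[:, 12:] += offset
        return pd.DataFrame(X, columns=batch.index), batch

    def test_identical_batches_nearly_unchanged(self):
        m, batch = self._toy(0.0)
        out = adjust_batch(m, batch)
        assert np.abs(out.to_numpy() - m.to_numpy()).mean() < 0.25

    def test_planted_offset_removed(self):
        m, batch = self._toy(2.0)
        out = adjust_batch(m, batch)

        def mean_gap(df):
            return float(np.abs(df.loc[:, batch == "y"].mean(axis=1)
                                - df.loc[:, batch == "x"].mean(axis=1)).mean())

        assert mean_gap(out) < 0.2 * mean_gap(m)
        # overall gene means approximately preserved
        np.testing.assert_allclose(out.mean(axis=1), m.mean(axis=1), atol=0.3)

    def test_matches_sva_combat_oracle(self):
        m, batch = self._toy(1.0)
        csv = m.to_csv(index=False, header=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(sva))
            x <- as.matrix(read.csv(text='{csv.strip()}', header=FALSE))
            b <- c(rep('x', 12), rep('y', 12))
            sink(tempfile())           # ComBat chatters on stdout
            out <- ComBat(dat=x, batch=b)
            sink()
            write.csv(round(out, 8), row.names=FALSE)
        """)
        oracle = pd.read_csv(pd.io.common.StringIO(_run_r(script)))
        ours = adjust_batch(m, batch)
        # implementations differ only in EB convergence criteria
        np.testing.assert_allclose(ours.to_numpy(), oracle.to_numpy(), atol=0.01)

    def test_single_sample_batch_rejected(self):
        m, batch = self._toy(0.0)
        batch.iloc[-1] = "z"
        with pytest.raises(ValueError, match="single-sample"):
            adjust_batch(m, batch)


@pytest.fixture(scope="module")
def escan(small_study):
    cross = small_study.cross
    expression = small_study.expression
    ecross = expression_cross(cross, expression, small_study.expr_covar)
    gp = calc_genoprob(ecross, step_cm=2.0)
    cov = build_covariates(ecross, include_dye=True)
    return small_study, ecross, gp, cov


class TestScanProbeset:
    def test_planted_local_eqtl_detected_in_window(self, escan):
        study, ecross, gp, cov = escan
        truth = study.truth["eqtl"]
        local = truth[truth["kind"] == "local"]
        hits = 0
        for ps in local["probeset"].iloc[:30]:
            recs = scan_probeset(ps, ecross, gp, study.annotation, cov,
                                 local_threshold=4.0, trans_threshold=8.0)
            hits += any(r.kind == "local" for r in recs)
        # ~76-80% per-probeset power at a 16% effect, n=130 (binomial slack)
        assert hits >= 18

    def test_local_peak_within_window(self, escan):
        study, ecross, gp, cov = escan
        truth = study.truth["eqtl"]
        for ps in truth[truth["kind"] == "local"]["probeset"].iloc[:20]:
            for r in scan_probeset(ps, ecross, gp, study.annotation, cov, 4.0, 8.0):
                if r.kind == "local":
                    gene_cm = study.annotation.loc[ps, "cm"]
                    assert r.chrom == str(study.annotation.loc[ps, "chrom"])
                    assert abs(r.peak_cm - gene_cm) <= 50.0 + 1e-9

    def test_window_clipped_at_chromosome_start(self, escan):
        study, ecross, gp, cov = escan
        mask = local_window_mask(gp.grid, "1", 0.0, 50.0)
        pos = gp.grid["pos_cm"].to_numpy()[mask]
        assert pos.min() >= 0.0 and pos.max() <= 50.0 + 1e-9

    def test_unannotated_probeset_scanned_distally_genome_wide(self, escan):
        study, ecross, gp, cov = escan
        ann_without = study.annotation.drop(index=["ps0201"])
        recs = scan_probeset("ps0201", ecross, gp, ann_without, cov, 4.0, 6.0)
        assert all(r.kind == "distal" for r in recs)
        assert len(recs) >= 1      # planted trans effect found somewhere

    def test_class_count_filter_drops_skewed_peaks(self, escan):
        study, ecross, gp, cov = escan
        truth = study.truth["eqtl"]
        trans = truth[truth["kind"] == "trans"]["probeset"]
        kept, dropped = 0, 0
        for ps in trans:
            recs = scan_probeset(ps, ecross, gp, study.annotation, cov, 4.0, 6.0,
                                 min_class=10)
            loose = scan_probeset(ps, ecross, gp, study.annotation, cov, 4.0, 6.0,
                                  min_class=0)
            kept += len(recs)
            dropped += len(loose) - len(recs)
        assert kept > 0
        # every kept distal record satisfies the filter
        for ps in trans.iloc[:10]:
            for r in scan_probeset(ps, ecross, gp, study.annotation, cov,
                                   4.0, 6.0, min_class=10):
                if r.kind == "distal":
                    assert min(r.class_counts.values()) > 10


class TestSubsampledThresholds:
    def test_trans_exceeds_local_and_reasonable_range(self, escan):
        study, ecross, gp, cov = escan
        thr = subsampled_thresholds(study.cross, study.expression,
                                    study.expr_covar, gp, study.annotation,
                                    n_probesets=60, n_reps=80, seed=4)
        assert thr.trans > thr.local > 0

    def test_seed_reproducible(self, escan):
        study, ecross, gp, cov = escan
        a = subsampled_thresholds(study.cross, study.expression,
                                  study.expr_covar, gp, study.annotation,
                                  n_probesets=40, n_reps=60, seed=9)
        b = subsampled_thresholds(study.cross, study.expression,
                                  study.expr_covar, gp, study.annotation,
                                  n_probesets=40, n_reps=60, seed=9)
        assert a.local == b.local and a.trans == b.trans

    def test_insufficient_probesets_rejected(self, escan):
        study, ecross, gp, cov = escan
        with pytest.raises(ValueError):
            subsampled_thresholds(study.cross, study.expression.iloc[:10],
                                  study.expr_covar, gp, study.annotation,
                                  n_probesets=100, n_reps=60, seed=0)


class TestEffectDirections:
    def test_empty_input_gives_empty_summary(self):
        out = effect_direction_summary([])
        assert out.empty

    def test_symmetric_effects_balanced(self, escan):
        study, ecross, gp, cov = escan
        records = scan_all_probesets(study.cross, study.expression,
                                     study.expr_covar, gp, study.annotation,
                                     4.0, 8.0)
        out = effect_direction_summary(records)
        add = out[(out["effect"] == "additive") & (out["kind"] == "local")]
        # additive signs drawn symmetrically -> proportions not extreme
        for _, row in add.iterrows():
            if row["n"] >= 20:
                assert 0.25 < row["prop_positive"] < 0.75

    def test_planted_negative_dominance_skews_summary(self):
        cfg = simcross.default_config(seed=31, n_final=150, n_probesets=650,
                                      n_expr_individuals=120)
        a16 = simcross.additive_effect_for_variance_fraction(0.16, 1.0)
        eqtl = tuple(simcross.EqtlSpec(f"ps{k + 1:04d}", "local", "1",
                                       10.0 * (k + 1), a=a16, d=-1.2 * a16)
                     for k in range(20))
        cfg = simcross.SimConfig(**{**simcross.asdict_shallow(cfg),
                                    "eqtl": eqtl, "hotspots": (),
                                    "causal_genes": ()})
        study = simcross.simulate_study(cfg)
        ecross = expression_cross(study.cross, study.expression,
                                  study.expr_covar)
        gp = calc_genoprob(ecross, step_cm=2.0)
        records = scan_all_probesets(study.cross, study.expression,
                                     study.expr_covar, gp, study.annotation,
                                     4.0, 8.0)
        out = effect_direction_summary([r for r in records if r.kind == "local"])
        dom = out[out["effect"] == "dominance"]
        assert (dom["n_negative"] > dom["n_positive"]).all()
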