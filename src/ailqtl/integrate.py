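"""QTL x eQTL integration: candidate genes, transcriptome-wide trait
association, and selective-sweep overlap testing.

A gene is a candidate quantitative trait gene for a QTL when (1) its local
eQTL confidence interval overlaps the QTL's support interval (half-open Mb
semantics) and (2) its expression level is associated with the trait in a
linear model with dye and batch as covariates (plus an
expression-by-sex interaction when the eQTL itself showed one). The same
linear model, applied across the whole array with a max-statistic
permutation test, yields transcriptome-wide trait-associated probesets
with family-wise error control. Finally, externally supplied selective
sweep intervals are tested for enrichment in QTL support intervals against
an empirical null that re-places the sweeps uniformly within their
chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossio import Cross


def intervals_overlap(lo1, hi1, lo2, hi2) -> bool:
    """Half-open [lo, hi) overlap (vectorizable)."""
    return (lo1 < hi2) & (lo2 < hi1)


# ---------------------------------------------------------------------------
# candidate genes


@dataclass
class CandidateGene:
    gene: str
    probeset: str
    trait: str
    qtl_chrom: str
    qtl_lo_mb: float
    qtl_hi_mb: float
    eqtl_lod: float
    eqtl_lo_mb: float
    eqtl_hi_mb: float
    p_value: float
    p_value_sex_interaction: float
    sex_interaction: bool


def _association_pvalues(y: np.ndarray, expr: np.ndarray, covar: pd.DataFrame):
    """p-values for expression in trait ~ expression + dye + batch, with and
    without an expression-by-sex interaction (joint F-test when interacting)."""
    import statsmodels.api as sm

    dummies = pd.get_dummies(covar["batch"].astype(str), prefix="batch",
                             drop_first=True, dtype=float)
    cols = [np.ones(len(y))]
    if "dye" in covar.columns:
        dyes = sorted(covar["dye"].astype(str).unique())
        if len(dyes) > 1:
            cols.append(covar["dye"].astype(str).map(
                {dyes[0]: -1.0, dyes[1]: 1.0}).to_numpy())
    cols.append(dummies.to_numpy())
    Z = np.column_stack(cols)
    sex = covar["sex"].astype(str).map({"male": 1.0, "female": -1.0}).to_numpy()

    fit_plain = sm.OLS(y, np.column_stack([Z, expr])).fit()
    p_plain = float(fit_plain.pvalues[-1])
    X_sex = np.column_stack([Z, sex, expr, expr * sex])
    fit_sex = sm.OLS(y, X_sex).fit()
    k = X_sex.shape[1]
    contrast = np.zeros((2, k))
    contrast[0, k - 2] = 1.0
    contrast[1, k - 1] = 1.0
    p_sex = float(fit_sex.f_test(contrast).pvalue)
    return p_plain, p_sex


def candidate_screen(qtl_intervals: pd.DataFrame, eqtl_table: pd.DataFrame,
                     expression: pd.DataFrame, expr_covar: pd.DataFrame,
                     cross: Cross, annotation: pd.DataFrame | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Candidate quantitative trait genes from QTL x local-eQTL overlap.

    ``qtl_intervals`` needs columns trait, chrom, lo_mb, hi_mb;
    ``eqtl_table`` is the local-eQTL table (columns probeset, chrom,
    ci_lo_mb, ci_hi_mb, lod, sex_interaction). The association model is
    trait ~ expression + dye + batch, with the expression-by-sex interaction
    folded in (joint F-test) when the eQTL record carries one. Output order
    is canonical (trait, then probeset), so input ordering is irrelevant.
    """
    ids = [i for i in expression.columns if i in cross.pheno.index]
    if not ids:
        raise ValueError("expression individuals disjoint from phenotyped ones")
    rows = []
    local = eqtl_table[eqtl_table["kind"] == "local"] if "kind" in eqtl_table \
        else eqtl_table
    for _, q in qtl_intervals.iterrows():
        hits = local[(local["chrom"].astype(str) == str(q["chrom"]))
                     & (local["ci_lo_mb"] < q["hi_mb"])
                     & (local["ci_hi_mb"] > q["lo_mb"])]
        for _, e in hits.iterrows():
            y = cross.pheno.loc[ids, q["trait"]].to_numpy(float)
            keep = np.isfinite(y)
            expr = expression.loc[e["probeset"], ids].to_numpy(float)[keep]
            p_plain, p_sex = _association_pvalues(
                y[keep], expr, expr_covar.loc[np.array(ids)[keep]])
            use_sex = bool(e.get("sex_interaction", False))
            p_used = p_sex if use_sex else p_plain
            if p_used < alpha:
                gene = ""
                if annotation is not None and e["probeset"] in annotation.index:
                    gene = str(annotation.loc[e["probeset"], "gene"])
                rows.append(dict(gene=gene, probeset=e["probeset"],
                                 trait=q["trait"], qtl_chrom=str(q["chrom"]),
                                 qtl_lo_mb=q["lo_mb"], qtl_hi_mb=q["hi_mb"],
                                 eqtl_lod=e["lod"], eqtl_lo_mb=e["ci_lo_mb"],
                                 eqtl_hi_mb=e["ci_hi_mb"], p_value=p_plain,
                                 p_value_sex_interaction=p_sex,
                                 sex_interaction=use_sex))
    out = pd.DataFrame(rows, columns=["gene", "probeset", "trait", "qtl_chrom",
                                      "qtl_lo_mb", "qtl_hi_mb", "eqtl_lod",
                                      "eqtl_lo_mb", "eqtl_hi_mb", "p_value",
                                      "p_value_sex_interaction",
                                      "sex_interaction"])
    return out.sort_values(["trait", "probeset"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# transcriptome-wide association


def transcriptome_wide_association(expression: pd.DataFrame, traits: pd.DataFrame,
                                   covar: pd.DataFrame, n_perm: int = 1000,
                                   seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Trait-associated probesets with a max-statistic permutation FWER test.

    For each trait, expression and trait are residualized on the technical
    covariates (dye, batch); the statistic per probeset is the squared
    residual correlation. Permuting trait values and taking the maximum
    statistic across the array per permutation gives the family-wise null;
    probesets above its (1 - alpha) quantile are reported with an empirical
    family-wise p-value.
    """
    if n_perm < 20:
        raise ValueError("n_perm too small")
    ids = [i for i in expression.columns if i in traits.index]
    covar = covar.loc[ids]
    cols = [np.ones(len(ids))]
    if "dye" in covar.columns:
        dyes = sorted(covar["dye"].astype(str).unique())
        if len(dyes) > 1:
            cols.append(covar["dye"].astype(str).map(
                {dyes[0]: -1.0, dyes[1]: 1.0}).to_numpy())
    cols.append(pd.get_dummies(covar["batch"].astype(str), prefix="b",
                               drop_first=True, dtype=float).to_numpy())
    Z = np.column_stack(cols)
    from .scanqtl import _ols_basis
    Q = _ols_basis(Z)

    X = expression[ids].to_numpy(float)
    Xr = X - (X @ Q) @ Q.T
    Xr /= np.maximum(np.linalg.norm(Xr, axis=1, keepdims=True), 1e-12)
    rng = np.random.default_rng(seed)
    rows = []
    for trait in traits.columns:
        y = traits.loc[ids, trait].to_numpy(float)
        keep = np.isfinite(y)
        if keep.sum() < 10 or np.nanstd(y) == 0:
            continue
        yk = y[keep]
        Qk = _ols_basis(Z[keep])
        Xk = X[:, keep]
        Xkr = Xk - (Xk @ Qk) @ Qk.T
        Xkr /= np.maximum(np.linalg.norm(Xkr, axis=1, keepdims=True), 1e-12)

        def stat(yv):
            yr = yv - Qk @ (Qk.T @ yv)
            norm = np.linalg.norm(yr)
            if norm < 1e-12:
                return np.zeros(Xkr.shape[0])
            return np.abs(Xkr @ (yr / norm))

        obs = stat(yk)
        perm_max = np.empty(n_perm)
        for p in range(n_perm):
            perm_max[p] = stat(yk[rng.permutation(len(yk))]).max()
        cutoff = np.quantile(perm_max, 1.0 - alpha)
        for i in np.flatnonzero(obs > cutoff):
            fwer_p = float((np.sum(perm_max >= obs[i]) + 1) / (n_perm + 1))
            rows.append(dict(trait=trait, probeset=expression.index[i],
                             abs_correlation=float(obs[i]), fwer_p=fwer_p))
    return pd.DataFrame(rows, columns=["trait", "probeset", "abs_correlation",
                                       "fwer_p"])


# ---------------------------------------------------------------------------
# selective-sweep overlap


@dataclass
class SweepOverlapResult:
    trait: str
    observed: int
    null_mean: float
    null_q95: float
    empirical_p: float
    n_sim: int


def count_overlaps(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Number of overlapping (row of a, row of b) pairs; half-open Mb."""
    n = 0
    for _, x in a.iterrows():
        same = b["chrom"].astype(str) == str(x["chrom"])
        n += int((intervals_overlap(x["lo_mb"], x["hi_mb"],
                                    b.loc[same, "lo_mb"],
                                    b.loc[same, "hi_mb"])).sum())
    return n


def sweep_overlap_test(qtl_intervals: pd.DataFrame, sweeps: pd.DataFrame,
                       chrom_lengths_mb: dict, n_sim: int = 1000,
                       seed: int = 0, trait: str = "all") -> SweepOverlapResult:
    """Empirical enrichment test of sweeps inside QTL support intervals.

    Observed = number of (QTL, sweep) overlapping pairs. The null keeps
    each sweep's length and chromosome and redraws its start uniformly in
    [0, chrom_length - length], ``n_sim`` times; the empirical p-value is
    the fraction of null replicates with at least the observed count.
    """
    rng = np.random.default_rng(seed)
    sweeps = sweeps.copy()
    sweeps["chrom"] = sweeps["chrom"].astype(str)
    lengths = (sweeps["hi_mb"] - sweeps["lo_mb"]).to_numpy(float)
    chrom_len = np.array([chrom_lengths_mb[c] for c in sweeps["chrom"]])
    if (lengths > chrom_len).any():
        raise ValueError("sweep longer than its chromosome")
    observed = count_overlaps(qtl_intervals, sweeps)

    # vectorized null: per sweep, per sim, random start on its chromosome
    q_by_chrom = {c: (sub["lo_mb"].to_numpy(), sub["hi_mb"].to_numpy())
                  for c, sub in qtl_intervals.groupby(
                      qtl_intervals["chrom"].astype(str))}
    null = np.zeros(n_sim, dtype=int)
    for j in range(len(sweeps)):
        c = sweeps["chrom"].iloc[j]
        if c not in q_by_chrom:
            continue
        qlo, qhi = q_by_chrom[c]
        starts = rng.uniform(0.0, chrom_len[j] - lengths[j], size=n_sim)
        ends = starts + lengths[j]
        null += ((starts[:, None] < qhi[None, :])
                 & (qlo[None, :] < ends[:, None])).sum(axis=1)
    p = float((null >= observed).mean())
    return SweepOverlapResult(trait, observed, float(null.mean()),
                              float(np.quantile(null, 0.95)), p, n_sim)
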