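"""Expression preprocessing and local/distal eQTL mapping.

Probe-level intensities are quantile-normalized, summarized to probesets by
Tukey median polish, and batch-adjusted with ComBat (parametric
empirical-Bayes, via scanpy). Each annotated probeset is then scanned for a
local eQTL inside a +/-50 cM window around the gene (distances on the
expanded final-generation map) and genome-wide outside it for distal
(trans) eQTL, with sex, batch and fluorophore (dye) as covariates and a
genotype-by-sex interaction kept when it improves the model LOD by more
than 1. Distal candidates with ten or fewer individuals in any observed
genotype class at the peak marker are discarded (skewed-genotype filter).

Significance thresholds use subsampled-probeset permutations: each
replicate permutes individual labels once and records the maximum LOD over
100 randomly drawn probesets — within local windows for the local null,
genome-wide for the trans null — so the thresholds account for the size of
the probeset family, not a single phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crossio import Cross, GENO_AA, GENO_AB, GENO_BB
from .genoprob import GenotypeProbabilities, genotype_scores
from . import scanqtl
from .scanqtl import CovariateSet, build_covariates, _ols_basis, _geno_design, \
    _batched_fit_rss

LOCAL_WINDOW_CM = 50.0      # each side of the gene
MIN_CLASS_COUNT = 10        # "ten or fewer" individuals in a class -> drop
SEX_DELTA_LOD = 1.0


# ---------------------------------------------------------------------------
# preprocessing


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column (sample) onto the common empirical distribution.

    The target distribution is the row-wise mean of the column-sorted
    values; tied values receive the mean of the quantiles they span
    (rank-average interpolation).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    X = matrix.to_numpy(float)
    if np.isnan(X).all(axis=0).any():
        raise ValueError("all-missing column")
    n = X.shape[0]
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    ranks_axis = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        r = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(r, ranks_axis, target)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish(x: np.ndarray, tol: float = 1e-6, max_iter: int = 10):
    """Tukey's median polish: x ~ overall + row + col + residual.

    Returns (overall, row_effects, col_effects, residuals).
    """
    resid = np.asarray(x, dtype=float).copy()
    nr, nc = resid.shape
    row = np.zeros(nr)
    col = np.zeros(nc)
    overall = 0.0
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        cmed_of_row = np.median(col)
        overall += cmed_of_row
        col -= cmed_of_row
        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col += cmed
        rmed_of_col = np.median(row)
        overall += rmed_of_col
        row -= rmed_of_col
        if np.abs(rmed).max(initial=0.0) < tol and np.abs(cmed).max(initial=0.0) < tol:
            break
    return overall, row, col, resid


def median_polish_summarize(probe_matrix: pd.DataFrame,
                            probeset_of: pd.Series) -> pd.DataFrame:
    """Summarize probe-level rows to one value per probeset per sample.

    ``probeset_of`` maps probe ids (the matrix index) to probeset ids. The
    probeset value for a sample is overall + column (sample) effect from the
    median polish of that probeset's probes; single-probe probesets pass
    through unchanged.
    """
    if probe_matrix.empty:
        raise ValueError("empty probe matrix")
    groups = probeset_of.loc[probe_matrix.index]
    rows = {}
    for ps, probes in groups.groupby(groups).groups.items():
        sub = probe_matrix.loc[probes].to_numpy(float)
        if sub.shape[0] == 1:
            rows[ps] = sub[0]
        else:
            overall, _, col, _ = median_polish(sub)
            rows[ps] = overall + col
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=probe_matrix.columns)
    out.index.name = "probeset"
    return out.sort_index()


def adjust_batch(matrix: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """ComBat batch adjustment (parametric empirical Bayes), genes x samples.

    Location/scale batch parameters per gene are shrunk toward their
    across-gene priors and removed; overall gene means are preserved.
    Delegates to scanpy's ComBat implementation.
    """
    import anndata as ad
    import scanpy as sc

    batch = batch.loc[matrix.columns].astype(str)
    counts = batch.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 batches")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"single-sample batch(es): {bad}")
    adata = ad.AnnData(matrix.to_numpy(float).T.copy())
    adata.obs["batch"] = batch.to_numpy()
    sc.pp.combat(adata, key="batch")
    return pd.DataFrame(adata.X.T, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# eQTL scanning


@dataclass
class EqtlRecord:
    """One significant expression QTL."""
    probeset: str
    kind: str                 # "local" | "distal"
    chrom: str
    peak_cm: float
    peak_mb: float | None
    lod: float
    ci_lo_cm: float
    ci_hi_cm: float
    ci_lo_mb: float | None
    ci_hi_mb: float | None
    sex_interaction: bool
    a: float
    d: float
    a_by_sex: float
    d_by_sex: float
    class_counts: dict

    @property
    def a_male(self) -> float:
        return self.a + self.a_by_sex

    @property
    def a_female(self) -> float:
        return self.a - self.a_by_sex

    @property
    def d_male(self) -> float:
        return self.d + self.d_by_sex

    @property
    def d_female(self) -> float:
        return self.d - self.d_by_sex


def records_to_frame(records: list[EqtlRecord]) -> pd.DataFrame:
    cols = ["probeset", "kind", "chrom", "peak_cm", "peak_mb", "lod",
            "ci_lo_cm", "ci_hi_cm", "ci_lo_mb", "ci_hi_mb", "sex_interaction",
            "a", "d", "a_by_sex", "d_by_sex", "min_class_count"]
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in cols[:-1]}
        row["min_class_count"] = min(r.class_counts.values()) if r.class_counts else 0
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def expression_cross(cross: Cross, expression: pd.DataFrame,
                     expr_covar: pd.DataFrame) -> Cross:
    """A Cross whose phenotypes are the expression profiles (for HK scans)."""
    ids = expression.columns
    return Cross(cross.gmap, cross.geno.loc[ids].copy(), expression.T.copy(),
                 expr_covar.loc[ids].copy(), dict(cross.metadata))


def gene_position_cm(annotation_row: pd.Series, gmap) -> tuple[str, float]:
    chrom = str(annotation_row["chrom"])
    if "cm" in annotation_row and np.isfinite(annotation_row.get("cm", np.nan)):
        return chrom, float(annotation_row["cm"])
    return chrom, float(gmap.mb_to_cm(chrom, float(annotation_row["mb"])))


def local_window_mask(grid: pd.DataFrame, chrom: str, gene_cm: float,
                      window_cm: float = LOCAL_WINDOW_CM) -> np.ndarray:
    """Boolean mask of grid positions within +/-window of the gene (clipped
    at chromosome ends by construction of the grid)."""
    pos = grid["pos_cm"].to_numpy()
    return ((grid["chrom"] == str(chrom)).to_numpy()
            & (np.abs(pos - gene_cm) <= window_cm + 1e-9))


def _class_counts_at(cross: Cross, ids, chrom: str, cm: float) -> dict:
    sub = cross.gmap.chrom_markers(chrom)
    marker = sub.index[int(np.argmin(np.abs(sub["cm"].to_numpy() - cm)))]
    codes = cross.geno.loc[ids, marker]
    return {"AA": int((codes == GENO_AA).sum()),
            "AB": int((codes == GENO_AB).sum()),
            "BB": int((codes == GENO_BB).sum())}


def _record_from_peak(probeset, kind, ecross, scan, mask, threshold, cross_for_ci,
                      delta_scan=None):
    lod_masked = np.where(mask, scan.lod, -np.inf)
    k = int(np.argmax(lod_masked))
    lod = float(lod_masked[k])
    if lod < threshold:
        return None
    chrom = scan.grid["chrom"].iloc[k]
    cm = float(scan.grid["pos_cm"].iloc[k])
    # sex-interaction decision at the peak
    sex_flag = (delta_scan is not None
                and delta_scan.lod[k] - scan.lod[k] > SEX_DELTA_LOD)
    use_scan = delta_scan if sex_flag else scan
    if sex_flag:
        lod = float(delta_scan.lod[k])
    ci = _window_interval(use_scan, mask, k, cross_for_ci)
    eff = scanqtl.fit_position(use_scan, k)

    def get(nm: str) -> float:
        return float(eff.loc[nm, "estimate"]) if nm in eff.index else 0.0
    try:
        peak_mb = ecross.gmap.cm_to_mb(chrom, cm)
    except ValueError:
        peak_mb = None
    return EqtlRecord(probeset, kind, chrom, cm, peak_mb, lod,
                      ci["lo_cm"], ci["hi_cm"], ci["lo_mb"], ci["hi_mb"],
                      sex_flag, get("a"), get("d"), get("a_by_sex"),
                      get("d_by_sex"),
                      _class_counts_at(ecross, ecross.geno.index, chrom, cm))


def _window_interval(scan, mask, k, cross, drop: float = 1.8) -> dict:
    """1.8-LOD drop interval restricted to the masked (window) positions."""
    chrom = scan.grid["chrom"].iloc[k]
    on_chrom = (scan.grid["chrom"] == chrom).to_numpy() & mask
    idx = np.flatnonzero(on_chrom)
    lod = scan.lod[idx]
    pos = scan.grid["pos_cm"].to_numpy()[idx]
    kk = int(np.flatnonzero(idx == k)[0])
    cutoff = lod[kk] - drop
    lo = kk
    while lo > 0 and lod[lo - 1] >= cutoff:
        lo -= 1
    hi = kk
    while hi < len(lod) - 1 and lod[hi + 1] >= cutoff:
        hi += 1
    lo = max(lo - 1, 0)
    hi = min(hi + 1, len(lod) - 1)
    out = {"lo_cm": float(pos[lo]), "hi_cm": float(pos[hi])}
    try:
        out["lo_mb"] = cross.gmap.cm_to_mb(chrom, out["lo_cm"])
        out["hi_mb"] = cross.gmap.cm_to_mb(chrom, out["hi_cm"])
    except ValueError:
        out["lo_mb"] = out["hi_mb"] = None
    return out


def scan_probeset(probeset: str, ecross: Cross, gp: GenotypeProbabilities,
                  annotation: pd.DataFrame, covariates: CovariateSet,
                  local_threshold: float, trans_threshold: float,
                  window_cm: float = LOCAL_WINDOW_CM,
                  min_class: int = MIN_CLASS_COUNT,
                  exclude_window_for_trans: bool = True,
                  _scans: tuple | None = None) -> list[EqtlRecord]:
    """Local and distal scans for one probeset; returns significant records.

    The local scan is restricted to the +/-window around the annotated gene
    position; distal peaks are per-chromosome maxima outside that window at
    or above the trans threshold, subject to the genotype-class-count
    filter. Unannotated probesets are scanned genome-wide, all hits distal.
    """
    if _scans is not None:
        base, sexs = _scans
    else:
        base = scanqtl.scan_one(ecross, gp, probeset, covariates,
                                sex_interaction=False, min_n=2)
        sexs = scanqtl.scan_one(ecross, gp, probeset, covariates,
                                sex_interaction=True, min_n=2)
    records = []
    annotated = probeset in annotation.index and \
        str(annotation.loc[probeset, "chrom"]) in set(gp.grid["chrom"])
    wmask = np.zeros(len(gp.grid), dtype=bool)
    if annotated:
        chrom, gene_cm = gene_position_cm(annotation.loc[probeset], ecross.gmap)
        wmask = local_window_mask(gp.grid, chrom, gene_cm, window_cm)
        if not wmask.any():
            raise ValueError(f"local window for {probeset} contains no grid positions")
        rec = _record_from_peak(probeset, "local", ecross, base, wmask,
                                local_threshold, ecross, delta_scan=sexs)
        if rec is not None:
            records.append(rec)

    distal_mask = ~wmask if (annotated and exclude_window_for_trans) \
        else np.ones(len(gp.grid), dtype=bool)
    for chrom in dict.fromkeys(gp.grid["chrom"]):
        cmask = distal_mask & (gp.grid["chrom"] == chrom).to_numpy()
        if not cmask.any():
            continue
        rec = _record_from_peak(probeset, "distal", ecross, base, cmask,
                                trans_threshold, ecross, delta_scan=sexs)
        if rec is not None:
            if min(rec.class_counts.values()) <= min_class:
                continue     # skewed genotype classes at the peak
            records.append(rec)
    return records


def _lod_matrix(ecross: Cross, gp: GenotypeProbabilities,
                covariates: CovariateSet, sex_interaction: bool) -> tuple:
    """LOD for every (grid position, probeset) in one batched computation.

    Returns (lod (L, P), context pieces shared by all probesets). Expression
    phenotypes have no missing values, so all probesets share one design.
    """
    ids = ecross.geno.index
    n = len(ids)
    Y = ecross.pheno.loc[ids].to_numpy(float)            # (n, P)
    Z = np.column_stack([np.ones(n), covariates.additive.loc[ids].to_numpy(float)])
    sex = covariates.interactive.loc[ids, "sex"].to_numpy(float)
    Q0 = _ols_basis(Z)
    pos_of = gp.individuals.get_indexer(ids)
    x_a, x_d = genotype_scores(gp)
    x_a, x_d = x_a[pos_of], x_d[pos_of]
    G = _geno_design(x_a, x_d, sex, sex_interaction)
    Gr = G - np.einsum("nj,jm,lmk->lnk", Q0, Q0.T, G, optimize=True)
    Q, mask = scanqtl._batched_basis(Gr)
    Yr = Y - Q0 @ (Q0.T @ Y)
    rss0 = np.einsum("np,np->p", Yr, Yr)
    B = np.einsum("lnk,np->lkp", Q, Yr) * mask[:, :, None]
    rss1 = np.maximum(rss0[None, :] - np.einsum("lkp,lkp->lp", B, B), 1e-12)
    lod = np.maximum(0.5 * n * np.log10(rss0[None, :] / rss1), 0.0)
    ctx = dict(ids=ids, Y=Y, Z=Z, sex=sex, x_a=x_a, x_d=x_d, rss0=rss0)
    return lod, ctx


def scan_all_probesets(cross: Cross, expression: pd.DataFrame,
                       expr_covar: pd.DataFrame, gp_expr: GenotypeProbabilities,
                       annotation: pd.DataFrame, local_threshold: float,
                       trans_threshold: float, **kwargs) -> list[EqtlRecord]:
    """Run scan_probeset over a whole expression matrix (batched LODs)."""
    ecross = expression_cross(cross, expression, expr_covar)
    covariates = build_covariates(ecross, include_dye=True)
    lod_base, ctx = _lod_matrix(ecross, gp_expr, covariates, False)
    lod_sex, _ = _lod_matrix(ecross, gp_expr, covariates, True)
    records = []
    for c, probeset in enumerate(expression.index):
        pctx = dict(ctx, y=ctx["Y"][:, c])
        base = scanqtl.ScanResult(gp_expr.grid, lod_base[:, c], probeset,
                                  len(pctx["y"]), False,
                                  list(covariates.additive.columns), pctx)
        sexs = scanqtl.ScanResult(gp_expr.grid, lod_sex[:, c], probeset,
                                  len(pctx["y"]), True,
                                  list(covariates.additive.columns), pctx)
        records.extend(scan_probeset(probeset, ecross, gp_expr, annotation,
                                     covariates, local_threshold,
                                     trans_threshold, _scans=(base, sexs),
                                     **kwargs))
    return records


# ---------------------------------------------------------------------------
# subsampled-probeset permutation thresholds


@dataclass
class EqtlThresholds:
    local: float
    trans: float
    null_local: np.ndarray
    null_trans: np.ndarray
    n_reps: int
    seed: int


def subsampled_thresholds(cross: Cross, expression: pd.DataFrame,
                          expr_covar: pd.DataFrame,
                          gp_expr: GenotypeProbabilities,
                          annotation: pd.DataFrame,
                          n_probesets: int = 100, n_reps: int = 200,
                          seed: int = 0, quantile: float = 0.95,
                          window_cm: float = LOCAL_WINDOW_CM) -> EqtlThresholds:
    """Local and trans LOD thresholds from subsampled-probeset permutations.

    Each replicate draws ``n_probesets`` probesets at random and permutes the
    individual labels once; the local null records the maximum LOD over the
    drawn probesets' local windows, the trans null the maximum genome-wide
    LOD over the same probesets. Thresholds are the ``quantile`` (default
    95%) of the replicate maxima.
    """
    if expression.shape[0] < n_probesets:
        raise ValueError("fewer probesets than subsample size")
    ecross = expression_cross(cross, expression, expr_covar)
    covariates = build_covariates(ecross, include_dye=True)
    ids = ecross.geno.index
    n = len(ids)
    Z = np.column_stack([np.ones(n), covariates.additive.loc[ids].to_numpy(float)])
    Q0 = _ols_basis(Z)
    pos_of = gp_expr.individuals.get_indexer(ids)
    x_a, x_d = genotype_scores(gp_expr)
    x_a, x_d = x_a[pos_of], x_d[pos_of]
    G = _geno_design(x_a, x_d, None, False)
    Gr = G - np.einsum("nj,jm,lmk->lnk", Q0, Q0.T, G, optimize=True)
    Qg, gmask = scanqtl._batched_basis(Gr)

    # local-window masks per probeset (annotated only)
    masks = {}
    for ps in expression.index:
        if ps in annotation.index and \
                str(annotation.loc[ps, "chrom"]) in set(gp_expr.grid["chrom"]):
            chrom, cm = gene_position_cm(annotation.loc[ps], ecross.gmap)
            masks[ps] = local_window_mask(gp_expr.grid, chrom, cm, window_cm)

    rng = np.random.default_rng(seed)
    X = expression.to_numpy(float)
    null_local = np.empty(n_reps)
    null_trans = np.empty(n_reps)
    all_ps = np.array(expression.index)
    for rep in range(n_reps):
        pick = rng.choice(len(all_ps), size=n_probesets, replace=False)
        perm = rng.permutation(n)
        Y = X[pick][:, perm].T                       # (n, C)
        Yr = Y - Q0 @ (Q0.T @ Y)
        rss0 = np.einsum("nc,nc->c", Yr, Yr)
        B = np.einsum("lnk,nc->lkc", Qg, Yr) * gmask[:, :, None]
        rss1 = np.maximum(rss0[None, :] - np.einsum("lkc,lkc->lc", B, B), 1e-12)
        lod = np.maximum(0.5 * n * np.log10(rss0[None, :] / rss1), 0.0)
        null_trans[rep] = lod.max()
        local_vals = [lod[masks[ps], c].max()
                      for c, ps in enumerate(all_ps[pick]) if ps in masks]
        null_local[rep] = max(local_vals) if local_vals else 0.0
    return EqtlThresholds(float(np.quantile(null_local, quantile)),
                          float(np.quantile(null_trans, quantile)),
                          null_local, null_trans, n_reps, seed)


# ---------------------------------------------------------------------------
# effect-direction summary


def effect_direction_summary(records: list[EqtlRecord]) -> pd.DataFrame:
    """Sign proportions of additive and dominance effects by sex and class.

    Additive sign > 0 means higher expression on the domestic (B) allele;
    dominance sign is the heterozygote's deviation from the mid-parental
    expectation. Per-sex effects fold the sex-interaction terms in
    (male = +1, female = -1 coding).
    """
    rows = []
    for r in records:
        for sex in ("male", "female"):
            rows.append(dict(kind=r.kind, sex=sex, effect="additive",
                             value=r.a_male if sex == "male" else r.a_female))
            rows.append(dict(kind=r.kind, sex=sex, effect="dominance",
                             value=r.d_male if sex == "male" else r.d_female))
    if not rows:
        return pd.DataFrame(columns=["kind", "sex", "effect", "n", "n_positive",
                                     "n_negative", "prop_positive"])
    df = pd.DataFrame(rows)
    out = df.groupby(["kind", "sex", "effect"]).agg(
        n=("value", "size"),
        n_positive=("value", lambda v: int((v > 0).sum())),
        n_negative=("value", lambda v: int((v < 0).sum()))).reset_index()
    out["prop_positive"] = out["n_positive"] / out["n"].where(out["n"] > 0, 1)
    return out
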