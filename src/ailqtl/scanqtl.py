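"""Haley-Knott QTL analysis.

Single-locus genome scans regress a trait on expected genotype scores
(additive dosage ``x_a = P(BB) - P(AA)`` and dominance indicator
``x_d = P(AB)``) at every grid position, with batch, sex and optional
genotype-PC covariates, reporting ``LOD = (n/2) log10(RSS0/RSS1)`` against
the covariates-only null. Genome-wide significance comes from permutation of
the trait vector; confidence intervals from a 1.8-LOD drop; epistasis from
two-dimensional scans with the five standard two-locus statistics; and
multiple-QTL models are assembled by forward inclusion with drop-one LOD
tests. An analytic power calculation (non-central chi-square) mirrors the
qtlDesign-style sample-size arithmetic.

All heavy paths are vectorized: genotype columns are residualized against
the covariate basis once, after which per-position (and per-permutation)
residual sums of squares reduce to small batched linear solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crossio import Cross
from .genoprob import GenotypeProbabilities, genotype_scores

LN10 = np.log(10.0)

# default two-locus declaration thresholds (full, full-vs-one, interactive,
# additive, additive-vs-one) — intercross genome-scan scale
DEFAULT_PAIR_THRESHOLDS = {"full": 11.0, "fv1": 9.0, "int": 7.0, "add": 7.0, "av1": 4.0}


# ---------------------------------------------------------------------------
# covariates


@dataclass
class CovariateSet:
    """Design columns used in every scan model.

    ``additive`` columns enter every model; ``interactive`` columns (sex)
    additionally multiply the genotype scores when a genotype-by-sex
    interaction is fitted. Neither may contain missing values for scanned
    individuals.
    """
    additive: pd.DataFrame
    interactive: pd.DataFrame

    @property
    def individuals(self) -> pd.Index:
        return self.additive.index


def build_covariates(cross: Cross, pcs: pd.DataFrame | None = None,
                     include_dye: bool = False,
                     covar: pd.DataFrame | None = None) -> CovariateSet:
    """Batch one-hot (reference dropped) + sex (+1/-1) [+ dye +1/-1] [+ PCs]."""
    covar = cross.covar if covar is None else covar
    cols = {}
    sex = covar["sex"].astype(str).map({"male": 1.0, "female": -1.0})
    cols["sex"] = sex
    batches = pd.get_dummies(covar["batch"].astype(str), prefix="batch",
                             drop_first=True, dtype=float)
    for c in batches.columns:
        cols[c] = batches[c]
    if include_dye and "dye" in covar.columns:
        dyes = sorted(covar["dye"].astype(str).unique())
        if len(dyes) > 1:
            cols["dye"] = covar["dye"].astype(str).map(
                {dyes[0]: -1.0, dyes[1]: 1.0})
    additive = pd.DataFrame(cols, index=covar.index)
    if pcs is not None:
        additive = additive.join(pcs)
    if additive.isna().any().any():
        raise ValueError("covariates contain missing values")
    return CovariateSet(additive=additive, interactive=additive[["sex"]])


def family_pcs(cross: Cross, trait: str, k: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """Genotype principal components associated with a trait.

    PCA of the additively coded, mean-imputed genotype matrix; each of the
    first ``k`` PCs is regressed against the trait and those with p < alpha
    are returned as covariate columns (possibly none). Controls residual
    family structure in the intercross.
    """
    from sklearn.decomposition import PCA

    x = cross.additive_coded_genotypes(impute=True)
    if k >= len(x):
        raise ValueError(f"k={k} PCs requested but only {len(x)} individuals")
    if float(x.var(axis=0).sum()) == 0.0:
        raise ValueError("degenerate genotype matrix: no variance")
    scores = PCA(n_components=k, svd_solver="full").fit_transform(
        x.to_numpy() - x.to_numpy().mean(axis=0))
    y = cross.pheno[trait]
    keep = y.notna().to_numpy()
    selected = []
    for j in range(k):
        res = stats.linregress(scores[keep, j], y.to_numpy()[keep])
        if res.pvalue < alpha:
            selected.append(j)
    return pd.DataFrame({f"PC{j + 1}": scores[:, j] for j in selected},
                        index=x.index)


# ---------------------------------------------------------------------------
# core least-squares machinery


def _ols_basis(Z: np.ndarray) -> np.ndarray:
    """Orthonormal basis (QR) of a design matrix, rank-trimmed."""
    q, r = np.linalg.qr(Z)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def _rss(y: np.ndarray, Q: np.ndarray) -> float:
    resid = y - Q @ (Q.T @ y)
    return float(resid @ resid)


def _batched_basis(Gr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched orthonormal bases of (L, n, k) column blocks via QR.

    Returns (Q, mask) where mask zeroes the contribution of numerically
    dependent columns (non-pivoted QR: a tiny |R_ii| marks column i as
    dependent on its predecessors).
    """
    Q, R = np.linalg.qr(Gr)
    diag = np.abs(np.diagonal(R, axis1=1, axis2=2))
    tol = 1e-10 * np.maximum(diag.max(axis=1, keepdims=True), 1e-300)
    return Q, (diag > tol).astype(float)


def _batched_fit_rss(Gr: np.ndarray, yr: np.ndarray, rss0) -> np.ndarray:
    """RSS of [covariates + k genotype columns] models, batched over positions.

    Gr: (L, n, k) genotype columns already residualized on the covariate
    basis; yr: (n,) residualized trait.
    """
    Q, mask = _batched_basis(Gr)
    b = np.einsum("lnk,n->lk", Q, yr) * mask
    rss = rss0 - np.einsum("lk,lk->l", b, b)
    return np.maximum(rss, 1e-12)


@dataclass
class ScanResult:
    """LOD curve on the scan grid plus the model context to refit peaks."""
    grid: pd.DataFrame                 # chrom, pos_cm, name, is_marker
    lod: np.ndarray
    trait: str
    n: int
    sex_interaction: bool
    covariate_names: list
    _context: dict = field(default_factory=dict, repr=False)

    def max(self, chrom: str | None = None) -> tuple[float, pd.Series]:
        mask = np.ones(len(self.grid), bool) if chrom is None else \
            (self.grid["chrom"] == str(chrom)).to_numpy()
        k = int(np.flatnonzero(mask)[np.argmax(self.lod[mask])])
        return float(self.lod[k]), self.grid.iloc[k]

    def chrom_peaks(self, threshold: float) -> pd.DataFrame:
        """Per-chromosome maxima with LOD >= threshold."""
        rows = []
        for chrom in dict.fromkeys(self.grid["chrom"]):
            lod, pos = self.max(chrom)
            if lod >= threshold:
                rows.append(dict(chrom=chrom, pos_cm=float(pos["pos_cm"]),
                                 name=pos["name"], lod=lod))
        return pd.DataFrame(rows, columns=["chrom", "pos_cm", "name", "lod"])


def _scan_arrays(cross: Cross, gp: GenotypeProbabilities, trait: str,
                 covariates: CovariateSet | None, individuals=None):
    """Listwise-complete y, covariate design, and genotype scores."""
    if covariates is None:
        covariates = build_covariates(cross)
    y_all = cross.pheno[trait]
    keep = y_all.notna()
    if individuals is not None:
        keep &= y_all.index.isin(individuals)
    ids = y_all.index[keep]
    y = y_all.loc[ids].to_numpy(float)
    Z = np.column_stack([np.ones(len(ids)),
                         covariates.additive.loc[ids].to_numpy(float)])
    sex = covariates.interactive.loc[ids, "sex"].to_numpy(float) \
        if "sex" in covariates.interactive.columns else None
    pos_of = gp.individuals.get_indexer(ids)
    if (pos_of < 0).any():
        raise ValueError("scanned individuals missing from genotype probabilities")
    x_a, x_d = genotype_scores(gp)
    return ids, y, Z, sex, x_a[pos_of], x_d[pos_of], covariates


def _geno_design(x_a, x_d, sex, sex_interaction) -> np.ndarray:
    """(L, n, k) stack of genotype columns per grid position."""
    cols = [x_a.T, x_d.T]
    if sex_interaction:
        cols += [(x_a * sex[:, None]).T, (x_d * sex[:, None]).T]
    return np.stack(cols, axis=2)


def scan_one(cross: Cross, gp: GenotypeProbabilities, trait: str,
             covariates: CovariateSet | None = None,
             sex_interaction: bool = False, individuals=None,
             min_n: int = 30) -> ScanResult:
    """Single-locus Haley-Knott genome scan.

    At each grid position the trait is regressed on the covariates plus
    ``x_a`` and ``x_d`` (plus ``sex*x_a`` and ``sex*x_d`` when
    ``sex_interaction``); LOD compares against the covariates-only null.
    Individuals with a missing trait value are dropped listwise.
    """
    ids, y, Z, sex, x_a, x_d, covariates = _scan_arrays(
        cross, gp, trait, covariates, individuals)
    n = len(ids)
    if n < min_n:
        raise ValueError(f"trait {trait!r}: only {n} phenotyped individuals (< {min_n})")
    if sex_interaction and sex is None:
        raise ValueError("sex interaction requested but no sex covariate")
    Q0 = _ols_basis(Z)
    if Q0.shape[1] < Z.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient covariate design")
    rss0 = _rss(y, Q0)
    G = _geno_design(x_a, x_d, sex, sex_interaction)
    Gr = G - np.einsum("nj,jm,lmk->lnk", Q0, Q0.T, G, optimize=True)
    yr = y - Q0 @ (Q0.T @ y)
    rss1 = _batched_fit_rss(Gr, yr, rss0)
    lod = np.maximum(0.5 * n * np.log10(rss0 / rss1), 0.0)
    return ScanResult(gp.grid.copy(), lod, trait, n, sex_interaction,
                      list(covariates.additive.columns),
                      _context=dict(ids=ids, y=y, Z=Z, sex=sex,
                                    x_a=x_a, x_d=x_d, rss0=rss0))


def fit_position(scan: ScanResult, position_index: int) -> pd.DataFrame:
    """OLS effect estimates (a, d and sex interactions) with SEs at one grid index."""
    import statsmodels.api as sm

    ctx = scan._context
    cols = {"a": ctx["x_a"][:, position_index], "d": ctx["x_d"][:, position_index]}
    if scan.sex_interaction:
        cols["a_by_sex"] = cols["a"] * ctx["sex"]
        cols["d_by_sex"] = cols["d"] * ctx["sex"]
    X = np.column_stack([ctx["Z"]] + [v for v in cols.values()])
    fit = sm.OLS(ctx["y"], X).fit()
    base = ctx["Z"].shape[1]
    return pd.DataFrame({"estimate": fit.params[base:], "se": fit.bse[base:]},
                        index=list(cols))


# ---------------------------------------------------------------------------
# permutation thresholds


@dataclass
class ThresholdSet:
    """Genome-wide significance thresholds from a permutation null."""
    thresholds: dict                  # alpha -> LOD threshold
    null_max: np.ndarray
    n_perm: int
    seed: int

    @property
    def significant(self) -> float:
        return self.thresholds[min(self.thresholds)]

    @property
    def suggestive(self) -> float:
        return self.thresholds[max(self.thresholds)]


def permutation_thresholds(cross: Cross, gp: GenotypeProbabilities, trait: str,
                           covariates: CovariateSet | None = None,
                           n_perm: int = 1000, alphas=(0.05, 0.20),
                           seed: int = 0, sex_interaction: bool = False,
                           individuals=None) -> ThresholdSet:
    """Empirical genome-wide max-LOD quantiles under trait permutation.

    The trait vector is shuffled over the scanned individuals while
    covariates stay attached to the genotypes, so the null preserves the
    covariate and family structure of the design.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    for a in alphas:
        if n_perm * a < 1 and a != 1.0:
            raise ValueError(f"n_perm={n_perm} too small for alpha={a}")
    null = null_max_lods(cross, gp, trait, covariates, n_perm, seed,
                         sex_interaction, individuals)
    thresholds = {float(a): float(np.quantile(null, 1.0 - a)) for a in alphas}
    return ThresholdSet(thresholds, null, n_perm, seed)


def null_max_lods(cross: Cross, gp: GenotypeProbabilities, trait: str,
                  covariates: CovariateSet | None = None, n_perm: int = 1000,
                  seed: int = 0, sex_interaction: bool = False,
                  individuals=None) -> np.ndarray:
    """Genome-wide max LOD for each trait permutation (vectorized)."""
    ids, y, Z, sex, x_a, x_d, _ = _scan_arrays(cross, gp, trait, covariates,
                                               individuals)
    n = len(ids)
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = y[perm].T                                    # (n, P)
    Q0 = _ols_basis(Z)
    Yr = Yp - Q0 @ (Q0.T @ Yp)
    rss0 = np.einsum("np,np->p", Yr, Yr)
    G = _geno_design(x_a, x_d, sex, sex_interaction)
    Gr = G - np.einsum("nj,jm,lmk->lnk", Q0, Q0.T, G, optimize=True)
    Q, mask = _batched_basis(Gr)
    B = np.einsum("lnk,np->lkp", Q, Yr) * mask[:, :, None]
    rss1 = np.maximum(rss0[None, :] - np.einsum("lkp,lkp->lp", B, B), 1e-12)
    lod = np.maximum(0.5 * n * np.log10(rss0[None, :] / rss1), 0.0)
    return lod.max(axis=0)


# ---------------------------------------------------------------------------
# LOD support intervals


@dataclass
class LodInterval:
    chrom: str
    peak_cm: float
    lo_cm: float
    hi_cm: float
    lo_mb: float | None
    hi_mb: float | None
    whole_chromosome: bool


def lod_interval(scan: ScanResult, cross: Cross, chrom: str,
                 drop: float = 1.8, peak_cm: float | None = None) -> LodInterval:
    """LOD-drop support interval around a chromosome's peak.

    The interval is the contiguous run of grid positions containing the peak
    with LOD >= peak - drop, expanded one grid position outward past the
    drop on each side (clamped at chromosome ends). If the whole chromosome
    stays above the drop the interval is the chromosome, flagged as such.
    """
    mask = (scan.grid["chrom"] == str(chrom)).to_numpy()
    idx = np.flatnonzero(mask)
    lod = scan.lod[idx]
    pos = scan.grid["pos_cm"].to_numpy()[idx]
    if peak_cm is None:
        k = int(np.argmax(lod))
    else:
        k = int(np.argmin(np.abs(pos - peak_cm)))
    cutoff = lod[k] - drop
    lo = k
    while lo > 0 and lod[lo - 1] >= cutoff:
        lo -= 1
    hi = k
    while hi < len(lod) - 1 and lod[hi + 1] >= cutoff:
        hi += 1
    whole = (lo == 0) and (hi == len(lod) - 1)
    lo = max(lo - 1, 0)
    hi = min(hi + 1, len(lod) - 1)
    try:
        lo_mb = cross.gmap.cm_to_mb(chrom, float(pos[lo]))
        hi_mb = cross.gmap.cm_to_mb(chrom, float(pos[hi]))
    except ValueError:
        lo_mb = hi_mb = None
    return LodInterval(str(chrom), float(pos[k]), float(pos[lo]), float(pos[hi]),
                       lo_mb, hi_mb, whole)


def merge_regions(intervals: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping [lo_mb, hi_mb) intervals (any trait) per chromosome.

    Used to count distinct genomic regions across per-trait QTL lists.
    Expects columns chrom, lo_mb, hi_mb; returns merged regions with member
    counts.
    """
    out = []
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sub = sub.sort_values("lo_mb")
        cur_lo = cur_hi = None
        members = 0
        for _, row in sub.iterrows():
            if cur_lo is None or row["lo_mb"] >= cur_hi:
                if cur_lo is not None:
                    out.append((chrom, cur_lo, cur_hi, members))
                cur_lo, cur_hi, members = row["lo_mb"], row["hi_mb"], 1
            else:
                cur_hi = max(cur_hi, row["hi_mb"])
                members += 1
        if cur_lo is not None:
            out.append((chrom, cur_lo, cur_hi, members))
    return pd.DataFrame(out, columns=["chrom", "lo_mb", "hi_mb", "n_members"])


# ---------------------------------------------------------------------------
# two-dimensional (epistasis) scan


@dataclass
class Scan2Result:
    """The five two-locus statistics over all grid-position pairs.

    Matrices are (S, S), filled for i < j only: ``full`` (both loci plus
    4-df interaction vs null), ``add`` (both loci, no interaction),
    ``int`` = full - add, ``fv1`` = full - best single locus,
    ``av1`` = add - best single locus.
    """
    grid: pd.DataFrame
    lod_full: np.ndarray
    lod_add: np.ndarray
    lod_int: np.ndarray
    lod_fv1: np.ndarray
    lod_av1: np.ndarray
    lod_one: np.ndarray
    trait: str
    n: int

    def declared_pairs(self, thresholds: dict | None = None) -> pd.DataFrame:
        """Pairs passing the joint two-locus declaration rule.

        A pair is declared if (full >= T_full and (fv1 >= T_fv1 or
        int >= T_int)) or (add >= T_add and av1 >= T_av1).
        """
        t = dict(DEFAULT_PAIR_THRESHOLDS)
        if thresholds:
            t.update(thresholds)
        rows = []
        S = len(self.grid)
        for i in range(S):
            for j in range(i + 1, S):
                ok_full = self.lod_full[i, j] >= t["full"] and (
                    self.lod_fv1[i, j] >= t["fv1"] or self.lod_int[i, j] >= t["int"])
                ok_add = self.lod_add[i, j] >= t["add"] and self.lod_av1[i, j] >= t["av1"]
                if ok_full or ok_add:
                    rows.append(dict(
                        chrom1=self.grid.iloc[i]["chrom"], cm1=self.grid.iloc[i]["pos_cm"],
                        chrom2=self.grid.iloc[j]["chrom"], cm2=self.grid.iloc[j]["pos_cm"],
                        lod_full=self.lod_full[i, j], lod_fv1=self.lod_fv1[i, j],
                        lod_int=self.lod_int[i, j], lod_add=self.lod_add[i, j],
                        lod_av1=self.lod_av1[i, j]))
        return pd.DataFrame(rows, columns=["chrom1", "cm1", "chrom2", "cm2",
                                           "lod_full", "lod_fv1", "lod_int",
                                           "lod_add", "lod_av1"])


def _coarsen_grid(grid: pd.DataFrame, step_cm: float) -> np.ndarray:
    """Indices of grid positions subsampled to >= step_cm spacing per chromosome."""
    keep = []
    for chrom in dict.fromkeys(grid["chrom"]):
        idx = np.flatnonzero((grid["chrom"] == chrom).to_numpy())
        pos = grid["pos_cm"].to_numpy()[idx]
        last = -np.inf
        for k, p in zip(idx, pos):
            if p - last >= step_cm - 1e-9:
                keep.append(k)
                last = p
    return np.array(keep, dtype=int)


def scan_two(cross: Cross, gp: GenotypeProbabilities, trait: str,
             covariates: CovariateSet | None = None, step_cm: float = 5.0,
             individuals=None, chunk: int = 256) -> Scan2Result:
    """Two-dimensional Haley-Knott scan for epistatic locus pairs.

    The grid is coarsened to >= ``step_cm`` spacing. For each pair the full
    model carries both loci's (a, d) terms plus the four interaction
    products; the additive model drops the products.
    """
    ids, y, Z, sex, x_a, x_d, covariates = _scan_arrays(
        cross, gp, trait, covariates, individuals)
    n = len(ids)
    sel = _coarsen_grid(gp.grid, step_cm)
    for chrom in dict.fromkeys(gp.grid["chrom"]):
        if int((gp.grid["chrom"].to_numpy()[sel] == chrom).sum()) < 2:
            raise ValueError(f"grid too coarse: <2 positions on chromosome {chrom}")
    grid = gp.grid.iloc[sel].reset_index(drop=True)
    xa, xd = x_a[:, sel], x_d[:, sel]
    S = len(sel)
    Q0 = _ols_basis(Z)
    rss0 = _rss(y, Q0)
    yr = y - Q0 @ (Q0.T @ y)

    # single-locus LOD on the coarse grid (for fv1 / av1)
    G1 = _geno_design(xa, xd, sex, False)
    G1r = G1 - np.einsum("nj,jm,lmk->lnk", Q0, Q0.T, G1, optimize=True)
    lod_one = 0.5 * n * np.log10(rss0 / _batched_fit_rss(G1r, yr, rss0))
    lod_one = np.maximum(lod_one, 0.0)

    pairs = [(i, j) for i in range(S) for j in range(i + 1, S)]
    lod_full = np.zeros((S, S))
    lod_add = np.zeros((S, S))
    for start in range(0, len(pairs), chunk):
        block = pairs[start:start + chunk]
        ii = np.array([p[0] for p in block])
        jj = np.array([p[1] for p in block])
        a1, d1 = xa[:, ii], xd[:, ii]          # (n, C)
        a2, d2 = xa[:, jj], xd[:, jj]
        G = np.stack([a1, d1, a2, d2, a1 * a2, a1 * d2, d1 * a2, d1 * d2],
                     axis=2).transpose(1, 0, 2)  # (C, n, 8)
        Gr = G - np.einsum("nj,jm,cmk->cnk", Q0, Q0.T, G, optimize=True)
        rss_full = _batched_fit_rss(Gr, yr, rss0)
        rss_add = _batched_fit_rss(Gr[:, :, :4], yr, rss0)
        lod_full[ii, jj] = np.maximum(0.5 * n * np.log10(rss0 / rss_full), 0.0)
        lod_add[ii, jj] = np.maximum(0.5 * n * np.log10(rss0 / rss_add), 0.0)

    best_one = np.maximum.outer(lod_one, lod_one)
    lod_int = np.triu(lod_full - lod_add, 1)
    lod_fv1 = np.triu(lod_full - best_one, 1)
    lod_av1 = np.triu(lod_add - best_one, 1)
    return Scan2Result(grid, lod_full, lod_add, lod_int, lod_fv1, lod_av1,
                       lod_one, trait, n)


# ---------------------------------------------------------------------------
# multiple-QTL models


@dataclass
class QtlModelFit:
    """A fitted multiple-QTL model for one trait."""
    trait: str
    loci: pd.DataFrame        # chrom, cm, mb, lod_drop1, sex_interaction,
    #                           a, se_a, d, se_d, a_by_sex, se_a_by_sex, ...,
    #                           var_explained_pct
    pairs: pd.DataFrame       # chrom1, cm1, chrom2, cm2, lod_drop1, var_explained_pct
    model_var_explained_pct: float
    n: int


def fit_multiqtl(cross: Cross, gp: GenotypeProbabilities, trait: str,
                 candidates: pd.DataFrame,
                 covariates: CovariateSet | None = None,
                 pairs: pd.DataFrame | None = None,
                 drop_one_threshold: float = 4.3,
                 pair_threshold: float = 7.0,
                 sex_delta_lod: float = 1.0,
                 individuals=None) -> QtlModelFit:
    """Forward-build a multiple-QTL model from candidate loci and pairs.

    Candidates (columns chrom, pos_cm, lod) are added most-significant
    first; a locus is kept if its drop-one LOD exceeds
    ``drop_one_threshold``. Planted epistatic pairs (columns chrom1, cm1,
    chrom2, cm2) whose loci survive contribute interaction terms kept at
    ``pair_threshold``. A locus's genotype-by-sex terms are retained when
    they improve the model LOD by more than ``sex_delta_lod``. Variance
    explained per term is 100*(RSS_reduced - RSS_full)/TSS.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    import statsmodels.api as sm

    ids, y, Z, sex, x_a, x_d, covariates = _scan_arrays(
        cross, gp, trait, covariates, individuals)
    n = len(ids)
    grid = gp.grid
    tss = float(((y - y.mean()) ** 2).sum())

    def grid_index(chrom, cm):
        idx = np.flatnonzero((grid["chrom"] == str(chrom)).to_numpy())
        return int(idx[np.argmin(np.abs(grid["pos_cm"].to_numpy()[idx] - cm))])

    def locus_cols(k, with_sex):
        cols = [x_a[:, k], x_d[:, k]]
        if with_sex:
            cols += [x_a[:, k] * sex, x_d[:, k] * sex]
        return cols

    def model_rss(locus_list, pair_list):
        cols = [Z]
        for k, with_sex in locus_list:
            cols.append(np.column_stack(locus_cols(k, with_sex)))
        for (k1, k2) in pair_list:
            cols.append((x_a[:, k1] * x_a[:, k2])[:, None])
        X = np.column_stack(cols)
        return _rss(y, _ols_basis(X))

    cand = candidates.sort_values("lod", ascending=False)
    included: list[tuple[int, bool]] = []
    for _, row in cand.iterrows():
        k = grid_index(row["chrom"], row["pos_cm"])
        trial = included + [(k, False)]
        rss_with = model_rss(trial, [])
        rss_without = model_rss(included, [])
        drop1 = 0.5 * n * np.log10(rss_without / rss_with)
        if drop1 > drop_one_threshold:
            # decide sex interaction for this locus
            rss_sex = model_rss(included + [(k, True)], [])
            use_sex = (sex is not None
                       and 0.5 * n * np.log10(rss_with / rss_sex) > sex_delta_lod)
            included.append((k, use_sex))

    pair_idx: list[tuple[int, int]] = []
    if pairs is not None and len(included) > 0:
        for _, row in pairs.iterrows():
            k1 = grid_index(row["chrom1"], row["cm1"])
            k2 = grid_index(row["chrom2"], row["cm2"])
            rss_with = model_rss(included, pair_idx + [(k1, k2)])
            rss_without = model_rss(included, pair_idx)
            if 0.5 * n * np.log10(rss_without / rss_with) > pair_threshold:
                pair_idx.append((k1, k2))

    rss_full = model_rss(included, pair_idx)
    rss_cov = _rss(y, _ols_basis(Z))

    # per-term statistics
    loci_rows = []
    for m, (k, with_sex) in enumerate(included):
        reduced = included[:m] + included[m + 1:]
        rss_red = model_rss(reduced, pair_idx)
        chrom = grid["chrom"].iloc[k]
        cm = float(grid["pos_cm"].iloc[k])
        try:
            mb = cross.gmap.cm_to_mb(chrom, cm)
        except ValueError:
            mb = np.nan
        loci_rows.append(dict(
            chrom=chrom, cm=cm, mb=mb,
            lod_drop1=0.5 * n * np.log10(rss_red / rss_full),
            sex_interaction=with_sex,
            var_explained_pct=100.0 * (rss_red - rss_full) / tss))
    pair_rows = []
    for m, (k1, k2) in enumerate(pair_idx):
        reduced = pair_idx[:m] + pair_idx[m + 1:]
        rss_red = model_rss(included, reduced)
        pair_rows.append(dict(
            chrom1=grid["chrom"].iloc[k1], cm1=float(grid["pos_cm"].iloc[k1]),
            chrom2=grid["chrom"].iloc[k2], cm2=float(grid["pos_cm"].iloc[k2]),
            lod_drop1=0.5 * n * np.log10(rss_red / rss_full),
            var_explained_pct=100.0 * (rss_red - rss_full) / tss))

    # effect estimates with SEs from the final joint fit
    cols, names = [Z], []
    for k, with_sex in included:
        for c, nm in zip(locus_cols(k, with_sex),
                         ["a", "d", "a_by_sex", "d_by_sex"]):
            cols.append(c[:, None])
            names.append((k, nm))
    for (k1, k2) in pair_idx:
        cols.append((x_a[:, k1] * x_a[:, k2])[:, None])
        names.append(((k1, k2), "aa"))
    X = np.column_stack(cols)
    fit = sm.OLS(y, X).fit()
    base = Z.shape[1]
    est = dict(zip(names, zip(fit.params[base:], fit.bse[base:])))
    for row, (k, with_sex) in zip(loci_rows, included):
        for nm in ["a", "d", "a_by_sex", "d_by_sex"]:
            val = est.get((k, nm))
            row[nm] = val[0] if val else np.nan
            row[f"se_{nm}"] = val[1] if val else np.nan

    loci = pd.DataFrame(loci_rows, columns=["chrom", "cm", "mb", "lod_drop1",
                                            "sex_interaction", "a", "se_a", "d",
                                            "se_d", "a_by_sex", "se_a_by_sex",
                                            "d_by_sex", "se_d_by_sex",
                                            "var_explained_pct"])
    pairs_df = pd.DataFrame(pair_rows, columns=["chrom1", "cm1", "chrom2", "cm2",
                                                "lod_drop1", "var_explained_pct"])
    return QtlModelFit(trait, loci, pairs_df,
                       100.0 * (rss_cov - rss_full) / tss, n)


# ---------------------------------------------------------------------------
# power


def power_detect(n: int, effect_fraction: float, threshold_lod: float,
                 df: int = 2) -> float:
    """Analytic detection power for a locus explaining a variance fraction.

    The scan statistic 2 ln(10) LOD at the true locus is approximately
    non-central chi-square with ``df`` degrees of freedom (2 for the
    intercross a+d model) and non-centrality n*f/(1-f); power is the
    probability of exceeding the LOD threshold.
    """
    if not 0.0 < effect_fraction < 1.0:
        raise ValueError("effect_fraction must be in (0, 1)")
    ncp = n * effect_fraction / (1.0 - effect_fraction)
    return float(stats.ncx2.sf(2.0 * LN10 * threshold_lod, df, ncp))
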