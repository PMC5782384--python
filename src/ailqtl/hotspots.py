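"""Trans-eQTL hotspot detection and conditional mediation analysis.

A hotspot is a genomic region covered by more distal-eQTL confidence
intervals than expected if the same intervals were dropped uniformly at
random on an unstructured genome (default 1 Gb, the sequenced autosomal
span). Observed coverage is computed on the real chromosome structure in
half-open Mb bins; the null keeps every interval's length and redraws its
start, and the hotspot threshold is a quantile (default 95%) of the null
maximum coverages.

For each called hotspot, local eQTL genes overlapping it are tested as
mediators of the member trans associations: both expression profiles are
residualized on sex, batch and dye, correlated, and the trans scan is refit
with the candidate mediator's expression as an additive covariate. A
mediator is flagged when the residual correlation is significant and the
conditional LOD falls below half the unconditional LOD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crossio import Cross
from .genoprob import GenotypeProbabilities
from . import scanqtl
from .eqtlscan import EqtlRecord, expression_cross
from .scanqtl import build_covariates, CovariateSet

DEFAULT_GENOME_LENGTH_MB = 1000.0
DEFAULT_BIN_MB = 0.1


@dataclass
class CoverageTrack:
    """Per-bin counts of overlapping intervals on the physical genome."""
    bins: pd.DataFrame        # chrom, start_mb, end_mb (half-open), count
    bin_mb: float

    def max_coverage(self) -> int:
        return int(self.bins["count"].max()) if len(self.bins) else 0


def coverage(intervals: pd.DataFrame, chrom_lengths_mb: dict,
             bin_mb: float = DEFAULT_BIN_MB) -> CoverageTrack:
    """Exact interval coverage on half-open Mb bins.

    ``intervals`` needs columns chrom, lo_mb, hi_mb. A bin counts an
    interval when the half-open spans [lo, hi) and [bin_start, bin_end)
    intersect.
    """
    if ((intervals["hi_mb"] - intervals["lo_mb"]) < 0).any():
        raise ValueError("negative-length interval")
    frames = []
    for chrom, length in chrom_lengths_mb.items():
        n_bins = int(np.ceil(length / bin_mb))
        starts = np.arange(n_bins) * bin_mb
        counts = np.zeros(n_bins, dtype=int)
        sub = intervals[intervals["chrom"].astype(str) == str(chrom)]
        for lo, hi in zip(sub["lo_mb"], sub["hi_mb"]):
            if hi <= lo:
                continue
            b0 = int(np.floor(lo / bin_mb))
            b1 = int(np.ceil(hi / bin_mb))
            counts[max(b0, 0):min(b1, n_bins)] += 1
        frames.append(pd.DataFrame({"chrom": str(chrom), "start_mb": starts,
                                    "end_mb": np.minimum(starts + bin_mb, length),
                                    "count": counts}))
    return CoverageTrack(pd.concat(frames, ignore_index=True), bin_mb)


def _max_stack(starts: np.ndarray, ends: np.ndarray) -> int:
    """Maximum number of simultaneously open intervals (event sweep)."""
    events = np.concatenate([starts, ends])
    deltas = np.concatenate([np.ones_like(starts), -np.ones_like(ends)])
    order = np.lexsort((deltas, events))    # close before open at a tie: half-open
    return int(np.cumsum(deltas[order]).max())


@dataclass
class RandomPlacementNull:
    null_max: np.ndarray
    threshold: float
    genome_length_mb: float
    quantile: float


def random_placement_null(intervals: pd.DataFrame,
                          genome_length_mb: float = DEFAULT_GENOME_LENGTH_MB,
                          n_sim: int = 1000, seed: int = 0,
                          quantile: float = 0.95) -> RandomPlacementNull:
    """Null distribution of maximum coverage under uniform random placement.

    Interval lengths are kept; each simulation redraws starts uniformly on
    [0, genome_length - length] on one unstructured line and records the
    highest coverage.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    lengths = (intervals["hi_mb"] - intervals["lo_mb"]).to_numpy(float)
    if (lengths > genome_length_mb).any():
        raise ValueError("interval longer than the null genome")
    rng = np.random.default_rng(seed)
    null = np.empty(n_sim, dtype=int)
    for s in range(n_sim):
        starts = rng.uniform(0.0, genome_length_mb - lengths)
        null[s] = _max_stack(starts, starts + lengths)
    return RandomPlacementNull(null, float(np.quantile(null, quantile)),
                               genome_length_mb, quantile)


@dataclass
class HotspotCall:
    chrom: str
    lo_mb: float
    hi_mb: float
    peak_coverage: int
    threshold: float
    members: list             # probeset ids of member distal eQTL


def call_hotspots(distal_records: list[EqtlRecord], chrom_lengths_mb: dict,
                  bin_mb: float = DEFAULT_BIN_MB,
                  genome_length_mb: float = DEFAULT_GENOME_LENGTH_MB,
                  n_sim: int = 1000, seed: int = 0,
                  quantile: float = 0.95) -> tuple[list[HotspotCall], RandomPlacementNull]:
    """Coverage-based hotspot calls against the random-placement null.

    A hotspot is a maximal run of bins whose coverage exceeds the null
    threshold; its extent is that run and its members are the distal eQTL
    whose confidence intervals overlap it.
    """
    ivals = pd.DataFrame([{"chrom": r.chrom, "lo_mb": r.ci_lo_mb,
                           "hi_mb": r.ci_hi_mb, "probeset": r.probeset}
                          for r in distal_records if r.ci_lo_mb is not None])
    if ivals.empty:
        return [], RandomPlacementNull(np.zeros(n_sim, dtype=int), np.inf,
                                       genome_length_mb, quantile)
    null = random_placement_null(ivals, genome_length_mb, n_sim, seed, quantile)
    track = coverage(ivals, chrom_lengths_mb, bin_mb)
    calls = []
    for chrom, sub in track.bins.groupby("chrom", sort=False):
        above = (sub["count"] > null.threshold).to_numpy()
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for lo_i, hi_i in zip(edges[::2], edges[1::2]):
            lo = float(sub["start_mb"].iloc[lo_i])
            hi = float(sub["end_mb"].iloc[hi_i - 1])
            members = ivals[(ivals["chrom"] == chrom) & (ivals["lo_mb"] < hi)
                            & (ivals["hi_mb"] > lo)]["probeset"].tolist()
            calls.append(HotspotCall(str(chrom), lo, hi,
                                     int(sub["count"].iloc[lo_i:hi_i].max()),
                                     null.threshold, members))
    return calls, null


# ---------------------------------------------------------------------------
# conditional mediation


@dataclass
class MediationResult:
    hotspot: str              # "chrom:lo-hi" label
    mediator_probeset: str
    trans_probeset: str
    correlation: float
    correlation_p: float
    lod_unconditional: float
    lod_conditional: float
    mediator_flag: bool


def _residualize(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    Q = scanqtl._ols_basis(design)
    return values - Q @ (Q.T @ values)


def mediation_test(hotspot: HotspotCall, mediator: EqtlRecord,
                   trans: EqtlRecord, cross: Cross, expression: pd.DataFrame,
                   expr_covar: pd.DataFrame, gp_expr: GenotypeProbabilities,
                   alpha: float = 0.05) -> MediationResult:
    """Conditional test of one local gene mediating one trans association.

    Expression of mediator and target are residualized on sex, batch and
    dye and correlated (Pearson); the trans LOD at the hotspot peak is then
    recomputed with the mediator's expression as an extra additive
    covariate. The mediator flag requires correlation p < alpha and the
    conditional LOD below half the unconditional one.
    """
    if mediator.probeset == trans.probeset:
        raise ValueError("mediator and target are the same probeset")
    ecross = expression_cross(cross, expression, expr_covar)
    covariates = build_covariates(ecross, include_dye=True)
    ids = ecross.geno.index
    Z = np.column_stack([np.ones(len(ids)),
                         covariates.additive.loc[ids].to_numpy(float)])
    m = expression.loc[mediator.probeset, ids].to_numpy(float)
    t = expression.loc[trans.probeset, ids].to_numpy(float)
    r, p = stats.pearsonr(_residualize(m, Z), _residualize(t, Z))

    scan_u = scanqtl.scan_one(ecross, gp_expr, trans.probeset, covariates,
                              sex_interaction=trans.sex_interaction, min_n=2)
    with_m = CovariateSet(
        additive=covariates.additive.assign(_mediator=pd.Series(m, index=ids)),
        interactive=covariates.interactive)
    scan_c = scanqtl.scan_one(ecross, gp_expr, trans.probeset, with_m,
                              sex_interaction=trans.sex_interaction, min_n=2)
    on_chrom = (gp_expr.grid["chrom"] == trans.chrom).to_numpy()
    pos = gp_expr.grid["pos_cm"].to_numpy()
    k = int(np.flatnonzero(on_chrom)[
        np.argmin(np.abs(pos[on_chrom] - trans.peak_cm))])
    lod_u = float(scan_u.lod[k])
    lod_c = float(scan_c.lod[k])
    label = f"{hotspot.chrom}:{hotspot.lo_mb:.1f}-{hotspot.hi_mb:.1f}"
    flag = bool(p < alpha and lod_c < 0.5 * lod_u)
    return MediationResult(label, mediator.probeset, trans.probeset,
                           float(r), float(p), lod_u, lod_c, flag)


def mediate_hotspot(hotspot: HotspotCall, local_records: list[EqtlRecord],
                    distal_records: list[EqtlRecord], cross: Cross,
                    expression: pd.DataFrame, expr_covar: pd.DataFrame,
                    gp_expr: GenotypeProbabilities,
                    alpha: float = 0.05) -> list[MediationResult]:
    """All (overlapping local gene) x (member trans eQTL) mediation tests."""
    results = []
    locals_over = [r for r in local_records
                   if r.chrom == hotspot.chrom and r.ci_lo_mb is not None
                   and r.ci_lo_mb < hotspot.hi_mb and r.ci_hi_mb > hotspot.lo_mb]
    members = {r.probeset: r for r in distal_records
               if r.probeset in hotspot.members and r.chrom == hotspot.chrom}
    for med in locals_over:
        for trans in members.values():
            if med.probeset == trans.probeset:
                continue
            results.append(mediation_test(hotspot, med, trans, cross,
                                          expression, expr_covar, gp_expr, alpha))
    return results


def export_network(calls: list[HotspotCall],
                   mediations: list[MediationResult]):
    """Node/edge tables and a directed graph of mediator -> target links.

    Nodes are hotspot marker locations and probesets; edges run from a
    flagged mediator gene to each of its trans targets. Returns
    ``(nodes, edges, graph)`` where graph is a networkx DiGraph (writable
    with ``networkx.write_graphml``).
    """
    import networkx as nx

    g = nx.DiGraph()
    for call in calls:
        g.add_node(f"{call.chrom}:{call.lo_mb:.1f}-{call.hi_mb:.1f}",
                   node_type="hotspot", chrom=call.chrom)
    for m in mediations:
        if not m.mediator_flag:
            continue
        g.add_node(m.mediator_probeset, node_type="probeset")
        g.add_node(m.trans_probeset, node_type="probeset")
        g.add_edge(m.mediator_probeset, m.trans_probeset,
                   hotspot=m.hotspot, correlation=m.correlation,
                   lod_drop=m.lod_unconditional - m.lod_conditional)
    nodes = pd.DataFrame([{"node": n, **attrs} for n, attrs in g.nodes(data=True)],
                         columns=["node", "node_type", "chrom"])
    edges = pd.DataFrame([{"source": u, "target": v, **attrs}
                          for u, v, attrs in g.edges(data=True)],
                         columns=["source", "target", "hotspot", "correlation",
                                  "lod_drop"])
    return nodes, edges, g
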