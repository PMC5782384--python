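"""Multipoint genotype probabilities for an intercross.

A three-state (AA/AB/BB) hidden Markov chain is run along each chromosome:
transition probabilities come from the F2 two-locus distribution with
recombination fractions from the Haldane map function, emissions allow a
genotyping-error rate and partially informative observation classes, and the
forward-backward algorithm yields a posterior probability triple at every
marker and at pseudomarkers inserted on a regular cM grid.

The advanced-intercross generations are handled implicitly: the map is the
one estimated from the final-generation data (already expanded by the extra
rounds of recombination), and F2 transition probabilities are applied on
that map — the same approximation used when such a cross is analysed as an
ordinary intercross.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossio import COMPATIBLE_STATES, Cross, GENO_MISSING

F2_PRIOR = np.array([0.25, 0.5, 0.25])


def haldane_r(d_cm) -> np.ndarray:
    """Recombination fraction for a map distance in cM (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def f2_transition(r: float) -> np.ndarray:
    """3x3 transition matrix between F2 genotypes at two loci at recomb. fraction r."""
    s = 1.0 - r
    return np.array([
        [s * s, 2 * r * s, r * r],
        [r * s, s * s + r * r, r * s],
        [r * r, 2 * r * s, s * s],
    ])


def emission_weights(error_rate: float) -> np.ndarray:
    """Likelihood table P(observed code | true state), shape (6, 3).

    Row order follows the internal genotype alphabet (AA, AB, BB, not-AA,
    not-BB) with the last row for missing. A compatible state keeps weight
    ``1 - eps``; the error mass is spread uniformly over incompatible states.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    w = np.empty((6, 3))
    for code, compat in COMPATIBLE_STATES.items():
        row = 5 if code == GENO_MISSING else code
        n_bad = 3 - len(compat)
        for s in range(3):
            if code == GENO_MISSING:
                w[row, s] = 1.0
            elif s in compat:
                w[row, s] = 1.0 - error_rate
            else:
                w[row, s] = error_rate / n_bad
    return w


@dataclass
class GenotypeProbabilities:
    """Posterior genotype probabilities on a pseudomarker grid.

    Attributes
    ----------
    grid
        DataFrame with one row per grid position: ``chrom``, ``pos_cm``,
        ``name`` (marker name or ``c{chrom}.loc{cm}``), ``is_marker``.
    probs
        Array of shape (n_individuals, n_positions, 3); each triple sums to 1.
    individuals
        Index matching the Cross the probabilities were computed from.
    error_rate, step_cm
        Settings used.
    """

    grid: pd.DataFrame
    probs: np.ndarray
    individuals: pd.Index
    error_rate: float
    step_cm: float

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.grid["chrom"] == str(chrom)).to_numpy())

    def positions_cm(self, chrom: str) -> np.ndarray:
        return self.grid.loc[self.grid["chrom"] == str(chrom), "pos_cm"].to_numpy()


def _build_grid(gmap, step_cm: float) -> pd.DataFrame:
    rows = []
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_markers(chrom)
        cm = sub["cm"].to_numpy(float)
        pos = list(cm)
        names = list(sub.index)
        is_marker = [True] * len(cm)
        if step_cm > 0:
            extra = np.arange(cm[0], cm[-1], step_cm)[1:]
            # keep pseudomarkers that do not coincide with a marker
            extra = extra[~np.isin(np.round(extra, 9), np.round(cm, 9))]
            pos.extend(extra)
            names.extend(f"c{chrom}.loc{p:g}" for p in extra)
            is_marker.extend([False] * len(extra))
        order = np.argsort(pos, kind="stable")
        for k in order:
            rows.append((str(chrom), float(pos[k]), names[k], is_marker[k]))
    return pd.DataFrame(rows, columns=["chrom", "pos_cm", "name", "is_marker"])


def calc_genoprob(cross: Cross, step_cm: float = 1.0,
                  error_rate: float = 0.001) -> GenotypeProbabilities:
    """Forward-backward genotype probabilities for every individual.

    Parameters
    ----------
    cross
        The intercross; observation codes may include partially informative
        and missing values.
    step_cm
        Pseudomarker spacing; 0 disables pseudomarkers.
    error_rate
        Genotyping-error rate epsilon used in the emission model.
    """
    if step_cm < 0:
        raise ValueError("step_cm must be >= 0")
    emit = emission_weights(error_rate)
    grid = _build_grid(cross.gmap, step_cm)
    n = cross.n_individuals
    probs = np.empty((n, len(grid), 3))

    for chrom in cross.gmap.chromosomes:
        sub = cross.gmap.chrom_markers(chrom)
        idx = np.flatnonzero((grid["chrom"] == chrom).to_numpy())
        gpos = grid["pos_cm"].to_numpy()[idx]
        # observation row index per grid position (5 = missing for pseudomarkers)
        obs = np.full((n, len(idx)), 5, dtype=np.int8)
        marker_cols = {}
        for name, cm in zip(sub.index, sub["cm"]):
            k = int(np.flatnonzero((grid["name"].to_numpy()[idx] == name))[0])
            marker_cols[k] = name
        for k, name in marker_cols.items():
            codes = cross.geno[name].to_numpy()
            obs[:, k] = np.where(codes == GENO_MISSING, 5, codes)

        trans = [f2_transition(float(haldane_r(gpos[k + 1] - gpos[k])))
                 for k in range(len(idx) - 1)]
        probs[:, idx, :] = _forward_backward(obs, emit, trans)

    return GenotypeProbabilities(grid, probs, cross.geno.index, error_rate, step_cm)


def _forward_backward(obs: np.ndarray, emit: np.ndarray, trans: list[np.ndarray]) -> np.ndarray:
    """Vectorized over individuals; obs is (n, L) of emission-row indices."""
    n, L = obs.shape
    e = emit[obs]                      # (n, L, 3)
    alpha = np.empty((n, L, 3))
    alpha[:, 0] = F2_PRIOR * e[:, 0]
    scale = alpha[:, 0].sum(axis=1, keepdims=True)
    alpha[:, 0] /= scale
    for k in range(1, L):
        a = alpha[:, k - 1] @ trans[k - 1]
        a *= e[:, k]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, k] = a
    beta = np.empty((n, L, 3))
    beta[:, L - 1] = 1.0
    for k in range(L - 2, -1, -1):
        b = (beta[:, k + 1] * e[:, k + 1]) @ trans[k].T
        b /= b.sum(axis=1, keepdims=True)
        beta[:, k] = b
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post


def genotype_scores(gp: GenotypeProbabilities) -> tuple[np.ndarray, np.ndarray]:
    """Haley-Knott regression scores from posterior probabilities.

    Returns ``(x_a, x_d)`` of shape (n_individuals, n_positions) with
    ``x_a = P(BB) - P(AA)`` in [-1, 1] and ``x_d = P(AB)`` in [0, 1].
    """
    x_a = gp.probs[:, :, 2] - gp.probs[:, :, 0]
    x_d = gp.probs[:, :, 1]
    return x_a, x_d


def brute_force_genoprob(obs_codes: np.ndarray, positions_cm: np.ndarray,
                         error_rate: float) -> np.ndarray:
    """Exhaustive path-sum posterior for one individual on one chromosome.

    Enumerates all 3**L state paths; usable only for small L. Serves as an
    independent oracle for the forward-backward recursion.
    """
    import itertools

    emit = emission_weights(error_rate)
    L = len(obs_codes)
    rows = [5 if c == GENO_MISSING else int(c) for c in obs_codes]
    trans = [f2_transition(float(haldane_r(positions_cm[k + 1] - positions_cm[k])))
             for k in range(L - 1)]
    post = np.zeros((L, 3))
    total = 0.0
    for path in itertools.product(range(3), repeat=L):
        p = F2_PRIOR[path[0]] * emit[rows[0], path[0]]
        for k in range(1, L):
            p *= trans[k - 1][path[k - 1], path[k]] * emit[rows[k], path[k]]
        total += p
        for k, s in enumerate(path):
            post[k, s] += p
    return post / total
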