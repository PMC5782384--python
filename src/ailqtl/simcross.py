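"""Synthetic advanced-intercross data generator.

Simulates the study design end-to-end so every downstream stage can be
exercised and calibrated without external data: two fully inbred founder
lines are crossed, the F1 is propagated by random non-self mating at a fixed
population size for a configurable number of generations (default F8 at
~100 birds per generation), and the final generation is genotyped at map
markers, phenotyped for body-mass traits with a planted QTL architecture
(additive, dominance, sex-interaction and epistatic effects), and assayed
for expression on a simulated two-colour array with planted local eQTL,
trans eQTL, sex-specific effects, batch/dye offsets and a mediated
trans-hotspot.

Meiosis uses the Haldane (no-interference) model: crossover counts are
Poisson with mean map-length/100 Morgans and positions are uniform, which
keeps the simulated map consistent with Haldane-based transition
probabilities downstream.

Truth tables (planted positions and effect sizes) travel with the simulated
study so parameter-recovery tests can compare estimates against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .crossio import (Cross, GeneticMap, GENO_AA, GENO_AB, GENO_BB,
                      GENO_NOT_AA, GENO_NOT_BB, GENO_MISSING)

# ---------------------------------------------------------------------------
# configuration


@dataclass
class QtlSpec:
    """One planted trait locus: position plus effect coefficients.

    ``a`` is half the homozygote difference (domestic minus wild), ``d`` the
    heterozygote deviation from the homozygote midpoint; ``a_by_sex`` /
    ``d_by_sex`` multiply the +/-1 sex code (male = +1).
    """
    trait: str
    chrom: str
    cm: float
    a: float = 0.0
    d: float = 0.0
    a_by_sex: float = 0.0
    d_by_sex: float = 0.0


@dataclass
class EpistasisSpec:
    """A planted two-locus interaction on the additive-by-additive product."""
    trait: str
    chrom1: str
    cm1: float
    chrom2: str
    cm2: float
    aa: float = 0.0   # coefficient on x_a1 * x_a2
    dd: float = 0.0   # coefficient on x_d1 * x_d2


@dataclass
class EqtlSpec:
    """One planted expression locus for a probeset."""
    probeset: str
    kind: str                 # "local" | "trans"
    chrom: str
    cm: float
    a: float = 0.0
    d: float = 0.0
    a_by_sex: float = 0.0
    d_by_sex: float = 0.0


@dataclass
class HotspotSpec:
    """A mediated trans-hotspot: a genotype drives a local mediator gene whose
    expression propagates to downstream target probesets."""
    mediator_probeset: str
    chrom: str
    cm: float
    mediator_a: float = 1.0
    mediator_noise_sd: float = 0.5
    targets: dict = field(default_factory=dict)   # probeset -> slope beta
    female_specific: bool = False


@dataclass
class CausalGeneSpec:
    """A gene whose expression both has a local eQTL and feeds a trait.

    The latent transcript level ``g = a * x_a + N(0, noise_sd)`` is added to
    the probeset's expression row (for assayed individuals) and
    ``slope * g`` is added to the trait (for all individuals), creating a
    genotype -> expression -> trait chain for candidate-gene recovery.
    """
    probeset: str
    trait: str
    chrom: str
    cm: float
    a: float = 1.0
    noise_sd: float = 1.0
    slope: float = 1.0


@dataclass
class TraitSpec:
    name: str
    mean: float = 0.0
    residual_sd: float = 1.0
    sex_offset: float = 0.0   # coefficient on the +/-1 sex code


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults emulate the real cross at a desk-friendly scale: an F8 advanced
    intercross propagated at ~100 individuals per generation, a marker map
    with ~15 cM spacing and ~15% partially informative markers, six rearing
    batches, and a two-colour expression assay on a subset of individuals.
    """
    generations: int = 8
    pop_size: int = 100
    n_final: int = 300
    chrom_lengths_cm: tuple = (400.0, 300.0, 250.0, 200.0, 200.0, 150.0)
    markers_per_chrom: int = 20
    mb_per_cm: float = 0.11       # physical:genetic scale of the expanded map
    frac_partial: float = 0.15    # markers observed as dominant (not-AA / not-BB)
    missing_rate: float = 0.01
    seed: int = 0
    n_batches: int = 6
    batch_sd_frac: float = 0.3   # per-trait batch-effect SD as a fraction of residual SD
    traits: tuple = ()
    trait_qtl: tuple = ()
    epistasis: tuple = ()
    # expression block
    n_probesets: int = 3000
    n_expr_individuals: int = 130
    expr_noise_sd: float = 1.0
    expr_batch_sd: float = 0.3
    expr_dye_sd: float = 0.2
    eqtl: tuple = ()
    hotspots: tuple = ()
    causal_genes: tuple = ()


def additive_effect_for_variance_fraction(frac: float, other_sd: float,
                                          var_xa: float = 0.5) -> float:
    """Additive coefficient so a single QTL explains ``frac`` of trait variance.

    ``other_sd`` is the standard deviation of everything else on the trait
    scale (residual noise plus sex, batch and any other planted components),
    so the fraction is of the total phenotypic variance — the scale on which
    variance-explained estimates are reported. Solves
    a^2 var(x_a) / (a^2 var(x_a) + other_sd^2) = frac; at allele frequency
    1/2 the additive score variance is 1/2.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    return other_sd * np.sqrt(frac / ((1.0 - frac) * var_xa))


def make_map(chrom_lengths_cm, markers_per_chrom: int, mb_per_cm: float) -> GeneticMap:
    """Equally spaced markers per chromosome, with proportional Mb positions."""
    rows, names = [], []
    for i, length in enumerate(chrom_lengths_cm, start=1):
        cm = np.linspace(0.0, float(length), markers_per_chrom)
        for j, pos in enumerate(cm, start=1):
            names.append(f"c{i}m{j}")
            rows.append((str(i), float(pos), float(pos) * mb_per_cm))
    return GeneticMap(pd.DataFrame(rows, columns=["chrom", "cm", "mb"],
                                   index=pd.Index(names, name="marker")))


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The bundled study architecture.

    Four mass traits (w8/w42/w112/w212) with a shared major locus on
    chromosome 1 ("growth1"-like, ~9% of variance in intermediate mass), a
    sex-interacting locus, one epistatic pair, and an expression block with
    local eQTL (16% effect scale), trans eQTL and one mediated hotspot.
    """
    traits = (
        TraitSpec("w8", mean=60.0, residual_sd=8.0, sex_offset=2.0),
        TraitSpec("w42", mean=460.0, residual_sd=60.0, sex_offset=40.0),
        TraitSpec("w112", mean=1200.0, residual_sd=150.0, sex_offset=180.0),
        TraitSpec("w212", mean=1700.0, residual_sd=200.0, sex_offset=260.0),
    )
    # size effects against total phenotypic variance (noise + sex + batch)
    def other_sd(t: TraitSpec, batch_frac: float = 0.3) -> float:
        return float(np.sqrt((1.0 + batch_frac ** 2) * t.residual_sd ** 2
                             + t.sex_offset ** 2))

    sd = {t.name: other_sd(t) for t in traits}
    a9 = additive_effect_for_variance_fraction(0.09, sd["w112"])
    qtl = (
        QtlSpec("w42", "1", 200.0, a=additive_effect_for_variance_fraction(0.06, sd["w42"])),
        QtlSpec("w112", "1", 200.0, a=a9, d=0.2 * a9),
        QtlSpec("w212", "1", 200.0, a=additive_effect_for_variance_fraction(0.08, sd["w212"])),
        QtlSpec("w112", "2", 120.0, a=0.0, d=0.0,
                a_by_sex=additive_effect_for_variance_fraction(0.05, sd["w112"])),
        QtlSpec("w212", "3", 80.0, a=additive_effect_for_variance_fraction(0.04, sd["w212"])),
    )
    epi = (EpistasisSpec("w212", "4", 100.0, "5", 100.0,
                         aa=additive_effect_for_variance_fraction(
                             0.06, sd["w212"], var_xa=0.25)),)
    # expression architecture: probeset ids ps0001..; planted loci on early ids
    eqtl = []
    rng = np.random.default_rng(987654321)   # architecture layout, not data noise
    a16 = additive_effect_for_variance_fraction(0.16, 1.0)
    n_local, n_trans = 200, 40
    chroms = [str(i) for i in range(1, 7)]
    lengths = dict(zip(chroms, (400.0, 300.0, 250.0, 200.0, 200.0, 150.0)))
    for k in range(n_local):
        c = chroms[k % 6]
        sign = 1.0 if rng.random() < 0.5 else -1.0   # no directional bias
        eqtl.append(EqtlSpec(f"ps{k + 1:04d}", "local", c,
                             float(rng.uniform(0, lengths[c])), a=sign * a16,
                             d=float(rng.normal(0, 0.2)) * a16,
                             a_by_sex=sign * 0.5 * a16 if k % 2 else 0.0))
    for k in range(n_trans):
        c = chroms[(k + 3) % 6]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        eqtl.append(EqtlSpec(f"ps{n_local + k + 1:04d}", "trans", c,
                             float(rng.uniform(0, lengths[c])), a=sign * 1.2 * a16,
                             d=-0.4 * a16))
    hot = HotspotSpec("ps0500", "5", 100.0, mediator_a=1.6, mediator_noise_sd=0.5,
                      targets={f"ps{600 + i:04d}": 1.0 for i in range(8)})
    causal = (CausalGeneSpec("ps0300", "w42", "1", 200.0, a=1.2, noise_sd=0.8,
                             slope=0.35 * sd["w42"] / np.sqrt(1.2 ** 2 * 0.5 + 0.64)),)
    cfg = SimConfig(seed=seed, traits=traits, trait_qtl=qtl, epistasis=epi,
                    eqtl=tuple(eqtl), hotspots=(hot,), causal_genes=causal,
                    **overrides)
    return cfg


# ---------------------------------------------------------------------------
# meiosis and population propagation


def simulate_meiosis(haplotypes: np.ndarray, positions_cm: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """One gamete from a pair of parental haplotypes on one chromosome.

    ``haplotypes`` is (2, n_markers). Crossover count is Poisson with mean
    length/100 (Haldane; no interference), crossover positions uniform on the
    chromosome, starting strand chosen at random.
    """
    if haplotypes.shape[1] == 0:
        raise ValueError("empty chromosome")
    pos = np.asarray(positions_cm, dtype=float)
    length = pos[-1] - pos[0]
    n_xo = rng.poisson(length / 100.0) if length > 0 else 0
    strand = np.full(len(pos), rng.integers(2), dtype=np.int8)
    if n_xo:
        xo = np.sort(rng.uniform(pos[0], pos[-1], size=n_xo))
        # switch strand after each crossover
        strand = (strand[0] + np.searchsorted(xo, pos, side="right")) % 2
    return haplotypes[strand, np.arange(len(pos))]


def simulate_ail(config: SimConfig, rng: np.random.Generator | None = None):
    """Propagate the intercross and return final-generation genotypes.

    Returns ``(dosage, gmap)`` where dosage is (n_final, n_markers) counts of
    the domestic (B) founder allele in {0, 1, 2}. Founders are fully inbred
    and fixed for alternative alleles, so the F1 is uniformly heterozygous;
    generations 2..G are produced by random mating excluding selfing; the
    final generation is expanded to ``n_final`` offspring of the previous one.
    """
    if config.pop_size < 2:
        raise ValueError("population size must be >= 2")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gmap = make_map(config.chrom_lengths_cm, config.markers_per_chrom, config.mb_per_cm)
    chrom_index = [np.flatnonzero((gmap.markers["chrom"] == c).to_numpy())
                   for c in gmap.chromosomes]
    chrom_pos = [gmap.markers["cm"].to_numpy()[ix] for ix in chrom_index]
    n_mark = len(gmap.markers)

    # haplotype pool: (n, 2, n_mark) of founder origins; F1 = (all-0, all-1)
    pop = np.zeros((config.pop_size, 2, n_mark), dtype=np.int8)
    pop[:, 1, :] = 1
    for gen in range(2, config.generations + 1):
        size = config.n_final if gen == config.generations else config.pop_size
        pop = _next_generation(pop, size, chrom_index, chrom_pos, rng)
    return pop.sum(axis=1), gmap


def _next_generation(pop, size, chrom_index, chrom_pos, rng):
    n = len(pop)
    sires = rng.integers(n, size=size)
    dams = (sires + 1 + rng.integers(n - 1, size=size)) % n   # non-self
    out = np.empty((size, 2, pop.shape[2]), dtype=np.int8)
    for i, (s, d) in enumerate(zip(sires, dams)):
        for parent, slot in ((s, 0), (d, 1)):
            for ix, pos in zip(chrom_index, chrom_pos):
                out[i, slot, ix] = simulate_meiosis(pop[parent][:, ix], pos, rng)
    return out


def observe_genotypes(dosage: np.ndarray, gmap: GeneticMap, config: SimConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Apply marker informativeness and missingness to true dosages.

    A ``frac_partial`` share of markers behaves as dominant: one homozygote is
    indistinguishable from the heterozygote, yielding not-AA / not-BB codes.
    """
    n_mark = dosage.shape[1]
    codes = np.array([GENO_AA, GENO_AB, GENO_BB], dtype=np.int8)[dosage]
    n_partial = int(round(config.frac_partial * n_mark))
    partial = rng.choice(n_mark, size=n_partial, replace=False)
    direction = rng.integers(2, size=n_partial)
    for j, d in zip(partial, direction):
        col = codes[:, j]
        if d == 0:   # cannot distinguish AB from BB
            col[(col == GENO_AB) | (col == GENO_BB)] = GENO_NOT_AA
        else:        # cannot distinguish AA from AB
            col[(col == GENO_AA) | (col == GENO_AB)] = GENO_NOT_BB
    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes[mask] = GENO_MISSING
    return codes


# ---------------------------------------------------------------------------
# traits and expression


def _locus_scores(dosage, gmap, chrom, cm):
    """(x_a, x_d, marker) at the marker nearest the requested position."""
    sub = gmap.chrom_markers(str(chrom))
    k = int(np.argmin(np.abs(sub["cm"].to_numpy() - cm)))
    marker = sub.index[k]
    col = dosage[:, gmap.markers.index.get_loc(marker)]
    return (col - 1.0).astype(float), (col == 1).astype(float), marker


def causal_latents(dosage: np.ndarray, gmap: GeneticMap, config: SimConfig,
                   rng: np.random.Generator) -> dict:
    """Latent transcript values for causal genes, for all individuals."""
    out = {}
    for cg in config.causal_genes:
        x_a, _, marker = _locus_scores(dosage, gmap, cg.chrom, cg.cm)
        out[cg.probeset] = (cg.a * x_a
                            + rng.normal(0.0, cg.noise_sd, size=len(x_a)), marker)
    return out


def simulate_traits(dosage: np.ndarray, gmap: GeneticMap, config: SimConfig,
                    rng: np.random.Generator, latents: dict | None = None):
    """Phenotype and covariate tables for the final generation.

    The model per trait is ``y = mean + batch + sex_offset*sex
    + sum_q [a x_a + d x_d + (a_by_sex x_a + d_by_sex x_d) sex]
    + sum_pairs [aa x_a1 x_a2 + dd x_d1 x_d2] + N(0, residual_sd^2)`` with
    sex coded male = +1, female = -1.
    """
    n = dosage.shape[0]
    sex = rng.permutation(np.repeat([1.0, -1.0], [n - n // 2, n // 2]))
    batch = rng.integers(config.n_batches, size=n)
    pheno = {}
    truth_rows = []
    for spec in config.traits:
        batch_effects = rng.normal(0.0, config.batch_sd_frac * spec.residual_sd,
                                   size=config.n_batches)
        y = (spec.mean + batch_effects[batch] + spec.sex_offset * sex
             + rng.normal(0.0, spec.residual_sd, size=n))
        for q in config.trait_qtl:
            if q.trait != spec.name:
                continue
            x_a, x_d, marker = _locus_scores(dosage, gmap, q.chrom, q.cm)
            y += (q.a * x_a + q.d * x_d + (q.a_by_sex * x_a + q.d_by_sex * x_d) * sex)
            truth_rows.append(dict(trait=q.trait, chrom=str(q.chrom), cm=q.cm,
                                   marker=marker, a=q.a, d=q.d,
                                   a_by_sex=q.a_by_sex, d_by_sex=q.d_by_sex))
        for e in config.epistasis:
            if e.trait != spec.name:
                continue
            xa1, xd1, _ = _locus_scores(dosage, gmap, e.chrom1, e.cm1)
            xa2, xd2, _ = _locus_scores(dosage, gmap, e.chrom2, e.cm2)
            y += e.aa * xa1 * xa2 + e.dd * xd1 * xd2
        for cg in config.causal_genes:
            if cg.trait == spec.name and latents and cg.probeset in latents:
                y += cg.slope * latents[cg.probeset][0]
        pheno[spec.name] = y
    index = pd.RangeIndex(n, name="id")
    covar = pd.DataFrame({
        "sex": np.where(sex > 0, "male", "female"),
        "batch": [f"b{b + 1}" for b in batch]}, index=index)
    truth = pd.DataFrame(truth_rows, columns=["trait", "chrom", "cm", "marker",
                                              "a", "d", "a_by_sex", "d_by_sex"])
    return pd.DataFrame(pheno, index=index), covar, truth


def simulate_expression(dosage: np.ndarray, gmap: GeneticMap, covar: pd.DataFrame,
                        config: SimConfig, rng: np.random.Generator,
                        latents: dict | None = None):
    """Expression matrix, probeset annotation and truth tables.

    Planted signal: local eQTL shift a probeset's mean by genotype at a
    marker near its annotated position; trans eQTL use a distant marker; a
    mediated hotspot generates a mediator transcript from genotype and feeds
    downstream targets linearly from the mediator's value (so conditioning on
    the mediator removes the genotype signal). Batch and dye offsets and
    Gaussian noise are added on top.
    """
    n_all = dosage.shape[0]
    n_expr = min(config.n_expr_individuals, n_all)
    expr_ids = np.sort(rng.choice(n_all, size=n_expr, replace=False))
    sex = np.where(covar["sex"].to_numpy()[expr_ids] == "male", 1.0, -1.0)
    dye = rng.integers(2, size=n_expr)
    batch_lab = covar["batch"].to_numpy()[expr_ids]
    batches = sorted(set(batch_lab))
    batch_eff = dict(zip(batches, rng.normal(0, config.expr_batch_sd, len(batches))))
    dye_eff = rng.normal(0, config.expr_dye_sd)

    probesets = [f"ps{k + 1:04d}" for k in range(config.n_probesets)]
    base = rng.normal(8.0, 1.0, size=config.n_probesets)
    tech = (np.array([batch_eff[b] for b in batch_lab])
            + dye_eff * (dye * 2.0 - 1.0))          # per-sample technical offset
    expr = (base[:, None] + tech[None, :]
            + rng.normal(0.0, config.expr_noise_sd,
                         size=(config.n_probesets, n_expr)))

    ps_index = {p: i for i, p in enumerate(probesets)}
    # annotation: planted local eQTL sit at their locus; everything else random
    chroms = gmap.chromosomes
    ann_chrom = [chroms[rng.integers(len(chroms))] for _ in probesets]
    ann_cm = [float(rng.uniform(*gmap.chrom_span_cm(c))) for c in ann_chrom]
    eqtl_rows = []
    for q in config.eqtl:
        if q.probeset not in ps_index:
            continue
        i = ps_index[q.probeset]
        x_a, x_d, marker = _locus_scores(dosage, gmap, q.chrom, q.cm)
        x_a, x_d = x_a[expr_ids], x_d[expr_ids]
        expr[i] += (q.a * x_a + q.d * x_d
                    + (q.a_by_sex * x_a + q.d_by_sex * x_d) * sex)
        if q.kind == "local":
            ann_chrom[i] = str(q.chrom)
            ann_cm[i] = float(q.cm)
        else:
            # make sure a trans target is annotated away from its locus
            far = [c for c in chroms if c != str(q.chrom)]
            ann_chrom[i] = far[rng.integers(len(far))]
            ann_cm[i] = float(rng.uniform(*gmap.chrom_span_cm(ann_chrom[i])))
        eqtl_rows.append(dict(probeset=q.probeset, kind=q.kind, chrom=str(q.chrom),
                              cm=q.cm, marker=marker, a=q.a, d=q.d,
                              a_by_sex=q.a_by_sex, d_by_sex=q.d_by_sex))

    med_rows = []
    for h in config.hotspots:
        i = ps_index[h.mediator_probeset]
        x_a, _, marker = _locus_scores(dosage, gmap, h.chrom, h.cm)
        x_a = x_a[expr_ids]
        gate = (sex < 0).astype(float) if h.female_specific else 1.0
        mediator = (h.mediator_a * x_a * gate
                    + rng.normal(0.0, h.mediator_noise_sd, size=n_expr))
        expr[i] += mediator
        ann_chrom[i], ann_cm[i] = str(h.chrom), float(h.cm)
        # targets inherit the mediator's *observed* signal (its expression
        # net of baseline and technical offsets), so conditioning on the
        # measured mediator expression removes the genotype effect
        med_observed = expr[i] - base[i] - tech
        for target, beta in h.targets.items():
            j = ps_index[target]
            expr[j] += beta * med_observed
            far = [c for c in chroms if c != str(h.chrom)]
            ann_chrom[j] = far[rng.integers(len(far))]
            ann_cm[j] = float(rng.uniform(*gmap.chrom_span_cm(ann_chrom[j])))
            med_rows.append(dict(mediator=h.mediator_probeset, target=target,
                                 slope=beta, chrom=str(h.chrom), cm=h.cm,
                                 marker=marker))

    causal_rows = []
    for cg in config.causal_genes:
        if latents is None or cg.probeset not in latents or \
                cg.probeset not in ps_index:
            continue
        i = ps_index[cg.probeset]
        values, marker = latents[cg.probeset]
        expr[i] += values[expr_ids]
        ann_chrom[i], ann_cm[i] = str(cg.chrom), float(cg.cm)
        eqtl_rows.append(dict(probeset=cg.probeset, kind="local",
                              chrom=str(cg.chrom), cm=cg.cm, marker=marker,
                              a=cg.a, d=0.0, a_by_sex=0.0, d_by_sex=0.0))
        causal_rows.append(dict(probeset=cg.probeset, trait=cg.trait,
                                chrom=str(cg.chrom), cm=cg.cm, marker=marker,
                                a=cg.a, slope=cg.slope))

    ann_mb = [GeneticMap.cm_to_mb(gmap, c, p) for c, p in zip(ann_chrom, ann_cm)]
    annotation = pd.DataFrame(
        {"probeset": probesets, "gene": [f"GENE{k + 1:04d}" for k in range(len(probesets))],
         "chrom": ann_chrom, "cm": ann_cm, "mb": ann_mb}).set_index("probeset")
    expression = pd.DataFrame(expr, index=pd.Index(probesets, name="probeset"),
                              columns=pd.Index(expr_ids, name="id"))
    expr_covar = pd.DataFrame(
        {"sex": np.where(sex > 0, "male", "female"), "batch": batch_lab,
         "dye": np.where(dye == 1, "Cy5", "Cy3")},
        index=expression.columns)
    truth = {"eqtl": pd.DataFrame(eqtl_rows, columns=["probeset", "kind", "chrom",
                                                      "cm", "marker", "a", "d",
                                                      "a_by_sex", "d_by_sex"]),
             "mediation": pd.DataFrame(med_rows, columns=["mediator", "target",
                                                          "slope", "chrom", "cm",
                                                          "marker"]),
             "causal_genes": pd.DataFrame(causal_rows,
                                          columns=["probeset", "trait", "chrom",
                                                   "cm", "marker", "a", "slope"])}
    return expression, annotation, expr_covar, truth


# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """A complete simulated dataset plus the planted truth."""
    cross: Cross
    expression: pd.DataFrame | None
    annotation: pd.DataFrame | None
    expr_covar: pd.DataFrame | None
    truth: dict
    config: SimConfig


def simulate_study(config: SimConfig | None = None, seed: int | None = None,
                   with_expression: bool = True) -> SimulatedStudy:
    """Run the whole generator under one seed and return Cross + expression + truth."""
    config = config or default_config(seed=0 if seed is None else seed)
    if seed is not None:
        config = SimConfig(**{**asdict_shallow(config), "seed": seed})
    rng = np.random.default_rng(config.seed)
    dosage, gmap = simulate_ail(config, rng)
    codes = observe_genotypes(dosage, gmap, config, rng)
    latents = causal_latents(dosage, gmap, config, rng)
    pheno, covar, trait_truth = simulate_traits(dosage, gmap, config, rng, latents)
    index = pheno.index
    geno = pd.DataFrame(codes, index=index, columns=gmap.markers.index)
    cross = Cross(gmap, geno, pheno, covar,
                  metadata={"seed": config.seed, "generations": config.generations,
                            "sex_coding": "male=+1,female=-1",
                            "mating": "random non-self pairs (stand-in design)"})
    truth = {"trait_qtl": trait_truth,
             "epistasis": pd.DataFrame([vars(e) for e in config.epistasis])}
    expression = annotation = expr_covar = None
    if with_expression and config.n_probesets > 0:
        expression, annotation, expr_covar, etruth = simulate_expression(
            dosage, gmap, covar, config, rng, latents)
        truth.update(etruth)
    return SimulatedStudy(cross, expression, annotation, expr_covar, truth, config)


def asdict_shallow(config: SimConfig) -> dict:
    """SimConfig fields without recursing into the nested spec dataclasses."""
    return {f: getattr(config, f) for f in config.__dataclass_fields__}


def config_to_dict(config: SimConfig) -> dict:
    """Fully nested dict (YAML/JSON-serializable) for provenance output."""
    return asdict(config)
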