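"""End-to-end pipeline orchestration.

Each stage reads its inputs from (and writes its outputs to) the run
directory, so stages can be re-run individually from cached intermediates;
``run_pipeline`` chains them. All randomness is seeded from the config and
a resolved copy of the configuration is written next to the outputs.

Stage outputs (all headered CSV):

- simulate:  cross.csv, expression.csv, annotation.csv, expr_covar.csv,
             truth_*.csv
- scan:      scans.csv (LOD curves, long), thresholds.csv, qtl.csv
             (per-trait loci with effects, intervals and variance explained),
             qtl_regions.csv (overlap-merged regions)
- eqtl:      eqtl_thresholds.csv, eqtl.csv, effect_directions.csv
- hotspots:  hotspots.csv, mediation.csv, network_nodes.csv, network_edges.csv
- integrate: candidates.csv, twa.csv, sweep_overlap.csv
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossio, simcross, genoprob, scanqtl, eqtlscan, hotspots, integrate

log = logging.getLogger("ailqtl")

GROWTH_SCAN_TRAITS = ("w42", "w112", "w212", "g8.42", "g42.112", "g112.212")


@dataclass
class PipelineConfig:
    """Resolved settings for a pipeline run.

    Defaults carry the analysis constants: a 100 cM local eQTL window
    (+/-50), the >10-individuals genotype-class filter, the LOD > 1 rule for
    sex interactions, 1.8-LOD support intervals, and a 1 Gb random-placement
    null genome for hotspots.
    """
    out_dir: str = "ailqtl_run"
    cross_csv: str | None = None
    expression_csv: str | None = None
    annotation_csv: str | None = None
    expr_covar_csv: str | None = None
    sweeps_csv: str | None = None
    simulate: bool = False
    sim_seed: int = 0
    sim_overrides: dict = field(default_factory=dict)
    seed: int = 0
    step_cm: float = 1.0
    error_rate: float = 0.001
    traits: tuple = GROWTH_SCAN_TRAITS
    n_perm: int = 1000
    alphas: tuple = (0.05, 0.20)
    lod_drop: float = 1.8
    scan2_step_cm: float = 5.0
    run_scan2: bool = False
    eqtl_window_cm: float = 50.0
    eqtl_min_class: int = 10
    eqtl_n_perm: int = 200
    eqtl_subsample: int = 100
    sex_delta_lod: float = 1.0
    hotspot_bin_mb: float = 0.1
    hotspot_genome_mb: float = 1000.0
    hotspot_n_sim: int = 1000
    sweep_n_sim: int = 1000
    candidate_alpha: float = 0.05
    twa_n_perm: int = 500

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def dump(self, path) -> None:
        data = dataclasses.asdict(self)
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _load_cross(config: PipelineConfig, out: Path) -> crossio.Cross:
    path = out / "cross.csv" if (out / "cross.csv").exists() else config.cross_csv
    if path is None:
        raise FileNotFoundError("no cross data: set cross_csv or run simulate")
    cross = crossio.read_cross_csv(path)
    have = set(cross.pheno.columns)
    if {"w8", "w42", "w112", "w212"} <= have and "g8.42" not in have:
        cross = crossio.derive_growth_traits(cross)
    return cross


def stage_simulate(config: PipelineConfig) -> Path:
    out = _outdir(config)
    sim_cfg = simcross.default_config(seed=config.sim_seed, **config.sim_overrides)
    study = simcross.simulate_study(sim_cfg)
    crossio.write_cross_csv(study.cross, out / "cross.csv")
    if study.expression is not None:
        study.expression.to_csv(out / "expression.csv")
        study.annotation.to_csv(out / "annotation.csv")
        study.expr_covar.to_csv(out / "expr_covar.csv")
    for name, table in study.truth.items():
        table.to_csv(out / f"truth_{name}.csv", index=False)
    # the written R/qtl csv drops physical positions; keep them beside it
    study.cross.gmap.markers.to_csv(out / "map.csv")
    log.info("simulate: %d individuals, %d markers",
             study.cross.n_individuals, study.cross.n_markers)
    return out


def _genoprob_for(cross, config):
    return genoprob.calc_genoprob(cross, step_cm=config.step_cm,
                                  error_rate=config.error_rate)


def _attach_map_mb(cross: crossio.Cross, out: Path) -> None:
    map_csv = out / "map.csv"
    if map_csv.exists() and cross.gmap.markers["mb"].isna().all():
        mb = pd.read_csv(map_csv, index_col=0)["mb"]
        cross.gmap.markers["mb"] = mb.reindex(cross.gmap.markers.index).to_numpy()


def stage_scan(config: PipelineConfig) -> Path:
    out = _outdir(config)
    cross = _load_cross(config, out)
    _attach_map_mb(cross, out)
    gp = _genoprob_for(cross, config)
    scan_rows, thr_rows, qtl_rows, region_rows = [], [], [], []
    for ti, trait in enumerate(config.traits):
        if trait not in cross.pheno.columns:
            log.warning("scan: trait %s missing, skipped", trait)
            continue
        pcs = scanqtl.family_pcs(cross, trait)
        cov = scanqtl.build_covariates(cross, pcs=pcs if len(pcs.columns) else None)
        thr = scanqtl.permutation_thresholds(
            cross, gp, trait, cov, n_perm=config.n_perm,
            alphas=config.alphas, seed=config.seed + 1000 * ti)
        scan = scanqtl.scan_one(cross, gp, trait, cov)
        for a, t in thr.thresholds.items():
            thr_rows.append(dict(trait=trait, alpha=a, threshold=t))
        scan_rows.append(pd.DataFrame(
            {"trait": trait, "chrom": scan.grid["chrom"],
             "pos_cm": scan.grid["pos_cm"], "lod": scan.lod}))
        peaks = scan.chrom_peaks(thr.significant)
        if len(peaks):
            pairs = None
            if config.run_scan2:
                s2 = scanqtl.scan_two(cross, gp, trait, cov,
                                      step_cm=config.scan2_step_cm)
                pairs = s2.declared_pairs()
            fit = scanqtl.fit_multiqtl(
                cross, gp, trait, peaks.rename(columns={"pos_cm": "pos_cm"}),
                cov, pairs=pairs, drop_one_threshold=thr.significant,
                sex_delta_lod=config.sex_delta_lod)
            for _, locus in fit.loci.iterrows():
                ivl = scanqtl.lod_interval(scan, cross, locus["chrom"],
                                           drop=config.lod_drop,
                                           peak_cm=locus["cm"])
                row = dict(trait=trait, **locus.to_dict(),
                           ci_lo_cm=ivl.lo_cm, ci_hi_cm=ivl.hi_cm,
                           ci_lo_mb=ivl.lo_mb, ci_hi_mb=ivl.hi_mb,
                           whole_chromosome=ivl.whole_chromosome,
                           model_var_explained_pct=fit.model_var_explained_pct)
                qtl_rows.append(row)
                if ivl.lo_mb is not None:
                    region_rows.append(dict(chrom=locus["chrom"],
                                            lo_mb=ivl.lo_mb, hi_mb=ivl.hi_mb))
    pd.concat(scan_rows, ignore_index=True).to_csv(out / "scans.csv", index=False)
    pd.DataFrame(thr_rows).to_csv(out / "thresholds.csv", index=False)
    qtl = pd.DataFrame(qtl_rows)
    qtl.to_csv(out / "qtl.csv", index=False)
    regions = scanqtl.merge_regions(pd.DataFrame(
        region_rows, columns=["chrom", "lo_mb", "hi_mb"])) if region_rows \
        else pd.DataFrame(columns=["chrom", "lo_mb", "hi_mb", "n_members"])
    regions.to_csv(out / "qtl_regions.csv", index=False)
    log.info("scan: %d QTL in %d regions", len(qtl), len(regions))
    return out


def _load_expression(config: PipelineConfig, out: Path):
    def pick(name, fallback):
        p = out / name
        return p if p.exists() else fallback
    e = pick("expression.csv", config.expression_csv)
    a = pick("annotation.csv", config.annotation_csv)
    c = pick("expr_covar.csv", config.expr_covar_csv)
    if e is None:
        return None
    expression = pd.read_csv(e, index_col=0)
    expr_covar = pd.read_csv(c, index_col=0) if c else None
    annotation = pd.read_csv(a, index_col=0) if a else pd.DataFrame(
        columns=["gene", "chrom", "cm", "mb"])
    expression.columns = expression.columns.astype(str)
    if expr_covar is not None:
        expr_covar.index = expr_covar.index.astype(str)
    return expression, annotation, expr_covar


def _align_expression(cross, expression, expr_covar):
    cross_ids = cross.geno.index.astype(str)
    cross.geno.index = cross_ids
    cross.pheno.index = cross_ids
    cross.covar.index = cross_ids
    ids = [i for i in expression.columns if i in set(cross_ids)]
    return expression[ids], expr_covar.loc[ids]


def stage_eqtl(config: PipelineConfig) -> Path:
    out = _outdir(config)
    loaded = _load_expression(config, out)
    if loaded is None:
        log.warning("eqtl: no expression data, stage skipped")
        return out
    expression, annotation, expr_covar = loaded
    cross = _load_cross(config, out)
    _attach_map_mb(cross, out)
    expression, expr_covar = _align_expression(cross, expression, expr_covar)
    ecross = eqtlscan.expression_cross(cross, expression, expr_covar)
    gp = _genoprob_for(ecross, config)
    thr = eqtlscan.subsampled_thresholds(
        cross, expression, expr_covar, gp, annotation,
        n_probesets=min(config.eqtl_subsample, len(expression)),
        n_reps=config.eqtl_n_perm, seed=config.seed,
        window_cm=config.eqtl_window_cm)
    pd.DataFrame([{"local": thr.local, "trans": thr.trans,
                   "n_reps": thr.n_reps, "seed": thr.seed}]).to_csv(
        out / "eqtl_thresholds.csv", index=False)
    records = eqtlscan.scan_all_probesets(
        cross, expression, expr_covar, gp, annotation, thr.local, thr.trans,
        window_cm=config.eqtl_window_cm, min_class=config.eqtl_min_class)
    eqtlscan.records_to_frame(records).to_csv(out / "eqtl.csv", index=False)
    eqtlscan.effect_direction_summary(records).to_csv(
        out / "effect_directions.csv", index=False)
    log.info("eqtl: %d records (local %d, distal %d)", len(records),
             sum(r.kind == "local" for r in records),
             sum(r.kind == "distal" for r in records))
    return out


def _records_from_csv(path) -> list:
    df = pd.read_csv(path)
    recs = []
    for _, r in df.iterrows():
        recs.append(eqtlscan.EqtlRecord(
            str(r["probeset"]), r["kind"], str(r["chrom"]), r["peak_cm"],
            r["peak_mb"], r["lod"], r["ci_lo_cm"], r["ci_hi_cm"],
            r["ci_lo_mb"], r["ci_hi_mb"], bool(r["sex_interaction"]),
            r["a"], r["d"], r["a_by_sex"], r["d_by_sex"],
            {"AA": int(r["min_class_count"]), "AB": int(r["min_class_count"]),
             "BB": int(r["min_class_count"])}))
    return recs


def _chrom_lengths_mb(cross) -> dict:
    lengths = {}
    for chrom in cross.gmap.chromosomes:
        mb = cross.gmap.chrom_markers(chrom)["mb"].dropna()
        if len(mb):
            lengths[str(chrom)] = float(mb.max())
    return lengths


def stage_hotspots(config: PipelineConfig) -> Path:
    out = _outdir(config)
    eqtl_csv = out / "eqtl.csv"
    if not eqtl_csv.exists():
        log.warning("hotspots: no eqtl.csv, stage skipped")
        return out
    records = _records_from_csv(eqtl_csv)
    cross = _load_cross(config, out)
    _attach_map_mb(cross, out)
    distal = [r for r in records if r.kind == "distal"]
    local = [r for r in records if r.kind == "local"]
    calls, null = hotspots.call_hotspots(
        distal, _chrom_lengths_mb(cross), bin_mb=config.hotspot_bin_mb,
        genome_length_mb=config.hotspot_genome_mb,
        n_sim=config.hotspot_n_sim, seed=config.seed)
    pd.DataFrame([{"chrom": c.chrom, "lo_mb": c.lo_mb, "hi_mb": c.hi_mb,
                   "peak_coverage": c.peak_coverage, "threshold": c.threshold,
                   "n_members": len(c.members),
                   "members": ";".join(c.members)} for c in calls]).to_csv(
        out / "hotspots.csv", index=False)
    med_results = []
    loaded = _load_expression(config, out)
    if loaded is not None and calls:
        expression, annotation, expr_covar = loaded
        expression, expr_covar = _align_expression(cross, expression, expr_covar)
        ecross = eqtlscan.expression_cross(cross, expression, expr_covar)
        gp = _genoprob_for(ecross, config)
        for call in calls:
            med_results.extend(hotspots.mediate_hotspot(
                call, local, distal, cross, expression, expr_covar, gp))
    pd.DataFrame([dataclasses.asdict(m) for m in med_results]).to_csv(
        out / "mediation.csv", index=False)
    nodes, edges, _ = hotspots.export_network(calls, med_results)
    nodes.to_csv(out / "network_nodes.csv", index=False)
    edges.to_csv(out / "network_edges.csv", index=False)
    log.info("hotspots: %d calls, %d mediation tests (%d flagged)",
             len(calls), len(med_results),
             sum(m.mediator_flag for m in med_results))
    return out


def stage_integrate(config: PipelineConfig) -> Path:
    out = _outdir(config)
    qtl_csv = out / "qtl.csv"
    if not qtl_csv.exists():
        log.warning("integrate: no qtl.csv, stage skipped")
        return out
    qtl = pd.read_csv(qtl_csv)
    cross = _load_cross(config, out)
    _attach_map_mb(cross, out)
    if len(qtl) == 0:
        qtl_intervals = pd.DataFrame(columns=["trait", "chrom", "lo_mb", "hi_mb"])
    else:
        qtl_intervals = qtl.rename(columns={"ci_lo_mb": "lo_mb",
                                            "ci_hi_mb": "hi_mb"})[
            ["trait", "chrom", "lo_mb", "hi_mb"]].dropna()
    qtl_intervals["chrom"] = qtl_intervals["chrom"].astype(str)
    loaded = _load_expression(config, out)
    if loaded is not None and (out / "eqtl.csv").exists():
        expression, annotation, expr_covar = loaded
        expression, expr_covar = _align_expression(cross, expression, expr_covar)
        eqtl_table = pd.read_csv(out / "eqtl.csv")
        eqtl_table["chrom"] = eqtl_table["chrom"].astype(str)
        cands = integrate.candidate_screen(
            qtl_intervals, eqtl_table, expression, expr_covar, cross,
            annotation=annotation, alpha=config.candidate_alpha)
        cands.to_csv(out / "candidates.csv", index=False)
        traits = cross.pheno[[t for t in config.traits
                              if t in cross.pheno.columns]]
        twa = integrate.transcriptome_wide_association(
            expression, traits, expr_covar, n_perm=config.twa_n_perm,
            seed=config.seed)
        twa.to_csv(out / "twa.csv", index=False)
        log.info("integrate: %d candidates, %d trait-associated probesets",
                 len(cands), len(twa))
    if config.sweeps_csv:
        sweeps = pd.read_csv(config.sweeps_csv)
        sweeps.columns = [c.lower() for c in sweeps.columns]
        sweeps = sweeps.rename(columns={"start": "lo_mb", "end": "hi_mb"})
        lengths = _chrom_lengths_mb(cross)
        rows = []
        for trait, sub in qtl_intervals.groupby("trait"):
            res = integrate.sweep_overlap_test(
                sub, sweeps, lengths, n_sim=config.sweep_n_sim,
                seed=config.seed, trait=trait)
            rows.append(dataclasses.asdict(res))
        pd.DataFrame(rows).to_csv(out / "sweep_overlap.csv", index=False)
    return out


STAGES = {"simulate": stage_simulate, "scan": stage_scan, "eqtl": stage_eqtl,
          "hotspots": stage_hotspots, "integrate": stage_integrate}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every applicable stage in order; returns the output directory."""
    out = _outdir(config)
    config.dump(out / "config_resolved.yaml")
    from . import __version__
    log.info("ailqtl %s | seed=%d sim_seed=%d", __version__, config.seed,
             config.sim_seed)
    timings = {}
    order = (["simulate"] if config.simulate else []) + \
        ["scan", "eqtl", "hotspots", "integrate"]
    for name in order:
        t0 = time.time()
        try:
            STAGES[name](config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.time() - t0, 2)
        log.info("stage %s finished in %.1fs", name, timings[name])
    with open(out / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=2)
    return out
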