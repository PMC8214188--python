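"""End-to-end experiment orchestration: simulate -> thin -> engines ->
evaluate -> slopes -> compare, with full seed provenance and resumable
on-disk artifacts.

Every random step derives its seed deterministically from the master seed,
so re-running a configuration (or resuming it from partial artifacts)
reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import io as dio
from .containers import CountMatrix, TruthTable
from .engines import ENGINES, EngineParams, EngineResult, run_engine
from .evaluation import call_degs, concordance, expression_strata, fold_filter, relative_fdr
from .robustness import (SLOPE_FRACTIONS, conover_posthoc, fit_fdr_slope,
                         friedman_test, make_population, nemenyi_posthoc)
from .simulate import SimulationConfig, generate_dataset
from .thinning import SubsampleSpec, thin_counts

__all__ = [
    "PipelineConfig",
    "run_experiment",
    "run_engines_on",
    "deg_sets",
    "depth_experiment",
    "slope_population_analysis",
    "compare_engines",
]

log = logging.getLogger("dgerobust")

#: posterior_kind by engine name (None = p-value engine)
_ENGINE_KIND = {"noiseq_like": "noise", "eb_nb": "mixture"}

REGIMES = ("no_fold", "two_fold")


# ---------------------------------------------------------------------------
# library-level orchestration


def run_engines_on(counts: CountMatrix, engines, params_map=None) -> dict:
    """Run several engines on one count matrix; returns name -> EngineResult."""
    params_map = params_map or {}
    return {name: run_engine(name, counts, params_map.get(name)) for name in engines}


def deg_sets(result: EngineResult, alpha: float = 0.05, fold_c: float = 2.0,
             f: float = 1.0, r: int = 0, noiseq_q: float = 0.95) -> dict:
    """Both filtering regimes of the significant-DEG set for one result."""
    no_fold = call_degs(result, alpha=alpha, noiseq_q=noiseq_q, f=f, r=r)
    two_fold = fold_filter(no_fold, result, c=fold_c)
    return {"no_fold": no_fold, "two_fold": two_fold}


def depth_experiment(counts: CountMatrix, engines, spec: SubsampleSpec,
                     alpha: float = 0.05, fold_c: float = 2.0,
                     params_map=None, noiseq_q: float = 0.95) -> pd.DataFrame:
    """Thin ``counts`` over the grid and score every engine's relative FDR.

    The full-depth (f = 1) result of each engine defines its TP reference.
    Returns one row per (engine, f, r, regime).
    """
    full_results = run_engines_on(counts, engines, params_map)
    full_sets = {
        name: deg_sets(res, alpha, fold_c, noiseq_q=noiseq_q)
        for name, res in full_results.items()
    }
    rows = []
    for f in spec.fractions:
        for r in range(1, spec.iterations + 1):
            thinned = thin_counts(counts, f, spec.seed_for(f, r))
            for name, res in run_engines_on(thinned, engines, params_map).items():
                sets = deg_sets(res, alpha, fold_c, f=f, r=r, noiseq_q=noiseq_q)
                for regime in REGIMES:
                    rec = relative_fdr(sets[regime], full_sets[name][regime])
                    rows.append(rec.as_dict())
    return pd.DataFrame(rows)


def slope_population_analysis(base: CountMatrix, engines, reps: int = 10,
                              slope_fractions=SLOPE_FRACTIONS, iterations: int = 5,
                              seed: int = 0, alpha: float = 0.05, fold_c: float = 2.0,
                              regime: str = "two_fold", params_map=None,
                              noiseq_q: float = 0.95,
                              per_iteration: bool = False) -> pd.DataFrame:
    """Slope of relative FDR vs f for every engine over a leave-one-out
    population of datasets.

    Per dataset and engine, relative FDR is measured at each fraction of
    ``slope_fractions`` with ``iterations`` thinning replicates; by default
    the per-f values are averaged before the OLS fit (``per_iteration=True``
    fits on all (f, r) points instead).  Returns one row per (engine,
    dataset_id) with slope, intercept and n_points.
    """
    population = make_population(base, reps=reps, seed=seed)
    rows = []
    for d_idx, (dataset_id, cm) in enumerate(population):
        spec = SubsampleSpec(fractions=tuple(slope_fractions), iterations=iterations,
                             master_seed=(int(seed) & 0x3FFFFFF) * 31 + d_idx)
        full_results = run_engines_on(cm, engines, params_map)
        full_sets = {name: deg_sets(res, alpha, fold_c, noiseq_q=noiseq_q)
                     for name, res in full_results.items()}
        points: dict = {name: [] for name in engines}
        for f in spec.fractions:
            for r in range(1, spec.iterations + 1):
                thinned = thin_counts(cm, f, spec.seed_for(f, r))
                for name, res in run_engines_on(thinned, engines, params_map).items():
                    sets = deg_sets(res, alpha, fold_c, f=f, r=r, noiseq_q=noiseq_q)
                    rec = relative_fdr(sets[regime], full_sets[name][regime])
                    points[name].append((f, rec.rel_fdr))
        for name, pts in points.items():
            if not per_iteration:
                frame = pd.DataFrame(pts, columns=["f", "rel_fdr"])
                pts = list(frame.groupby("f")["rel_fdr"].mean().items())
            rec = fit_fdr_slope(pts, engine=name, dataset_id=dataset_id)
            rows.append({"engine": name, "dataset_id": dataset_id,
                         "slope": rec.slope, "intercept": rec.intercept,
                         "n_points": len(pts)})
    return pd.DataFrame(rows)


def compare_engines(slopes: pd.DataFrame):
    """Friedman test plus Conover and Nemenyi post-hocs over a slope table
    (columns engine, dataset_id, slope)."""
    matrix = slopes.pivot(index="dataset_id", columns="engine", values="slope")
    fried = friedman_test(matrix)
    return fried, conover_posthoc(matrix), nemenyi_posthoc(matrix)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Structured configuration of one end-to-end experiment."""

    simulation: SimulationConfig | None = None
    counts_path: str | None = None      # pair (counts TSV, sample sheet) for real data
    samples_path: str | None = None
    subsample: SubsampleSpec = field(default_factory=SubsampleSpec)
    engines: tuple[str, ...] = tuple(ENGINES)
    alpha: float = 0.05
    fold_threshold: float = 2.0
    noiseq_q: float = 0.95
    strata_normalization: str = "cpm"
    population_reps: int = 10
    slope_fractions: tuple[float, ...] = SLOPE_FRACTIONS
    slope_iterations: int = 5
    slope_regime: str = "two_fold"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and self.counts_path is None:
            self.simulation = SimulationConfig()
        unknown = [e for e in self.engines if e not in ENGINES]
        if unknown:
            raise ValueError(f"unknown engines {unknown}; available {sorted(ENGINES)}")

    def engine_params(self) -> dict:
        return {name: EngineParams(seed=self.master_seed) for name in self.engines}

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            sim = dict(d["simulation"])
            for key in ("n_samples_per_group", "baseline_mean_log_params"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            if isinstance(sim.get("log2fc_magnitude"), list):
                sim["log2fc_magnitude"] = tuple(sim["log2fc_magnitude"])
            d["simulation"] = SimulationConfig(**sim)
        if d.get("subsample") is not None and not isinstance(d["subsample"], SubsampleSpec):
            sub = dict(d["subsample"])
            sub["fractions"] = tuple(sub["fractions"])
            d["subsample"] = SubsampleSpec(**sub)
        for key in ("engines", "slope_fractions"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# on-disk experiment


def _result_from_tsv(path: str, engine: str) -> EngineResult:
    table = pd.read_csv(path, sep="\t")
    table["filtered"] = table["filtered"].astype(bool)
    return EngineResult(engine=engine, table=table,
                        posterior_kind=_ENGINE_KIND.get(engine))


def _fr_tag(f: float, r: int) -> str:
    return f"f{f:g}_r{r:02d}"


def run_experiment(config: PipelineConfig, out_dir: str, resume: bool = True) -> dict:
    """Run the full experiment, writing all stage artifacts under ``out_dir``.

    Stages: simulate (or load) counts; thin over the subsample grid; run
    every engine on every instance; score relative FDR per regime and
    concordance at full depth; fit the leave-one-out slope population;
    compare engines with Friedman + post-hocs.  With ``resume=True`` any
    stage whose artifact already exists is loaded instead of recomputed, so
    deleting intermediates and resuming reproduces identical numbers.

    Returns a dict of the principal in-memory results.
    """
    dio.ensure_dir(out_dir)
    _setup_logging(os.path.join(out_dir, "run.log"))
    config.to_yaml(os.path.join(out_dir, "config.yaml"))
    params_map = config.engine_params()

    # -- stage: input counts ------------------------------------------
    sim_dir = dio.ensure_dir(os.path.join(out_dir, "simulate"))
    counts_tsv = os.path.join(sim_dir, "counts.tsv")
    samples_tsv = os.path.join(sim_dir, "samples.tsv")
    truth: TruthTable | None = None
    if resume and os.path.exists(counts_tsv):
        counts = dio.read_counts_tsv(counts_tsv, samples_tsv)
        log.info("simulate: loaded existing %s", counts_tsv)
    elif config.counts_path is not None:
        counts = dio.read_counts_tsv(config.counts_path, config.samples_path)
        dio.write_counts_tsv(counts, counts_tsv)
        dio.write_sample_sheet(counts, samples_tsv)
        log.info("loaded real counts from %s", config.counts_path)
    else:
        sim = dataclasses.replace(config.simulation, seed=config.master_seed)
        counts, truth = generate_dataset(sim)
        dio.write_counts_tsv(counts, counts_tsv)
        dio.write_sample_sheet(counts, samples_tsv)
        dio.write_truth_tsv(truth, os.path.join(sim_dir, "truth.tsv"))
        log.info("simulated %d genes x %d samples", counts.n_genes, counts.n_samples)
    counts.validate_for_testing()

    # -- stage: thinning grid ------------------------------------------
    spec = dataclasses.replace(config.subsample, master_seed=config.master_seed)
    thin_dir = dio.ensure_dir(os.path.join(out_dir, "thin"))
    manifest_rows = []
    for f in spec.fractions:
        for r in range(1, spec.iterations + 1):
            path = os.path.join(thin_dir, _fr_tag(f, r) + ".tsv")
            if not (resume and os.path.exists(path)):
                thinned = thin_counts(counts, f, spec.seed_for(f, r))
                dio.write_counts_tsv(thinned, path)
            manifest_rows.append({
                "f": f, "r": r, "path": os.path.relpath(path, out_dir),
                "seed": "-".join(str(e) for e in spec.seed_for(f, r).entropy),
            })
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(os.path.join(thin_dir, "manifest.tsv"), sep="\t", index=False)
    log.info("thinning grid: %d instances", len(manifest))

    # -- stage: engines ------------------------------------------------
    eng_dir = dio.ensure_dir(os.path.join(out_dir, "engines"))

    def engine_result(name: str, cm: CountMatrix, tag: str) -> EngineResult:
        path = os.path.join(dio.ensure_dir(os.path.join(eng_dir, name)), tag + ".tsv")
        if resume and os.path.exists(path):
            return _result_from_tsv(path, name)
        res = run_engine(name, cm, params_map.get(name))
        res.to_tsv(path)
        return res

    full_results = {name: engine_result(name, counts, "full") for name in config.engines}
    full_sets = {name: deg_sets(res, config.alpha, config.fold_threshold,
                                noiseq_q=config.noiseq_q)
                 for name, res in full_results.items()}

    rows = []
    for row in manifest_rows:
        f, r = row["f"], row["r"]
        thinned = dio.read_counts_tsv(os.path.join(out_dir, row["path"]), samples_tsv)
        for name in config.engines:
            res = engine_result(name, thinned, _fr_tag(f, r))
            sets = deg_sets(res, config.alpha, config.fold_threshold,
                            f=f, r=r, noiseq_q=config.noiseq_q)
            for regime in REGIMES:
                rows.append(relative_fdr(sets[regime], full_sets[name][regime]).as_dict())
    relfdr = pd.DataFrame(rows)

    # -- stage: evaluation tables --------------------------------------
    eval_dir = dio.ensure_dir(os.path.join(out_dir, "evaluate"))
    relfdr.to_csv(os.path.join(eval_dir, "relfdr.tsv"), sep="\t", index=False)
    if not relfdr.empty:
        per_f = (relfdr.groupby(["engine", "regime", "f"])["rel_fdr"]
                 .mean().reset_index())
        per_f.to_csv(os.path.join(eval_dir, "relfdr_mean_by_f.tsv"), sep="\t", index=False)
    reports = {}
    for regime in REGIMES:
        rep = concordance({n: s[regime].gene_ids for n, s in full_sets.items()})
        rep.to_frame().to_csv(os.path.join(eval_dir, f"concordance_{regime}.tsv"),
                              sep="\t", index=False)
        reports[regime] = rep
    high, low = expression_strata(counts, normalization=config.strata_normalization)
    pd.DataFrame({"gene_id": sorted(high | low),
                  "stratum": ["high" if g in high else "low" for g in sorted(high | low)]}
                 ).to_csv(os.path.join(eval_dir, "strata.tsv"), sep="\t", index=False)
    log.info("evaluation: %d relative-FDR records", len(relfdr))

    # -- stage: slope population ---------------------------------------
    slope_dir = dio.ensure_dir(os.path.join(out_dir, "slopes"))
    slope_path = os.path.join(slope_dir, "slopes.tsv")
    if resume and os.path.exists(slope_path):
        slopes = pd.read_csv(slope_path, sep="\t")
    else:
        slopes = slope_population_analysis(
            counts, config.engines, reps=config.population_reps,
            slope_fractions=config.slope_fractions, iterations=config.slope_iterations,
            seed=config.master_seed, alpha=config.alpha, fold_c=config.fold_threshold,
            regime=config.slope_regime, params_map=params_map,
            noiseq_q=config.noiseq_q)
        slopes.to_csv(slope_path, sep="\t", index=False)
    log.info("slopes: %d records", len(slopes))

    # -- stage: engine comparison --------------------------------------
    cmp_dir = dio.ensure_dir(os.path.join(out_dir, "compare"))
    fried, conover, nemenyi = compare_engines(slopes)
    pd.DataFrame([{"chi_squared": fried.chi2, "df": fried.df, "p_value": fried.p_value}]
                 ).to_csv(os.path.join(cmp_dir, "friedman.tsv"), sep="\t", index=False)
    for ph in (conover, nemenyi):
        ph.p_values.to_csv(os.path.join(cmp_dir, f"{ph.method}_p.tsv"), sep="\t")
        ph.stars().to_csv(os.path.join(cmp_dir, f"{ph.method}_stars.tsv"), sep="\t")
    log.info("friedman: chi2=%.3f df=%d p=%.3g", fried.chi2, fried.df, fried.p_value)

    return {
        "counts": counts, "truth": truth, "manifest": manifest,
        "full_results": full_results, "relfdr": relfdr, "concordance": reports,
        "slopes": slopes, "friedman": fried, "conover": conover, "nemenyi": nemenyi,
    }


def _setup_logging(logfile: str) -> None:
    log.setLevel(logging.INFO)
    have_file = any(isinstance(h, logging.FileHandler)
                    and getattr(h, "baseFilename", None) == os.path.abspath(logfile)
                    for h in log.handlers)
    if not have_file:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())
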