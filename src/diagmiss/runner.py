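"""Factorial study orchestration.

Builds the scenario grid (the default grid crosses three values each of true
sensitivity, true specificity, missingness mechanism, missing proportion,
prevalence and sample size — 729 scenarios), drives seeded repetitions
through data generation -> amputation -> every handler -> estimation, applies
the degenerate-dataset exclusion rule, and writes long-form result tables.

Seeding is counter-based: each repetition draws its streams from
``SeedSequence(master, spawn_key=(scenario_index, rep_index, stage))`` so the
per-repetition output is invariant to execution order and to the degree of
parallelism.  All handlers within a repetition consume the *same* amputated
dataset (paired comparison).

A repetition whose amputated dataset has observed index results of only one
type (all positive or all negative) is excluded for every method; handler
failures on non-degenerate datasets (e.g. a donor-less hot-deck stratum) are
flagged per method.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import __version__
from .amputation import AmputationConfig, ampute
from .datagen import ScenarioSpec, build_latent_model, generate_complete
from .errors import ConfigurationError, HandlerFailure
from .estimation import EstimateCI, confusion_counts, sens_spec_ci
from .mice import mice_sens_spec
from .multinomial import (
    from_catdata,
    ml_mar_allocate,
    ml_mcar_allocate,
    substitute_zero_cells,
    to_catdata,
    wls_mcar_allocate,
)
from .performance import summarize
from .simple_handlers import cca, random_hot_deck, worst_case

__all__ = [
    "ALL_METHODS",
    "StudyConfig",
    "RepResult",
    "build_grid",
    "expected_effective_n",
    "apply_method",
    "run_rep",
    "run_scenario",
    "run_study",
    "export_nestedloop",
]

ALL_METHODS = ("CCA", "WC", "RHD", "MICE", "MLMCAR", "MLMAR", "WLSMCAR")

# factor iteration order for the cartesian grid (documented, deterministic)
FACTOR_ORDER = ("true_sens", "true_spec", "mechanism", "miss_prop", "prevalence", "n")

TABLE1_GRID = {
    "true_sens": (0.7, 0.8, 0.9),
    "true_spec": (0.7, 0.8, 0.9),
    "mechanism": ("MCAR", "MAR", "MNAR"),
    "miss_prop": (0.1, 0.3, 0.5),
    "prevalence": (0.1, 0.2, 0.4),
    "n": (400, 800, 1600),
}


@dataclass
class StudyConfig:
    """Study configuration; every default reproduces the factorial design."""

    grid: dict = field(default_factory=lambda: {k: list(v) for k, v in TABLE1_GRID.items()})
    n_sim: int = 1000
    methods: tuple = ALL_METHODS
    seed: int = 1
    mice_m: int = 5
    theta0: object = None  # float or {"sensitivity": ..., "specificity": ...}
    n_jobs: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.grid) - set(FACTOR_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown grid factors: {sorted(unknown)}")
        missing = set(FACTOR_ORDER) - set(self.grid)
        if missing:
            raise ConfigurationError(f"grid is missing factors: {sorted(missing)}")
        bad = set(self.methods) - set(ALL_METHODS)
        if bad:
            raise ConfigurationError(f"unknown methods: {sorted(bad)}")
        if self.n_sim < 1:
            raise ConfigurationError("n_sim must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "grid" in raw:
            grid = {k: list(v) for k, v in TABLE1_GRID.items()}
            grid.update({k: list(v) for k, v in raw["grid"].items()})
            kwargs["grid"] = grid
        for key in ("n_sim", "seed", "mice_m", "theta0", "n_jobs"):
            if key in raw:
                kwargs[key] = raw[key]
        if "methods" in raw:
            kwargs["methods"] = tuple(raw["methods"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d


@dataclass(frozen=True)
class RepResult:
    scenario_id: str
    method: str
    estimand: str
    rep: int
    point: float
    lower: float
    upper: float
    excluded: bool
    failed: bool
    degenerate: bool


def build_grid(config: StudyConfig) -> list[ScenarioSpec]:
    """Cartesian product of the factor values, in documented factor order."""
    values = [config.grid[f] for f in FACTOR_ORDER]
    return [
        ScenarioSpec(**dict(zip(FACTOR_ORDER, combo)))
        for combo in itertools.product(*values)
    ]


def expected_effective_n(scenario: ScenarioSpec) -> dict[str, float]:
    """Expected observed group sizes under MCAR-style uniform missingness."""
    keep = 1.0 - scenario.miss_prop
    return {
        "sensitivity": scenario.n_diseased * keep,
        "specificity": scenario.n_nondiseased * keep,
    }


def _stage_seed(master: int, scenario_idx: int, rep_idx: int, stage: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(scenario_idx, rep_idx, stage))
    return int(ss.generate_state(1)[0])


def apply_method(
    method: str, table: pd.DataFrame, seed: int, mice_m: int = 5, level: float = 0.95
) -> tuple[EstimateCI, EstimateCI]:
    """Run one handler on an amputated table and estimate both margins."""
    if method == "CCA":
        return sens_spec_ci(confusion_counts(cca(table)), level)
    if method == "WC":
        return sens_spec_ci(confusion_counts(worst_case(table)), level)
    if method == "RHD":
        return sens_spec_ci(confusion_counts(random_hot_deck(table, seed)), level)
    if method == "MICE":
        return mice_sens_spec(table, m=mice_m, seed=seed, level=level)
    if method in ("MLMCAR", "MLMAR", "WLSMCAR"):
        cat = to_catdata(table)
        allocate = {
            "MLMCAR": ml_mcar_allocate,
            "MLMAR": ml_mar_allocate,
            "WLSMCAR": wls_mcar_allocate,
        }[method]
        filled = allocate(substitute_zero_cells(cat))
        return sens_spec_ci(from_catdata(filled), level)
    raise ConfigurationError(f"unknown method {method!r}")


def run_rep(
    scenario: ScenarioSpec,
    methods: tuple,
    rep_seed: tuple[int, int, int],
    model=None,
    mice_m: int = 5,
) -> list[RepResult]:
    """One repetition: generate, ampute once, apply every method.

    ``rep_seed`` is (master, scenario_index, rep_index).  If the amputated
    dataset has observed index results of one type only, the repetition is
    excluded for all methods.
    """
    master, si, ri = rep_seed
    if model is None:
        model = build_latent_model(scenario)
    complete = generate_complete(scenario, model, _stage_seed(master, si, ri, 0))
    amp_cfg = AmputationConfig(scenario.mechanism, scenario.miss_prop)
    amputed = ampute(complete, amp_cfg, _stage_seed(master, si, ri, 1))

    observed = amputed["Y"].dropna()
    degenerate_dataset = observed.empty or observed.nunique() == 1

    results: list[RepResult] = []
    sid = scenario.label()
    for k, method in enumerate(methods):
        if degenerate_dataset:
            results.extend(
                RepResult(sid, method, est, ri, np.nan, np.nan, np.nan, True, False,
                          False)
                for est in ("sensitivity", "specificity")
            )
            continue
        seed_m = _stage_seed(master, si, ri, 2 + k)
        try:
            sens, spec = apply_method(method, amputed, seed_m, mice_m=mice_m)
        except HandlerFailure:
            results.extend(
                RepResult(sid, method, est, ri, np.nan, np.nan, np.nan, False, True,
                          False)
                for est in ("sensitivity", "specificity")
            )
            continue
        for est in (sens, spec):
            results.append(
                RepResult(sid, method, est.estimand, ri, est.point, est.lower,
                          est.upper, False, False, est.degenerate_flag)
            )
    return results


def _scenario_frame(scenario: ScenarioSpec, rows: list[RepResult]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in rows])
    for factor in FACTOR_ORDER:
        df[factor] = getattr(scenario, factor)
    df["theta_true"] = np.where(
        df["estimand"] == "sensitivity", scenario.true_sens, scenario.true_spec
    )
    return df


def run_scenario(
    scenario: ScenarioSpec,
    scenario_idx: int,
    config: StudyConfig,
) -> pd.DataFrame:
    """All repetitions of one scenario (the latent model is built once)."""
    model = build_latent_model(scenario)
    rows: list[RepResult] = []
    for ri in range(config.n_sim):
        rows.extend(
            run_rep(
                scenario,
                config.methods,
                (config.seed, scenario_idx, ri),
                model=model,
                mice_m=config.mice_m,
            )
        )
    return _scenario_frame(scenario, rows)


def run_study(config: StudyConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute the full factorial study and write results.

    Writes ``reps.csv`` (one row per repetition x method x estimand),
    ``summary.csv`` (performance measures per scenario x method x estimand)
    and ``manifest.json``.  Scenario-level parallelism (``config.n_jobs``)
    does not change the output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = build_grid(config)
    frames = Parallel(n_jobs=config.n_jobs)(
        delayed(run_scenario)(sc, i, config) for i, sc in enumerate(grid)
    )
    reps = pd.concat(frames, ignore_index=True)
    summary = summarize(reps, theta0=config.theta0)
    paths = {
        "reps": out / "reps.csv",
        "summary": out / "summary.csv",
        "manifest": out / "manifest.json",
    }
    reps.to_csv(paths["reps"], index=False)
    summary.to_csv(paths["summary"], index=False)
    manifest = {
        "package": "diagmiss",
        "version": __version__,
        "config": config.to_dict(),
        "n_scenarios": len(grid),
        "n_rep_rows": int(len(reps)),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return paths


def export_nestedloop(
    summary: pd.DataFrame,
    factor_order: tuple = FACTOR_ORDER,
    measures: tuple = ("bias", "coverage"),
) -> pd.DataFrame:
    """Long-form table for nested-loop-plot frontends.

    Scenarios are sorted by the requested factor nesting and assigned an
    x-position; each factor additionally gets an integer level index
    (its step-function height).  One row per scenario x method x estimand
    x measure.
    """
    missing = [f for f in factor_order if f not in summary.columns]
    if missing:
        raise ConfigurationError(f"summary lacks factor columns: {missing}")
    scen = (
        summary[list(factor_order)]
        .drop_duplicates()
        .sort_values(list(factor_order), kind="mergesort")
        .reset_index(drop=True)
    )
    scen["x_pos"] = np.arange(len(scen))
    levels = {
        f: {v: i for i, v in enumerate(sorted(scen[f].unique()))} for f in factor_order
    }
    merged = summary.merge(scen, on=list(factor_order), how="left")
    rows = []
    for measure in measures:
        part = merged[
            ["x_pos", *factor_order, "method", "estimand", measure]
        ].copy()
        part["measure"] = measure
        part = part.rename(columns={measure: "value"})
        for f in factor_order:
            part[f"{f}_level"] = part[f].map(levels[f])
        rows.append(part)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["measure", "estimand", "method", "x_pos"]).reset_index(
        drop=True
    )
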