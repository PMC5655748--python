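"""Replicated benchmark: scenarios x methods, detection and selection rates.

Runs many simulated replicates of each causal scenario, applies any
subset of the six inference procedures (MR, CIT, SEM, BUF and the two
Bayesian-network scores) to each replicate, and aggregates

* detection proportions for the two hypothesis-testing methods,
* proportion-correct / tie / failure rates for the four model-selection
  methods, and
* the mean model-score matrix (one row per tested model, one column per
  scenario).

Truth definitions are derived programmatically from the generative
equations rather than hard-coded:

* the *correct model* for a scenario is its structure with the latent
  confounder deleted (so h -> a, i -> b, j -> c, k -> m, l -> n);
* MR truth = scenarios whose equations contain an X -> Y arrow;
* CIT truth = scenarios that are exactly a mediation chain
  G -> X -> Y with no direct G -> Y arrow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import bn, buf, cit, mr, sem
from ._exceptions import CausalTrioError, DegenerateDataError
from .simulate import (EQUATIONS, SCENARIO_IDS, ScenarioSpec, default_spec,
                       rng_for, simulate_triplet)

METHODS: tuple[str, ...] = ("mr", "cit", "sem", "buf", "bnlearn", "deal")
DETECTION_METHODS: frozenset[str] = frozenset({"mr", "cit"})
SELECTION_METHODS: frozenset[str] = frozenset({"sem", "buf", "bnlearn", "deal"})


def _structure_without_confounder(scenario_id: str) -> frozenset:
    edges = set()
    for child in ("x", "y"):
        for parent, _ in EQUATIONS[scenario_id][child]:
            if parent != "e":
                edges.add((parent, child))
    return frozenset(edges)


def correct_model_map() -> dict[str, str]:
    """Scenario -> correct model id, by deleting the confounder."""
    return {s: bn._ID_BY_EDGES[_structure_without_confounder(s)]
            for s in SCENARIO_IDS}


def mr_true_scenarios() -> frozenset[str]:
    """Scenarios whose generating equations contain an X -> Y arrow."""
    return frozenset(
        s for s in SCENARIO_IDS
        if any(p == "x" for p, _ in EQUATIONS[s]["y"])
    )


def cit_true_scenarios() -> frozenset[str]:
    """Scenarios that are a pure mediation chain G -> X -> Y."""
    out = set()
    for s in SCENARIO_IDS:
        x_parents = {p for p, _ in EQUATIONS[s]["x"]}
        y_parents = {p for p, _ in EQUATIONS[s]["y"]}
        if "x" in y_parents and "g" in x_parents and "g" not in y_parents:
            out.add(s)
    return frozenset(out)


@dataclass(frozen=True)
class TruthTables:
    """Fixed truth constants used to grade detections and selections."""

    correct_model: Mapping[str, str]
    mr_true: frozenset
    cit_true: frozenset
    sem_testable: tuple = sem.SEM_MODEL_IDS
    buf_testable: tuple = tuple(sorted(buf.ALIAS_TO_PARTITION))

    @classmethod
    def build(cls) -> "TruthTables":
        return cls(correct_model=correct_model_map(),
                   mr_true=mr_true_scenarios(),
                   cit_true=cit_true_scenarios())


TRUTH = TruthTables.build()


@dataclass
class BenchConfig:
    """Method settings shared across a benchmark run."""

    threshold: float = 0.05
    cit_b_perm: int = 1000
    cit_coding: str = "additive"
    sigma_a_grid: tuple = buf.DEFAULT_SIGMA_A_GRID
    iss: float = 6.0

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "cit_b_perm": self.cit_b_perm,
                "cit_coding": self.cit_coding,
                "sigma_a_grid": list(self.sigma_a_grid), "iss": self.iss}


@dataclass
class BenchSummary:
    """Aggregated results for one (scenario, method) cell."""

    scenario: str
    method: str
    n_reps: int
    detection_rate: float | None = None
    true_detection: bool | None = None
    correct_rate: float | None = None
    incorrect_rate: float | None = None
    tie_rate: float = 0.0
    failure_rate: float = 0.0
    mean_scores: dict = field(default_factory=dict)
    selection_counts: dict = field(default_factory=dict)
    correct_model: str | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario, "method": self.method,
            "n_reps": self.n_reps, "detection_rate": self.detection_rate,
            "true_detection": self.true_detection,
            "correct_rate": self.correct_rate,
            "incorrect_rate": self.incorrect_rate,
            "tie_rate": self.tie_rate, "failure_rate": self.failure_rate,
            "mean_scores": self.mean_scores,
            "selection_counts": self.selection_counts,
            "correct_model": self.correct_model, "config": self.config,
        }


def _apply_method(method: str, dataset, method_rng, cfg: BenchConfig) -> dict:
    g, x, y = dataset.triplet()
    if method == "mr":
        r = mr.mr_test(g, x, y, threshold=cfg.threshold)
        return {"detected": r.detected}
    if method == "cit":
        r = cit.cit_test(g, x, y, b_perm=cfg.cit_b_perm,
                         threshold=cfg.threshold, coding=cfg.cit_coding,
                         rng=method_rng)
        return {"detected": r.detected}
    if method == "sem":
        s = sem.sem_select(g, x, y)
        return {"selected": s.selected, "tie": s.tie_flag,
                "scores": s.bic_table}
    if method == "buf":
        r = buf.buf_bf(g, x, y, sigma_a_grid=cfg.sigma_a_grid)
        label = r.selected_alias or "".join(r.selected)
        scores = {(buf.PARTITION_ALIASES.get(p) or "".join(p)): v
                  for p, v in r.log10_bf.items()}
        return {"selected": label, "tie": r.tie_flag, "scores": scores}
    if method in ("bnlearn", "deal"):
        kind = "bic_cg" if method == "bnlearn" else "deal"
        t = bn.score_all_dags(g, x, y, score_kind=kind, iss=cfg.iss)
        return {"selected_class": t.selected_class, "tie": t.tie_flag,
                "scores": t.scores}
    raise ValueError(f"unknown method {method!r}")


def _grade_selection(method: str, scenario: str, rec: dict) -> str:
    """Classify one selection replicate as correct / incorrect / tie."""
    truth = TRUTH.correct_model[scenario]
    if rec.get("tie"):
        return "tie"
    if method == "sem":
        return "correct" if rec["selected"] == truth else "incorrect"
    if method == "buf":
        return "correct" if rec["selected"] == truth else "incorrect"
    return "correct" if truth in rec["selected_class"] else "incorrect"


def _selection_applicable(method: str, scenario: str) -> bool:
    truth = TRUTH.correct_model[scenario]
    if method == "sem":
        return truth in TRUTH.sem_testable
    if method == "buf":
        return truth in TRUTH.buf_testable
    return True


def run_scenario(scenario_id: str, methods: Sequence[str] = METHODS,
                 n_reps: int = 1000, base_seed: int = 0,
                 overrides: Mapping | None = None,
                 config: BenchConfig | None = None,
                 seed_extra: tuple = ()) -> dict[str, BenchSummary]:
    """Simulate ``n_reps`` replicates of one scenario and apply each method.

    Deterministic given ``base_seed``: replicate ``r`` draws from a
    substream keyed by (base_seed, scenario, r).  Method failures on
    individual replicates are counted in ``failure_rate`` and never abort
    the run.  Returns one :class:`BenchSummary` per method.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    methods = tuple(methods)
    if not methods:
        raise ValueError("methods must be nonempty")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    cfg = config or BenchConfig()
    spec = default_spec(scenario_id)
    if overrides:
        spec = spec.replace(**dict(overrides))

    counters = {m: {"detected": 0, "correct": 0, "incorrect": 0, "tie": 0,
                    "failed": 0, "score_sums": {}, "score_n": 0,
                    "selection_counts": {}} for m in methods}

    for rep in range(n_reps):
        data_rng = rng_for(base_seed, scenario_id, rep, stream=0, extra=seed_extra)
        dataset = simulate_triplet(spec, data_rng,
                                   seed_record=(base_seed, scenario_id, rep, 0))
        for m in methods:
            method_rng = rng_for(base_seed, scenario_id, rep, stream=1,
                                 extra=seed_extra)
            c = counters[m]
            try:
                rec = _apply_method(m, dataset, method_rng, cfg)
            except (CausalTrioError, np.linalg.LinAlgError):
                c["failed"] += 1
                continue
            if m in DETECTION_METHODS:
                c["detected"] += bool(rec["detected"])
            else:
                grade = _grade_selection(m, scenario_id, rec)
                c[grade] += 1
                label = (rec.get("selected")
                         or "/".join(rec.get("selected_class", ())))
                c["selection_counts"][label] = c["selection_counts"].get(label, 0) + 1
                for model_id, val in rec["scores"].items():
                    c["score_sums"][model_id] = c["score_sums"].get(model_id, 0.0) + val
                c["score_n"] += 1

    out: dict[str, BenchSummary] = {}
    for m in methods:
        c = counters[m]
        summary = BenchSummary(
            scenario=scenario_id, method=m, n_reps=n_reps,
            failure_rate=c["failed"] / n_reps,
            correct_model=TRUTH.correct_model[scenario_id],
            config={"base_seed": base_seed, "spec": spec.to_dict(),
                    **cfg.to_dict()},
        )
        if m in DETECTION_METHODS:
            summary.detection_rate = c["detected"] / n_reps
            truth_set = TRUTH.mr_true if m == "mr" else TRUTH.cit_true
            summary.true_detection = scenario_id in truth_set
        else:
            summary.tie_rate = c["tie"] / n_reps
            if _selection_applicable(m, scenario_id):
                summary.correct_rate = c["correct"] / n_reps
                summary.incorrect_rate = c["incorrect"] / n_reps
            else:
                summary.correct_rate = None
                summary.incorrect_rate = None
            summary.selection_counts = dict(sorted(
                c["selection_counts"].items(), key=lambda kv: -kv[1]))
            if c["score_n"]:
                summary.mean_scores = {k: v / c["score_n"]
                                       for k, v in c["score_sums"].items()}
        out[m] = summary
    return out


def run_benchmark(scenarios: Sequence[str] = SCENARIO_IDS,
                  methods: Sequence[str] = METHODS, n_reps: int = 1000,
                  base_seed: int = 0, config: BenchConfig | None = None,
                  overrides: Mapping | None = None) -> list[BenchSummary]:
    """Run the full scenario x method grid; returns a flat summary list."""
    out: list[BenchSummary] = []
    for s in scenarios:
        out.extend(run_scenario(s, methods, n_reps=n_reps, base_seed=base_seed,
                                overrides=overrides, config=config).values())
    return out


SWEEPABLE = ("alpha", "beta", "gamma", "delta", "zeta", "maf", "n")


def run_sweep(parameter: str, values: Sequence, scenario_id: str,
              methods: Sequence[str], n_reps: int = 200, base_seed: int = 0,
              config: BenchConfig | None = None) -> list[BenchSummary]:
    """Re-run one scenario over a grid of one generative parameter.

    All other parameters stay at their defaults.  Each grid value uses its
    own substream family so results are independent across values and
    reproducible.  Effect-size parameters must actually appear in the
    scenario's equations.
    """
    if parameter not in SWEEPABLE:
        raise ValueError(f"parameter must be one of {SWEEPABLE}")
    if len(values) == 0:
        raise ValueError("values must be nonempty")
    if parameter not in ("maf", "n"):
        used = {coef for child in ("x", "y")
                for _, coef in EQUATIONS[scenario_id][child]}
        if parameter not in used:
            raise ValueError(
                f"parameter {parameter!r} does not enter scenario {scenario_id!r}")
    out: list[BenchSummary] = []
    for i, v in enumerate(values):
        res = run_scenario(scenario_id, methods, n_reps=n_reps,
                           base_seed=base_seed, overrides={parameter: v},
                           config=config, seed_extra=(i,))
        for summary in res.values():
            summary.config["sweep"] = {"parameter": parameter, "value": v}
            out.append(summary)
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_ROW_ORDER = {
    "sem": list(sem.SEM_MODEL_IDS),
    "buf": ["a", "b", "c", "m", "n"],
    "bnlearn": ["a", "b", "c", "d", "e", "f", "g", "m", "n", "null", "xy", "yx"],
    "deal": ["a", "b", "c", "d", "e", "f", "g", "m", "n", "null", "xy", "yx"],
}


def summarize_scores(summaries: Iterable[BenchSummary]) -> dict[str, pd.DataFrame]:
    """Mean-score matrices, one per selection method.

    Rows are tested models, columns the scenarios present in the input.
    Missing cells stay NaN — they are never imputed.
    """
    groups: dict[str, dict[str, dict]] = {}
    for s in summaries:
        if s.method in SELECTION_METHODS and s.mean_scores:
            groups.setdefault(s.method, {})[s.scenario] = s.mean_scores
    out = {}
    for method, cols in groups.items():
        scen_order = [s for s in SCENARIO_IDS if s in cols] + \
                     [s for s in cols if s not in SCENARIO_IDS]
        rows = [r for r in _ROW_ORDER[method]
                if any(r in cols[s] for s in scen_order)]
        df = pd.DataFrame(index=rows, columns=scen_order, dtype=float)
        for scen, scores in cols.items():
            for model_id, val in scores.items():
                if model_id in rows:
                    df.loc[model_id, scen] = val
        out[method] = df
    return out


def preferred_models(matrix: pd.DataFrame, method: str) -> dict[str, str]:
    """Per-column preferred tested model (lowest BIC for SEM, else highest)."""
    pick = matrix.idxmin if method == "sem" else matrix.idxmax
    return {c: v for c, v in pick().dropna().items()}


def tidy_summaries(summaries: Iterable[BenchSummary]) -> pd.DataFrame:
    """One row per (scenario, method, statistic) — the tidy CSV layout."""
    rows = []
    for s in summaries:
        base = {"scenario": s.scenario, "method": s.method, "n_reps": s.n_reps}
        sweep = s.config.get("sweep")
        if sweep:
            base["sweep_parameter"] = sweep["parameter"]
            base["sweep_value"] = sweep["value"]
        stats = {"detection_rate": s.detection_rate,
                 "correct_rate": s.correct_rate,
                 "incorrect_rate": s.incorrect_rate,
                 "tie_rate": s.tie_rate, "failure_rate": s.failure_rate}
        for stat, val in stats.items():
            if val is not None:
                rows.append({**base, "statistic": stat, "value": val})
    return pd.DataFrame(rows)
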