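"""Simulation of genotype-mediator-phenotype triplets.

The generative world is a single biallelic SNP ``G`` (coded 0/1/2 by
minor-allele count, drawn under Hardy-Weinberg equilibrium), a continuous
intermediate trait ``X`` (e.g. a gene-expression level) and a continuous
outcome trait ``Y``.  Twelve causal scenarios, labelled ``a`` through
``l``, define linear-Gaussian structural equations between the three
variables; scenarios ``h``-``l`` additionally include a latent standard
environmental confounder ``E`` that influences both traits but is never
visible to any inference procedure.

Scenario structure (arrows are causal):

====  =======================================  =========
id    structure                                confounder
====  =======================================  =========
a     G -> X, G -> Y (pleiotropy)              no
b     G -> X -> Y (mediation)                  no
c     G -> Y -> X (reverse mediation)          no
d     G -> X, G -> Y, X -> Y                   no
e     G -> X, G -> Y, Y -> X                   no
f     G -> X, Y -> X                           no
g     G -> Y, X -> Y                           no
h     as (a) plus E -> X, E -> Y               yes
i     as (b) plus E -> X, E -> Y               yes
j     as (c) plus E -> X, E -> Y               yes
k     G -> X plus E -> X, E -> Y               yes
l     G -> Y plus E -> X, E -> Y               yes
====  =======================================  =========

Effect sizes are named after the arrow they scale: ``alpha`` (G on X),
``beta`` (G on Y), ``gamma`` (the X<->Y arrow in chains and in the
three-arrow models), ``delta`` (a Y -> X arrow entering jointly with G
or E), ``zeta`` (E on either trait).  Defaults put every effect at 1,
trait means at 10, all noise standard deviations at 0.3, minor-allele
frequency at 0.1 and sample size at 1000.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import DegenerateDataError, InvalidScenarioError

SCENARIO_IDS: tuple[str, ...] = tuple("abcdefghijkl")

#: Scenarios whose generative model includes the latent confounder E.
CONFOUNDED_SCENARIOS: frozenset[str] = frozenset("hijkl")

#: Structural equations: for each scenario, the parents of x and of y as
#: ``(parent_variable, effect_parameter)`` pairs.  The latent confounder
#: ``e`` appears as a parent only in scenarios h-l.  This table is the
#: single source of truth for the generative structure; the benchmark
#: derives its truth sets from it rather than hard-coding them twice.
EQUATIONS: dict[str, dict[str, tuple[tuple[str, str], ...]]] = {
    "a": {"x": (("g", "alpha"),), "y": (("g", "beta"),)},
    "b": {"x": (("g", "alpha"),), "y": (("x", "gamma"),)},
    "c": {"x": (("y", "gamma"),), "y": (("g", "beta"),)},
    "d": {"x": (("g", "alpha"),), "y": (("g", "beta"), ("x", "gamma"))},
    "e": {"x": (("g", "alpha"), ("y", "delta")), "y": (("g", "beta"),)},
    "f": {"x": (("g", "alpha"), ("y", "delta")), "y": ()},
    "g": {"x": (), "y": (("g", "beta"), ("x", "gamma"))},
    "h": {"x": (("g", "alpha"), ("e", "zeta")), "y": (("g", "beta"), ("e", "zeta"))},
    "i": {"x": (("g", "alpha"), ("e", "zeta")), "y": (("x", "gamma"), ("e", "zeta"))},
    "j": {"x": (("y", "delta"), ("e", "zeta")), "y": (("g", "beta"), ("e", "zeta"))},
    "k": {"x": (("g", "alpha"), ("e", "zeta")), "y": (("e", "zeta"),)},
    "l": {"x": (("e", "zeta"),), "y": (("g", "beta"), ("e", "zeta"))},
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete parameterisation of one generative scenario.

    Parameters
    ----------
    scenario_id : str
        One of ``a`` .. ``l``.
    alpha, beta, gamma, delta, zeta : float
        Effect sizes (trait units per unit of the parent variable).
    mu_x, mu_y : float
        Trait means.
    sigma_x, sigma_y, sigma_e : float
        Noise / confounder standard deviations (must be positive).
    maf : float
        Minor-allele frequency, in (0, 0.5].
    n : int
        Sample size per replicate (>= 2).
    """

    scenario_id: str
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    delta: float = 1.0
    zeta: float = 1.0
    mu_x: float = 10.0
    mu_y: float = 10.0
    sigma_x: float = 0.3
    sigma_y: float = 0.3
    sigma_e: float = 0.3
    maf: float = 0.1
    n: int = 1000

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_IDS:
            raise InvalidScenarioError(
                f"unknown scenario {self.scenario_id!r}; expected one of {SCENARIO_IDS}"
            )
        if not (self.sigma_x > 0 and self.sigma_y > 0 and self.sigma_e > 0):
            raise ValueError("noise standard deviations must be positive")
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")

    @property
    def confounded(self) -> bool:
        return self.scenario_id in CONFOUNDED_SCENARIOS

    def replace(self, **changes) -> "ScenarioSpec":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TripletDataset:
    """One simulated replicate (or one user-supplied data set).

    ``e`` is retained purely for diagnostics when the generating scenario
    includes the latent confounder; the method-facing accessors
    (:meth:`triplet`, :meth:`to_frame`) expose only ``(g, x, y)``.
    """

    g: np.ndarray
    x: np.ndarray
    y: np.ndarray
    e: np.ndarray | None = None
    truth: str | None = None
    seed_record: tuple | None = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.g) == len(self.x) == len(self.y)):
            raise ValueError("g, x, y must have equal length")
        if not np.isin(self.g, (0, 1, 2)).all():
            raise ValueError("g may only contain genotype codes 0, 1, 2")

    def __len__(self) -> int:
        return len(self.g)

    def triplet(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return the observable data ``(g, x, y)`` — never ``e``."""
        return self.g, self.x, self.y

    def to_frame(self) -> pd.DataFrame:
        """Observable data as a DataFrame with columns ``g, x, y``."""
        return pd.DataFrame({"g": self.g, "x": self.x, "y": self.y})

    def as_array(self) -> np.ndarray:
        """Observable data as an ``(n, 3)`` array ``[g, x, y]``."""
        return np.column_stack([self.g, self.x, self.y]).astype(float)


def default_spec(scenario_id: str) -> ScenarioSpec:
    """Return the default parameterisation for a scenario.

    All effects 1, means 10, standard deviations 0.3, MAF 0.1, n = 1000.
    """
    return ScenarioSpec(scenario_id=scenario_id)


def rng_for(base_seed: int, scenario_id: str, replicate: int,
            stream: int = 0, extra: Sequence[int] = ()) -> np.random.Generator:
    """Deterministic substream generator.

    Replicate ``r`` of scenario ``s`` draws from an independent substream
    derived from ``(base_seed, index(s), r, stream, *extra)`` through
    :class:`numpy.random.SeedSequence`, so runs parallelise and reproduce
    bit-for-bit.  ``stream`` separates data generation (0) from any
    method-internal randomness (1) on the same replicate.
    """
    if scenario_id not in SCENARIO_IDS:
        raise InvalidScenarioError(f"unknown scenario {scenario_id!r}")
    entropy = (int(base_seed), SCENARIO_IDS.index(scenario_id),
               int(replicate), int(stream), *map(int, extra))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` SNP genotypes under Hardy-Weinberg equilibrium.

    Genotypes are minor-allele counts, i.e. Binomial(2, maf) draws:
    P(0) = (1-maf)^2, P(1) = 2 maf (1-maf), P(2) = maf^2.
    """
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must lie in (0, 0.5], got {maf}")
    return rng.binomial(2, maf, size=int(n))


def _topological_order(scenario_id: str) -> list[str]:
    eq = EQUATIONS[scenario_id]
    # x before y unless x depends on y
    if any(p == "y" for p, _ in eq["x"]):
        return ["y", "x"]
    return ["x", "y"]


def simulate_triplet(spec: ScenarioSpec, rng: np.random.Generator,
                     seed_record: tuple | None = None) -> TripletDataset:
    """Simulate one replicate under the structural equations of a scenario.

    Variables are generated in topological order: genotype first, then the
    confounder (scenarios h-l), then whichever trait has no trait parent.
    All noise terms are independent given the parents.
    """
    if spec.scenario_id not in EQUATIONS:
        raise InvalidScenarioError(f"unknown scenario {spec.scenario_id!r}")
    eq = EQUATIONS[spec.scenario_id]
    n = spec.n
    values: dict[str, np.ndarray] = {}
    values["g"] = simulate_genotypes(n, spec.maf, rng).astype(float)
    e: np.ndarray | None = None
    if spec.confounded:
        e = rng.normal(0.0, spec.sigma_e, size=n)
        values["e"] = e
    sigmas = {"x": spec.sigma_x, "y": spec.sigma_y}
    means = {"x": spec.mu_x, "y": spec.mu_y}
    for var in _topological_order(spec.scenario_id):
        mean = np.full(n, means[var])
        for parent, coef_name in eq[var]:
            mean = mean + getattr(spec, coef_name) * values[parent]
        values[var] = rng.normal(mean, sigmas[var])
    return TripletDataset(
        g=values["g"].astype(np.int64),
        x=values["x"],
        y=values["y"],
        e=e,
        truth=spec.scenario_id,
        seed_record=seed_record,
    )


def simulate_replicate(spec: ScenarioSpec, base_seed: int, replicate: int) -> TripletDataset:
    """Simulate replicate ``replicate`` of a scenario under the substream contract."""
    rng = rng_for(base_seed, spec.scenario_id, replicate, stream=0)
    seed_record = (int(base_seed), spec.scenario_id, int(replicate), 0)
    return simulate_triplet(spec, rng, seed_record=seed_record)


# ---------------------------------------------------------------------------
# Delimited-text I/O: one replicate per file (columns g,x,y; no e column),
# with an optional JSON sidecar recording the generating spec and seed.
# ---------------------------------------------------------------------------

def write_triplet(dataset: TripletDataset, path: str | Path,
                  spec: ScenarioSpec | None = None, sep: str = ",") -> Path:
    """Write the observable columns ``g, x, y`` to a delimited text file.

    A sidecar ``<path>.meta.json`` records the generating spec and seed
    material when available.  The latent ``e`` is deliberately never
    written: it is unmeasured by construction.
    """
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False, sep=sep)
    meta: dict = {}
    if spec is not None:
        meta["spec"] = spec.to_dict()
    if dataset.truth is not None:
        meta["truth"] = dataset.truth
    if dataset.seed_record is not None:
        meta["seed_record"] = list(dataset.seed_record)
    if meta:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=1))
    return path


def read_triplets(path: str | Path, sep: str = ",") -> TripletDataset:
    """Read a delimited ``g, x, y`` table (the same dialect the writer emits).

    Accepts user-supplied data; genotype codes must be 0/1/2.  If a
    sidecar metadata file is present the recorded truth label and seed are
    restored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    missing = {"g", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"input table lacks required columns: {sorted(missing)}")
    truth = None
    seed_record = None
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        truth = meta.get("truth")
        if meta.get("seed_record") is not None:
            seed_record = tuple(meta["seed_record"])
    return TripletDataset(
        g=df["g"].to_numpy(), x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float), truth=truth, seed_record=seed_record,
    )
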