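"""Demographic scenarios: life histories, size trajectories, and the study grid.

Time is expressed in years before present (ybp) throughout.  A scenario
combines a life history (annual G1 or overlapping-generations G2), a recent
size trajectory (stable or exponentially declining at per-year rate
``lambda_``), and an optional 10-fold ancestral size change at 10,000
generations before present.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LifeHistory",
    "SizeTrajectory",
    "AncestralChange",
    "DemographicScenario",
    "GridEntry",
    "trajectory_size",
    "decline_ratio",
    "enumerate_study_grid",
    "paper_grid_config",
    "G1",
    "G2",
    "solve_g2_survival",
]

MAX_AGE_G2 = 8
DEFAULT_DURATION = 220
CHECKPOINT_YEARS = (120, 90, 60, 30, 0)
ANCESTRAL_CHANGE_GENERATION = 10_000


@dataclass(frozen=True)
class LifeHistory:
    """Age-structured yearly survival schedule with breeding from age 1."""

    id: str
    age_first_breeding: int
    max_age: int
    annual_survival: tuple[float, ...]  # survival from age x to x+1, x = 0..max_age-1
    expected_generation_time: float

    def __post_init__(self) -> None:
        if len(self.annual_survival) != self.max_age:
            raise ValueError("need one survival probability per age class")
        if any(not 0.0 <= s <= 1.0 for s in self.annual_survival):
            raise ValueError("survival probabilities must lie in [0, 1]")

    @property
    def survivorship(self) -> np.ndarray:
        """l_x: probability a newborn is alive at age x (x = 0..max_age)."""
        return np.concatenate([[1.0], np.cumprod(self.annual_survival)])

    def mean_breeder_age(self) -> float:
        l = self.survivorship
        ages = np.arange(self.age_first_breeding, self.max_age + 1)
        lx = l[ages]
        return float(np.sum(ages * lx) / np.sum(lx))

    def expected_breeders_per_newborn(self) -> float:
        """E[N_B] / N_O in a stable population with constant yearly recruitment."""
        l = self.survivorship
        return float(np.sum(l[self.age_first_breeding : self.max_age + 1]))


def solve_g2_survival(max_age: int = MAX_AGE_G2, target_mean_age: float = 3.0) -> tuple[float, float]:
    """Calibrate the G2 schedule: first-year survival ``a`` then constant ``s``.

    ``s`` is chosen so the mean breeder age equals ``target_mean_age`` and
    ``a`` so that the expected breeding-age count equals the yearly offspring
    count in a stable population.
    """

    def mean_age(s: float) -> float:
        x = np.arange(1, max_age + 1)
        w = s ** (x - 1.0)
        return float(np.sum(x * w) / np.sum(w))

    s = brentq(lambda v: mean_age(v) - target_mean_age, 1e-6, 1 - 1e-9)
    denom = np.sum(s ** (np.arange(1, max_age + 1) - 1.0))
    a = 1.0 / denom
    return a, s


def _make_g2() -> LifeHistory:
    a, s = solve_g2_survival()
    survival = (a,) + (s,) * (MAX_AGE_G2 - 1)
    lh = LifeHistory(
        id="G2",
        age_first_breeding=1,
        max_age=MAX_AGE_G2,
        annual_survival=survival,
        expected_generation_time=3.0,
    )
    return lh


G1 = LifeHistory(
    id="G1",
    age_first_breeding=1,
    max_age=1,
    annual_survival=(1.0,),  # all newborns recruit; all die after breeding once
    expected_generation_time=1.0,
)

G2 = _make_g2()

_LIFE_HISTORIES = {"G1": G1, "G2": G2}


def life_history(name: str) -> LifeHistory:
    try:
        return _LIFE_HISTORIES[name]
    except KeyError:
        raise ValueError(f"unknown life history {name!r}; expected G1 or G2") from None


@dataclass(frozen=True)
class SizeTrajectory:
    """Recent yearly offspring-count trajectory over ``duration`` forward years."""

    Ne_H: int
    lambda_: float = 1.0
    T_dec: int | None = None  # ybp at which the decline starts; None = stable
    duration: int = DEFAULT_DURATION

    def __post_init__(self) -> None:
        if self.Ne_H <= 0:
            raise ValueError("Ne_H must be positive")
        if not 0.0 < self.lambda_ <= 1.0:
            raise ValueError("lambda must lie in (0, 1]")
        if self.T_dec is not None and not 0 <= self.T_dec <= self.duration:
            raise ValueError("T_dec outside simulated window")

    @property
    def is_decline(self) -> bool:
        return self.lambda_ < 1.0 and self.T_dec is not None

    @property
    def Ne_C(self) -> int:
        return trajectory_size(self, 0)


def trajectory_size(trajectory: SizeTrajectory, t: float) -> int:
    """Population size (yearly offspring count) at ``t`` years before present."""
    if not 0 <= t <= trajectory.duration:
        raise ValueError(f"t={t} outside [0, {trajectory.duration}]")
    if not trajectory.is_decline or t >= trajectory.T_dec:
        return trajectory.Ne_H
    size = trajectory.Ne_H * trajectory.lambda_ ** (trajectory.T_dec - t)
    return max(2, int(round(size)))


def decline_ratio(lambda_: float, T: float, gen_time: float = 1.0) -> float:
    """Ratio of contemporary to pre-decline size after ``T`` years at rate ``lambda_``."""
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    if T < 0:
        raise ValueError("T must be non-negative")
    return lambda_**T


@dataclass(frozen=True)
class AncestralChange:
    """Instantaneous ancestral size change at a fixed generation before present."""

    kind: str = "none"  # none | expansion | bottleneck
    factor: float = 10.0
    time_generations: int = ANCESTRAL_CHANGE_GENERATION

    def __post_init__(self) -> None:
        if self.kind not in ("none", "expansion", "bottleneck"):
            raise ValueError(f"unknown ancestral change kind {self.kind!r}")
        if self.factor <= 0:
            raise ValueError("factor must be positive")

    def ancestral_size(self, Ne_H: int) -> int:
        """N_e,A: the size before ``time_generations`` ago.

        Reading forward in time, an ancestral *expansion* means the population
        grew to Ne_H (ancestral size smaller); an ancestral *bottleneck* means
        it shrank to Ne_H (ancestral size larger).
        """
        if self.kind == "none":
            return Ne_H
        if self.kind == "expansion":
            return max(2, int(round(Ne_H / self.factor)))
        return int(round(Ne_H * self.factor))


@dataclass(frozen=True)
class DemographicScenario:
    life_history: LifeHistory
    trajectory: SizeTrajectory
    ancestral: AncestralChange = AncestralChange()
    mutation_rate: float = 1e-8
    recombination_rate: float = 1e-8

    @property
    def Ne_H(self) -> int:
        return self.trajectory.Ne_H

    @property
    def Ne_C(self) -> int:
        return self.trajectory.Ne_C

    @property
    def gen_time(self) -> float:
        return self.life_history.expected_generation_time

    def label(self) -> str:
        t = self.trajectory
        recent = "stable" if not t.is_decline else f"lam{t.lambda_:g}_T{t.T_dec}"
        anc = "" if self.ancestral.kind == "none" else f"_{self.ancestral.kind}"
        return f"{self.life_history.id}_N{t.Ne_H}_{recent}{anc}"


# ---------------------------------------------------------------------------
# Study-grid enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridEntry:
    scenario: DemographicScenario
    replicate: int
    scheme: str
    sample_size: int
    data_type: str
    seed: int


def paper_grid_config() -> dict:
    """The full study-grid configuration (2 x Ne_H x 6 recent trajectories,
    plus 2 ancestral changes x 3 recent trajectories at the larger size)."""
    return {
        "life_history": "G1",
        "Ne_H": [1000, 10000],
        "recent": [
            {"lambda": 1.0, "T_dec": None},
            {"lambda": 0.99, "T_dec": 120},
            {"lambda": 0.99, "T_dec": 90},
            {"lambda": 0.99, "T_dec": 60},
            {"lambda": 0.99, "T_dec": 30},
            {"lambda": 0.95, "T_dec": 30},
        ],
        "ancestral": ["expansion", "bottleneck"],
        "ancestral_recent": [
            {"lambda": 1.0, "T_dec": None},
            {"lambda": 0.95, "T_dec": 30},
            {"lambda": 0.99, "T_dec": 120},
        ],
        "replicates": 5,
        "schemes": ["contemporary", "two_sample", "serial"],
        "data_types": {
            "WGS": [20, 50, 100],
            "RAD10k": [50, 100, 200],
            "RAD50k": [50, 100, 200],
        },
        "master_seed": 20220914,
    }


def enumerate_scenarios(config: dict) -> list[DemographicScenario]:
    lh = life_history(config.get("life_history", "G1"))
    scenarios: list[DemographicScenario] = []
    for ne in config["Ne_H"]:
        for rec in config["recent"]:
            traj = SizeTrajectory(Ne_H=ne, lambda_=rec["lambda"], T_dec=rec["T_dec"])
            scenarios.append(DemographicScenario(life_history=lh, trajectory=traj))
    anc_ne = max(config["Ne_H"]) if config.get("ancestral") else None
    for kind in config.get("ancestral", []):
        for rec in config.get("ancestral_recent", []):
            traj = SizeTrajectory(Ne_H=anc_ne, lambda_=rec["lambda"], T_dec=rec["T_dec"])
            scenarios.append(
                DemographicScenario(
                    life_history=lh,
                    trajectory=traj,
                    ancestral=AncestralChange(kind=kind),
                )
            )
    return scenarios


def derive_seed(master_seed: int, *parts) -> int:
    """Stable collision-resistant seed from the master seed and a key tuple."""
    key = repr((master_seed,) + tuple(parts)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:8], "little") % (2**63 - 1)


def enumerate_study_grid(config: dict) -> list[GridEntry]:
    """Deterministically enumerate every (scenario, replicate, scheme, n, type) cell."""
    valid_schemes = {"contemporary", "two_sample", "serial"}
    for scheme in config["schemes"]:
        if scheme not in valid_schemes:
            raise ValueError(f"unknown sampling scheme {scheme!r}")
    scenarios = enumerate_scenarios(config)
    master = config.get("master_seed", 0)
    entries: list[GridEntry] = []
    for si, scenario in enumerate(scenarios):
        for rep in range(config["replicates"]):
            for scheme in config["schemes"]:
                for data_type, sizes in config["data_types"].items():
                    for n in sizes:
                        seed = derive_seed(
                            master, scenario.label(), rep, scheme, data_type, n
                        )
                        entries.append(
                            GridEntry(scenario, rep, scheme, n, data_type, seed)
                        )
    return entries
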