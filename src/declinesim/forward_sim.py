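"""Individual-based forward-time simulation of pedigrees and chromosomes.

The simulator runs the population forward year by year for the scenario's
duration, drawing one male and one female parent with replacement from all
breeding-age individuals for every offspring.  The realized pedigree is then
reused for every chromosome: transmission with recombination is recorded as
node/edge tables so that ancestry can be completed backward in time later.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tskit

from .demography import CHECKPOINT_YEARS, DemographicScenario, trajectory_size

__all__ = [
    "ChromosomeSpec",
    "Pedigree",
    "SegmentMosaic",
    "ChromosomeAncestry",
    "SimulationError",
    "simulate_pedigree",
    "transmit_gamete",
    "simulate_chromosome",
    "realized_demography",
    "founder_mosaic",
]

FOUNDER = -1


class SimulationError(RuntimeError):
    """Raised when the forward simulation cannot proceed (e.g. a sex died out)."""


@dataclass(frozen=True)
class ChromosomeSpec:
    index: int = 1
    length_bp: int = 30_000_000
    recombination_rate: float = 1e-8

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("chromosome length must be positive")
        if self.recombination_rate < 0:
            raise ValueError("recombination rate must be non-negative")


@dataclass
class Pedigree:
    """Complete parentage record of a forward simulation.

    Individuals are indexed 0..n-1 in creation order (founders first).
    ``birth_year`` is in years before present; founders created with age > 0
    have birth years exceeding the simulated duration.
    """

    sex: np.ndarray  # int8, 0 = female, 1 = male
    birth_year: np.ndarray  # int32, ybp
    mother: np.ndarray  # int32, FOUNDER for founders
    father: np.ndarray
    duration: int
    gen_time: float
    n_founders: int
    checkpoints: dict[int, np.ndarray] = field(default_factory=dict)
    breeders_by_year: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return self.sex.shape[0]

    def node_time(self, individual: np.ndarray | int) -> np.ndarray | float:
        """Birth time in generations before present (tskit/msprime convention)."""
        return np.asarray(self.birth_year)[individual] / self.gen_time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n_individuals),
                "sex": np.where(self.sex == 0, "F", "M"),
                "birth_year": self.birth_year,
                "mother": self.mother,
                "father": self.father,
            }
        )


def _init_founders(scenario: DemographicScenario, rng: np.random.Generator):
    """Founder cohort(s) at the start of the forward period (stable age structure)."""
    lh = scenario.life_history
    duration = scenario.trajectory.duration
    n0 = trajectory_size(scenario.trajectory, duration)
    survivorship = lh.survivorship
    counts = []
    for age in range(lh.max_age + 1):
        c = int(round(n0 * survivorship[age])) if age > 0 else n0
        if lh.id == "G1" and age == 0:
            # annual life history: a single founder cohort of breeders-to-be
            counts.append(n0)
            break
        counts.append(c)
    sexes, years = [], []
    for age, c in enumerate(counts):
        sexes.append((rng.random(c) < 0.5).astype(np.int8))  # 0 = female
        years.append(np.full(c, duration + age, dtype=np.int32))
    return np.concatenate(sexes), np.concatenate(years)


def simulate_pedigree(
    scenario: DemographicScenario,
    seed: int,
    checkpoint_years: tuple[int, ...] = CHECKPOINT_YEARS,
    n_record: int = 200,
) -> Pedigree:
    """Run the yearly forward simulation and record the full pedigree.

    At each historical checkpoint ``n_record`` living individuals (all of
    them at 0 ybp) are recorded for downstream genotype extraction; recording
    is non-destructive.
    """
    rng = np.random.default_rng(seed)
    lh = scenario.life_history
    traj = scenario.trajectory
    duration = traj.duration
    survival = np.asarray(lh.annual_survival)

    sex0, year0 = _init_founders(scenario, rng)
    n_founders = sex0.shape[0]
    sex_parts = [sex0]
    year_parts = [year0]
    mother_parts = [np.full(n_founders, FOUNDER, dtype=np.int32)]
    father_parts = [np.full(n_founders, FOUNDER, dtype=np.int32)]
    alive = np.arange(n_founders, dtype=np.int32)
    alive_birth = year0.copy()
    next_id = n_founders
    checkpoints: dict[int, np.ndarray] = {}
    breeders_by_year: dict[int, np.ndarray] = {}

    for year in range(duration - 1, -1, -1):
        age = alive_birth - year  # age this year, before recruitment
        if lh.max_age > 1:
            # age-specific mortality applied to last year's survivors
            p = np.zeros(alive.shape[0])
            in_range = age <= lh.max_age
            p[in_range] = survival[age[in_range] - 1]
            keep = rng.random(alive.shape[0]) < p
            alive, alive_birth = alive[keep], alive_birth[keep]
            age = age[keep]
        breeders = alive[age >= lh.age_first_breeding]
        breeders_by_year[year] = breeders
        bsex = _gather_sex(sex_parts, breeders)
        females = breeders[bsex == 0]
        males = breeders[bsex == 1]
        if females.size == 0 or males.size == 0:
            raise SimulationError(
                f"sex extinct at {year} ybp ({females.size} females, {males.size} males)"
            )
        n_off = trajectory_size(traj, year)
        mothers = rng.choice(females, size=n_off, replace=True)
        fathers = rng.choice(males, size=n_off, replace=True)
        newsex = (rng.random(n_off) < 0.5).astype(np.int8)
        newids = np.arange(next_id, next_id + n_off, dtype=np.int32)
        next_id += n_off
        sex_parts.append(newsex)
        year_parts.append(np.full(n_off, year, dtype=np.int32))
        mother_parts.append(mothers.astype(np.int32))
        father_parts.append(fathers.astype(np.int32))
        if lh.max_age == 1:
            alive = newids
            alive_birth = np.full(n_off, year, dtype=np.int32)
        else:
            alive = np.concatenate([alive, newids])
            alive_birth = np.concatenate([alive_birth, np.full(n_off, year, dtype=np.int32)])
        if year in checkpoint_years:
            if year == 0:
                checkpoints[year] = np.sort(alive.copy())
            else:
                if alive.size < n_record:
                    raise SimulationError(
                        f"only {alive.size} individuals alive at {year} ybp, "
                        f"cannot record {n_record}"
                    )
                checkpoints[year] = np.sort(rng.choice(alive, size=n_record, replace=False))

    return Pedigree(
        sex=np.concatenate(sex_parts),
        birth_year=np.concatenate(year_parts),
        mother=np.concatenate(mother_parts),
        father=np.concatenate(father_parts),
        duration=duration,
        gen_time=lh.expected_generation_time,
        n_founders=n_founders,
        checkpoints=checkpoints,
        breeders_by_year=breeders_by_year,
    )


def _gather_sex(sex_parts: list[np.ndarray], ids: np.ndarray) -> np.ndarray:
    if len(sex_parts) > 1:
        sex_parts[0] = np.concatenate(sex_parts)
        del sex_parts[1:]
    return sex_parts[0][ids]


def realized_demography(pedigree: Pedigree) -> pd.DataFrame:
    """Per-year realized breeder counts, parental ages, and offspring variance."""
    rows = []
    sex = pedigree.sex
    for year in sorted(pedigree.breeders_by_year, reverse=True):
        breeders = pedigree.breeders_by_year[year]
        cohort = np.flatnonzero(pedigree.birth_year == year)
        cohort = cohort[pedigree.mother[cohort] != FOUNDER]
        mothers = pedigree.mother[cohort]
        fathers = pedigree.father[cohort]
        par_age = np.concatenate(
            [
                pedigree.birth_year[mothers] - year,
                pedigree.birth_year[fathers] - year,
            ]
        )
        counts = np.bincount(mothers, minlength=pedigree.n_individuals)
        counts += np.bincount(fathers, minlength=pedigree.n_individuals)
        per_parent = counts[breeders]
        rows.append(
            {
                "year": year,
                "n_breeders_f": int(np.sum(sex[breeders] == 0)),
                "n_breeders_m": int(np.sum(sex[breeders] == 1)),
                "n_offspring": cohort.size,
                "mean_parental_age": float(par_age.mean()) if par_age.size else np.nan,
                "offspring_var": float(per_parent.var(ddof=1)) if per_parent.size > 1 else np.nan,
                "offspring_mean": float(per_parent.mean()) if per_parent.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Segment mosaics and gamete transmission
# ---------------------------------------------------------------------------

class SegmentMosaic:
    """Ordered founder-segment tiling of one haplotype over [0, L).

    Segments are (start, end, founder_haplotype_id) with 0-based half-open
    coordinates; adjacent segments with the same founder id are merged.
    """

    __slots__ = ("segments", "length")

    def __init__(self, segments, length: int):
        merged: list[tuple[int, int, int]] = []
        for start, end, fid in segments:
            if end <= start:
                continue
            if merged and merged[-1][2] == fid and merged[-1][1] == start:
                merged[-1] = (merged[-1][0], end, fid)
            else:
                merged.append((int(start), int(end), int(fid)))
        self.segments = merged
        self.length = length
        self._validate()

    def _validate(self) -> None:
        if not self.segments:
            raise ValueError("empty mosaic")
        if self.segments[0][0] != 0 or self.segments[-1][1] != self.length:
            raise ValueError("mosaic does not tile [0, L)")
        for (s0, e0, _), (s1, e1, _) in zip(self.segments, self.segments[1:]):
            if e0 != s1:
                raise ValueError("mosaic has a gap or overlap")

    @classmethod
    def founder(cls, founder_hap_id: int, length: int) -> "SegmentMosaic":
        return cls([(0, length, founder_hap_id)], length)

    def founder_at(self, pos: int) -> int:
        for start, end, fid in self.segments:
            if start <= pos < end:
                return fid
        raise ValueError(f"position {pos} outside [0, {self.length})")

    def __eq__(self, other) -> bool:
        return isinstance(other, SegmentMosaic) and self.segments == other.segments

    def __repr__(self) -> str:
        return f"SegmentMosaic({self.segments!r})"


def _draw_breakpoints(spec: ChromosomeSpec, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(spec.recombination_rate * spec.length_bp)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    # continuous uniforms floored to integer bp; collisions resampled
    bp = np.unique(rng.integers(1, spec.length_bp, size=n))
    while bp.size < n:
        extra = rng.integers(1, spec.length_bp, size=n - bp.size)
        bp = np.unique(np.concatenate([bp, extra]))
    return bp


def transmit_gamete(
    parent_mosaics: tuple[SegmentMosaic, SegmentMosaic],
    spec: ChromosomeSpec,
    rng: np.random.Generator,
) -> SegmentMosaic:
    """Recombine the two parental haplotype mosaics into one gamete.

    Crossover count is Poisson(r*L); breakpoints are uniform; the gamete
    alternates between the parental haplotypes starting from a fair coin.
    """
    breakpoints = _draw_breakpoints(spec, rng)
    phase = int(rng.integers(0, 2))
    bounds = np.concatenate([[0], breakpoints, [spec.length_bp]])
    segments = []
    for j in range(bounds.size - 1):
        left, right = int(bounds[j]), int(bounds[j + 1])
        source = parent_mosaics[(phase + j) % 2]
        for s, e, fid in source.segments:
            lo, hi = max(s, left), min(e, right)
            if lo < hi:
                segments.append((lo, hi, fid))
    return SegmentMosaic(segments, spec.length_bp)


def propagate_mosaics(
    pedigree: Pedigree, spec: ChromosomeSpec, seed: int
) -> dict[int, tuple[SegmentMosaic, SegmentMosaic]]:
    """Explicit mosaic propagation through the whole pedigree (toy scale only).

    Founder haplotype ids are 2*ind and 2*ind+1.  Serves as an independent
    reference implementation for the table-based transmission route.
    """
    rng = np.random.default_rng(seed)
    mosaics: dict[int, tuple[SegmentMosaic, SegmentMosaic]] = {}
    order = np.argsort(-pedigree.birth_year, kind="stable")
    for ind in order:
        ind = int(ind)
        if pedigree.mother[ind] == FOUNDER:
            mosaics[ind] = (
                SegmentMosaic.founder(2 * ind, spec.length_bp),
                SegmentMosaic.founder(2 * ind + 1, spec.length_bp),
            )
        else:
            maternal = transmit_gamete(mosaics[pedigree.mother[ind]], spec, rng)
            paternal = transmit_gamete(mosaics[pedigree.father[ind]], spec, rng)
            mosaics[ind] = (maternal, paternal)
    return mosaics


# ---------------------------------------------------------------------------
# Table-based chromosome simulation (pedigree-conditioned transmission)
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeAncestry:
    """Recorded ancestry of checkpoint samples for one chromosome.

    ``ts`` holds the simplified (but not yet coalesced) tree sequence with
    input roots retained at founder level; ``sample_nodes`` maps checkpoint
    year -> (k, 2) array of node ids for the recorded individuals, in the
    same order as ``Pedigree.checkpoints``.
    """

    ts: tskit.TreeSequence
    spec: ChromosomeSpec
    sample_nodes: dict[int, np.ndarray]
    founder_time: float


def _cohort_edges(
    child_nodes: np.ndarray,
    parent_ids: np.ndarray,
    spec: ChromosomeSpec,
    rng: np.random.Generator,
):
    """Vectorized gamete edges for one cohort and one parent type."""
    n = child_nodes.shape[0]
    L = spec.length_bp
    k = rng.poisson(spec.recombination_rate * L, size=n)
    reps = k + 1
    total = int(reps.sum())
    nbp = int(k.sum())
    bp = rng.integers(1, L, size=nbp, dtype=np.int64)
    owner = np.repeat(np.arange(n), k)
    order = np.lexsort((bp, owner))
    bp = bp[order]

    starts = np.cumsum(reps) - reps  # first-segment index per child
    first = np.zeros(total, dtype=bool)
    first[starts] = True
    last = np.zeros(total, dtype=bool)
    last[starts + k] = True

    left = np.empty(total, dtype=np.int64)
    right = np.empty(total, dtype=np.int64)
    left[first] = 0
    left[~first] = bp
    right[last] = L
    right[~last] = bp

    seg_j = np.arange(total) - np.repeat(starts, reps)
    phase0 = rng.integers(0, 2, size=n)
    parity = (np.repeat(phase0, reps) + seg_j) & 1
    parent_nodes = np.repeat(2 * parent_ids.astype(np.int64), reps) + parity
    child_col = np.repeat(child_nodes, reps)

    ok = right > left  # drop zero-length segments from breakpoint collisions
    return left[ok], right[ok], parent_nodes[ok], child_col[ok]


def simulate_chromosome(
    pedigree: Pedigree, spec: ChromosomeSpec, seed: int
) -> ChromosomeAncestry:
    """Record pedigree-conditioned transmission of one chromosome.

    The same pedigree can be passed repeatedly with different seeds to
    simulate independently recombining chromosomes.  Node times are in
    generations (birth year / generation time) so the output can be handed
    to a backward-time coalescent completion directly.
    """
    rng = np.random.default_rng(seed)
    n = pedigree.n_individuals
    node_time = np.repeat(pedigree.birth_year / pedigree.gen_time, 2)

    lefts, rights, parents, children = [], [], [], []
    years = np.unique(pedigree.birth_year[pedigree.mother != FOUNDER])[::-1]
    for year in years:
        cohort = np.flatnonzero(pedigree.birth_year == year)
        cohort = cohort[pedigree.mother[cohort] != FOUNDER]
        child_nodes = 2 * cohort.astype(np.int64)
        for parent_ids, offset in (
            (pedigree.mother[cohort], 0),
            (pedigree.father[cohort], 1),
        ):
            l, r, p, c = _cohort_edges(child_nodes + offset, parent_ids, spec, rng)
            lefts.append(l)
            rights.append(r)
            parents.append(p)
            children.append(c)

    tables = tskit.TableCollection(sequence_length=spec.length_bp)
    tables.time_units = "generations"
    tables.populations.metadata_schema = tskit.MetadataSchema.permissive_json()
    tables.populations.add_row(metadata={"name": "pop0"})

    sample_node_ids = []
    years_sorted = sorted(pedigree.checkpoints, reverse=True)
    for year in years_sorted:
        ids = pedigree.checkpoints[year]
        pairs = np.column_stack([2 * ids, 2 * ids + 1]).astype(np.int64)
        sample_node_ids.append(pairs)
    flat_samples = np.concatenate([p.ravel() for p in sample_node_ids])

    flags = np.zeros(2 * n, dtype=np.uint32)
    flags[flat_samples] = tskit.NODE_IS_SAMPLE
    tables.nodes.set_columns(
        flags=flags,
        time=node_time,
        population=np.zeros(2 * n, dtype=np.int32),
    )
    left = np.concatenate(lefts).astype(np.float64)
    right = np.concatenate(rights).astype(np.float64)
    parent = np.concatenate(parents).astype(np.int32)
    child = np.concatenate(children).astype(np.int32)
    # pre-sort in tskit's canonical edge order to skip TableCollection.sort()
    order = np.lexsort((left, child, parent, node_time[parent]))
    tables.edges.set_columns(
        left=left[order], right=right[order], parent=parent[order], child=child[order]
    )
    node_map = tables.simplify(
        samples=flat_samples.astype(np.int32),
        keep_input_roots=True,
        filter_populations=False,
    )
    ts = tables.tree_sequence()

    sample_nodes = {}
    for year, pairs in zip(years_sorted, sample_node_ids):
        sample_nodes[year] = node_map[pairs]
    founder_time = pedigree.duration / pedigree.gen_time
    return ChromosomeAncestry(
        ts=ts, spec=spec, sample_nodes=sample_nodes, founder_time=founder_time
    )


def founder_mosaic(
    ancestry: ChromosomeAncestry, node: int
) -> SegmentMosaic:
    """Founder-segment tiling of one sample haplotype, read off the trees."""
    segments = []
    for tree in ancestry.ts.trees():
        u = node
        parent = tree.parent(u)
        while parent != tskit.NULL and ancestry.ts.node(u).time < ancestry.founder_time:
            u = parent
            parent = tree.parent(u)
        segments.append((int(tree.interval.left), int(tree.interval.right), u))
    return SegmentMosaic(segments, int(ancestry.ts.sequence_length))
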