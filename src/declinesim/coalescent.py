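"""Backward-time completion of forward-simulated ancestry and mutation dropping.

The forward stage leaves founder-level lineages uncoalesced.  Here the
genealogy is completed with a coalescent-with-recombination process run at
the scenario's historic size (with an optional instantaneous ancestral size
change at 10,000 generations), after which mutations are dropped at a
per-base, per-generation rate and genotypes are read off for the recorded
checkpoint samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np
import tskit

from .demography import DemographicScenario
from .forward_sim import ChromosomeAncestry

__all__ = ["AncestryForest", "VariantTable", "recapitate", "drop_mutations", "genotypes_at"]


@dataclass
class AncestryForest:
    """Fully coalesced genealogies for one chromosome's checkpoint samples."""

    ts: tskit.TreeSequence
    chrom: int
    length_bp: int
    sample_nodes: dict[int, np.ndarray]  # checkpoint year -> (k, 2) node ids
    sample_ids: dict[int, np.ndarray]  # checkpoint year -> pedigree individual ids

    @property
    def fully_coalesced(self) -> bool:
        return all(tree.num_roots == 1 for tree in self.ts.trees())


@dataclass
class VariantTable:
    """Biallelic variants with diploid derived-allele dosages per individual.

    Columns are ordered by checkpoint year (oldest first) and within a year
    by pedigree individual id; ``sample_years`` tags each column.
    """

    chrom: int
    length_bp: int
    positions: np.ndarray  # int64, strictly increasing
    dosages: np.ndarray  # (n_sites, n_individuals) int8 in {0, 1, 2}
    sample_ids: np.ndarray  # pedigree individual id per column
    sample_years: np.ndarray  # checkpoint year per column

    def __post_init__(self) -> None:
        if self.positions.shape[0] != self.dosages.shape[0]:
            raise ValueError("positions/dosages length mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]

    def timepoints(self) -> list[int]:
        return sorted(set(int(y) for y in self.sample_years), reverse=True)


def demography_for(scenario: DemographicScenario) -> msprime.Demography:
    """Single-population size history for the backward-time completion."""
    dem = msprime.Demography()
    dem.add_population(name="pop0", initial_size=scenario.Ne_H)
    anc = scenario.ancestral
    if anc.kind != "none":
        dem.add_population_parameters_change(
            time=anc.time_generations,
            initial_size=anc.ancestral_size(scenario.Ne_H),
            population="pop0",
        )
    return dem


def recapitate(
    ancestry: ChromosomeAncestry,
    scenario: DemographicScenario,
    seed: int,
    pedigree_checkpoints: dict[int, np.ndarray] | None = None,
    model: str = "hudson",
) -> AncestryForest:
    """Coalesce the founder-level roots of a recorded chromosome.

    The discrete life history is not modelled backward in time; the
    continuous coalescent runs at diploid size ``Ne_H`` back to the ancestral
    change time (if any), then at ``Ne_A`` until all intervals reach a common
    ancestor.  Times are in generations throughout.
    """
    ts = msprime.sim_ancestry(
        initial_state=ancestry.ts,
        demography=demography_for(scenario),
        recombination_rate=ancestry.spec.recombination_rate,
        random_seed=seed % (2**31 - 2) + 1,
        model=model,
    )
    if pedigree_checkpoints is not None:
        sample_ids = {
            int(y): np.asarray(pedigree_checkpoints[y]) for y in ancestry.sample_nodes
        }
    else:
        sample_ids = {
            int(y): np.arange(v.shape[0]) for y, v in ancestry.sample_nodes.items()
        }
    return AncestryForest(
        ts=ts,
        chrom=ancestry.spec.index,
        length_bp=ancestry.spec.length_bp,
        sample_nodes=ancestry.sample_nodes,
        sample_ids=sample_ids,
    )


def drop_mutations(forest: AncestryForest, mu: float, seed: int) -> VariantTable:
    """Drop mutations at rate ``mu`` per bp per generation and read genotypes.

    Sites are emitted only if biallelic and segregating among the full set of
    checkpoint samples; positions are unique integers.
    """
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    mts = msprime.sim_mutations(
        forest.ts,
        rate=mu,
        random_seed=seed % (2**31 - 2) + 1,
        model=msprime.BinaryMutationModel(),
        discrete_genome=True,
    )
    years = sorted(forest.sample_nodes, reverse=True)
    node_order = np.concatenate([forest.sample_nodes[y].ravel() for y in years])
    sample_ids = np.concatenate([forest.sample_ids[y] for y in years])
    sample_years = np.concatenate(
        [np.full(len(forest.sample_ids[y]), y, dtype=np.int32) for y in years]
    )

    if mts.num_sites == 0:
        return VariantTable(
            chrom=forest.chrom,
            length_bp=forest.length_bp,
            positions=np.empty(0, dtype=np.int64),
            dosages=np.empty((0, sample_ids.shape[0]), dtype=np.int8),
            sample_ids=sample_ids,
            sample_years=sample_years,
        )

    # genotype_matrix columns follow ts.samples(); map to our ordering
    samples = mts.samples()
    col_of = {int(node): i for i, node in enumerate(samples)}
    order = np.array([col_of[int(nd)] for nd in node_order])
    G = mts.genotype_matrix()[:, order]
    n_hap = G.shape[1]
    derived = G.sum(axis=1)
    keep = (derived > 0) & (derived < n_hap)
    G = G[keep]
    positions = mts.tables.sites.position[keep].astype(np.int64)
    # collapse haplotype pairs to diploid dosages
    dosages = (G[:, 0::2] + G[:, 1::2]).astype(np.int8)
    return VariantTable(
        chrom=forest.chrom,
        length_bp=forest.length_bp,
        positions=positions,
        dosages=dosages,
        sample_ids=sample_ids,
        sample_years=sample_years,
    )


def genotypes_at(
    variants: VariantTable,
    sample_ids: np.ndarray | None = None,
    timepoint: int | None = None,
) -> np.ndarray:
    """Diploid dosage matrix (individuals x sites) for a sample subset.

    Sites fixed within the subset are retained (rows are not filtered); use
    :func:`declinesim.sfs.folded_sfs` to obtain the segregating spectrum.
    """
    mask = np.ones(variants.n_individuals, dtype=bool)
    if timepoint is not None:
        mask &= variants.sample_years == timepoint
    if sample_ids is not None:
        wanted = np.asarray(sample_ids)
        pool = variants.sample_ids[mask]
        missing = np.setdiff1d(wanted, pool)
        if missing.size:
            raise KeyError(f"unknown sample ids {missing.tolist()} at timepoint {timepoint}")
        cols = np.flatnonzero(mask)
        id_to_col = {int(variants.sample_ids[c]): c for c in cols}
        sel = np.array([id_to_col[int(i)] for i in wanted])
    else:
        sel = np.flatnonzero(mask)
    return variants.dosages[:, sel].T.copy()
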