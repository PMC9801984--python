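"""Analysis-ready datasets: temporal sampling, WGS/RAD subsetting, export.

A :class:`SimulatedDataset` bundles the diploid dosages of the sampled
individuals across all chromosomes together with the sampling scheme, the
data-type specification (which fixes the monomorphic-inclusive site total L)
and provenance.  RAD-like data keeps only SNPs inside randomly placed,
non-overlapping 150-bp windows shared by all timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coalescent import VariantTable
from .sfs import FoldedSFS, folded_sfs, write_sfs_text

__all__ = [
    "SamplingScheme",
    "DataTypeSpec",
    "SimulatedDataset",
    "draw_samples",
    "assemble_dataset",
    "rad_subset",
    "apply_maf_filter",
    "write_vcf",
    "read_vcf",
]

SERIAL_YEARS = (0, 30, 60, 90, 120)
RAD_LOCUS_LENGTH = 150


@dataclass(frozen=True)
class SamplingScheme:
    kind: str  # contemporary | two_sample | serial
    n_total: int

    def __post_init__(self) -> None:
        if self.kind not in ("contemporary", "two_sample", "serial"):
            raise ValueError(f"unknown sampling scheme {self.kind!r}")
        if self.kind == "two_sample" and self.n_total % 2:
            raise ValueError("two_sample requires an even total sample size")
        if self.kind == "serial" and self.n_total % 5:
            raise ValueError("serial requires a total divisible by 5")

    @property
    def allocation(self) -> dict[int, int]:
        if self.kind == "contemporary":
            return {0: self.n_total}
        if self.kind == "two_sample":
            return {0: self.n_total // 2, 120: self.n_total // 2}
        return {y: self.n_total // 5 for y in SERIAL_YEARS}


@dataclass(frozen=True)
class DataTypeSpec:
    kind: str  # WGS | RAD
    loci_per_chromosome: int = 0
    locus_length: int = RAD_LOCUS_LENGTH
    genome_length: int = 25 * 30_000_000

    def __post_init__(self) -> None:
        if self.kind not in ("WGS", "RAD"):
            raise ValueError(f"unknown data type {self.kind!r}")
        if self.kind == "RAD" and self.loci_per_chromosome < 0:
            raise ValueError("loci_per_chromosome must be non-negative")

    def total_sites(self, n_chromosomes: int) -> float:
        if self.kind == "WGS":
            return float(self.genome_length)
        return float(self.locus_length * self.loci_per_chromosome * n_chromosomes)


@dataclass
class SimulatedDataset:
    """Genotypes of the sampled individuals at all retained SNPs."""

    chrom: np.ndarray  # per-site chromosome index
    positions: np.ndarray  # per-site position within chromosome
    dosages: np.ndarray  # (sites, individuals)
    sample_ids: np.ndarray
    sample_years: np.ndarray
    L: float  # monomorphic-inclusive total sites
    scheme: SamplingScheme
    data_type: DataTypeSpec
    chrom_lengths: dict[int, int]
    rad_windows: dict[int, np.ndarray] = field(default_factory=dict)  # chrom -> (k,2)
    provenance: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    def timepoints(self) -> list[int]:
        return sorted({int(y) for y in self.sample_years}, reverse=True)

    def genotypes(self, timepoint: int) -> np.ndarray:
        """(individuals x sites) dosages for one timepoint."""
        cols = np.flatnonzero(self.sample_years == timepoint)
        if cols.size == 0:
            raise KeyError(f"no samples at timepoint {timepoint}")
        return self.dosages[:, cols].T

    def folded_spectra(self) -> list[FoldedSFS]:
        return [
            folded_sfs(self.genotypes(t), L=self.L, timepoint=t)
            for t in self.timepoints()
        ]


def draw_samples(
    checkpoints: dict[int, np.ndarray],
    scheme: SamplingScheme,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Uniform without-replacement draws per timepoint according to the scheme."""
    chosen: dict[int, np.ndarray] = {}
    for year, count in scheme.allocation.items():
        if year not in checkpoints:
            raise KeyError(f"no recorded individuals at {year} ybp")
        pool = np.asarray(checkpoints[year])
        if pool.size < count:
            raise ValueError(
                f"requested {count} samples at {year} ybp but only {pool.size} recorded"
            )
        chosen[year] = np.sort(rng.choice(pool, size=count, replace=False))
    return chosen


def assemble_dataset(
    tables: list[VariantTable],
    chosen: dict[int, np.ndarray],
    scheme: SamplingScheme,
    data_type: DataTypeSpec,
    rng: np.random.Generator | None = None,
    provenance: dict | None = None,
) -> SimulatedDataset:
    """Column-select the chosen individuals and stack chromosomes.

    For RAD data the window subset is drawn here (once per dataset, shared
    by all timepoints) and L is set to 150 x total loci; for WGS, L is the
    summed chromosome length.
    """
    years = sorted(chosen, reverse=True)
    first = tables[0]
    col_idx = []
    for year in years:
        cols = np.flatnonzero(first.sample_years == year)
        id_to_col = {int(first.sample_ids[c]): int(c) for c in cols}
        for ind in chosen[year]:
            col_idx.append(id_to_col[int(ind)])
    col_idx = np.asarray(col_idx, dtype=int)

    chrom_parts, pos_parts, dos_parts = [], [], []
    chrom_lengths = {}
    for table in tables:
        chrom_lengths[table.chrom] = table.length_bp
        sub = table.dosages[:, col_idx]
        # drop sites monomorphic within the selected individuals
        tot = sub.sum(axis=1, dtype=np.int64)
        seg = (tot > 0) & (tot < 2 * col_idx.size)
        chrom_parts.append(np.full(int(seg.sum()), table.chrom, dtype=np.int32))
        pos_parts.append(table.positions[seg])
        dos_parts.append(sub[seg])

    n_chrom = len(tables)
    spec = data_type
    if spec.kind == "WGS":
        spec = replace(spec, genome_length=int(sum(chrom_lengths.values())))
    dataset = SimulatedDataset(
        chrom=np.concatenate(chrom_parts),
        positions=np.concatenate(pos_parts),
        dosages=np.concatenate(dos_parts),
        sample_ids=np.concatenate([chosen[y] for y in years]),
        sample_years=np.concatenate(
            [np.full(len(chosen[y]), y, dtype=np.int32) for y in years]
        ),
        L=spec.total_sites(n_chrom),
        scheme=scheme,
        data_type=spec,
        chrom_lengths=chrom_lengths,
        provenance=provenance or {},
    )
    if spec.kind == "RAD":
        dataset = rad_subset(dataset, spec, rng or np.random.default_rng(0))
    return dataset


def _place_windows(
    length: int, k: int, w: int, rng: np.random.Generator
) -> np.ndarray:
    """k non-overlapping w-bp windows uniformly placed on [0, length)."""
    slack = length - k * w
    if slack < 0:
        raise ValueError(f"cannot place {k} non-overlapping {w}-bp windows in {length} bp")
    gaps = np.sort(rng.integers(0, slack + 1, size=k))
    starts = gaps + w * np.arange(k)
    return np.column_stack([starts, starts + w])


def rad_subset(
    dataset: SimulatedDataset,
    spec: DataTypeSpec,
    rng: np.random.Generator,
) -> SimulatedDataset:
    """Keep only SNPs inside randomly placed non-overlapping RAD windows."""
    if spec.kind != "RAD":
        raise ValueError("rad_subset requires a RAD data type")
    keep = np.zeros(dataset.n_sites, dtype=bool)
    windows = {}
    for ch, length in sorted(dataset.chrom_lengths.items()):
        win = _place_windows(length, spec.loci_per_chromosome, spec.locus_length, rng)
        windows[ch] = win
        sites = np.flatnonzero(dataset.chrom == ch)
        if sites.size == 0 or win.shape[0] == 0:
            continue
        pos = dataset.positions[sites]
        slot = np.searchsorted(win[:, 0], pos, side="right") - 1
        inside = (slot >= 0) & (pos < win[np.maximum(slot, 0), 1])
        keep[sites[inside]] = True
    return replace(
        dataset,
        chrom=dataset.chrom[keep],
        positions=dataset.positions[keep],
        dosages=dataset.dosages[keep],
        L=spec.total_sites(len(dataset.chrom_lengths)),
        data_type=spec,
        rad_windows=windows,
    )


def apply_maf_filter(dataset: SimulatedDataset, threshold: float) -> SimulatedDataset:
    """Drop sites whose pooled (all timepoints) minor-allele frequency is below
    ``threshold``.  L is left unchanged."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    n_hap = 2 * dataset.dosages.shape[1]
    freq = dataset.dosages.sum(axis=1, dtype=np.int64) / n_hap
    keep = np.minimum(freq, 1 - freq) >= threshold
    return replace(
        dataset,
        chrom=dataset.chrom[keep],
        positions=dataset.positions[keep],
        dosages=dataset.dosages[keep],
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def sample_name(year: int, ind: int) -> str:
    return f"t{year}_ind{ind:03d}"


def write_vcf(dataset: SimulatedDataset, path) -> None:
    """Minimal VCF v4.2 with diploid GT fields and per-chromosome contigs."""
    names = [
        sample_name(int(y), int(i))
        for y, i in zip(dataset.sample_years, dataset.sample_ids)
    ]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=declinesim\n")
        for ch, length in sorted(dataset.chrom_lengths.items()):
            fh.write(f"##contig=<ID=chr{ch},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(names) + "\n")
        order = np.lexsort((dataset.positions, dataset.chrom))
        for row in order:
            gts = "\t".join(_GT[int(d)] for d in dataset.dosages[row])
            fh.write(
                f"chr{dataset.chrom[row]}\t{dataset.positions[row] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Read back a dosage matrix from a declinesim-style VCF (text, GT only)."""
    chroms, positions, rows = [], [], []
    names: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                names = parts[9:]
                continue
            chroms.append(int(parts[0].removeprefix("chr")))
            positions.append(int(parts[1]) - 1)
            rows.append([gt.count("1") for gt in parts[9:]])
    return (
        np.asarray(chroms, dtype=np.int32),
        np.asarray(positions, dtype=np.int64),
        np.asarray(rows, dtype=np.int8),
        names,
    )


def write_dataset_sfs(dataset: SimulatedDataset, path) -> None:
    write_sfs_text(path, dataset.folded_spectra())
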