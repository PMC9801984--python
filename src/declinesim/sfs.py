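"""Folded site-frequency spectra: observed, perturbed, and expected.

The expected-SFS engine computes, for a piecewise constant/exponential
diploid size history N(t), the expected number of sites at each derived
count via the numerically stable lineage-weight recursion, with the
size-history dependence entering only through the integrals

    c_j = int_0^inf exp(-binom(j,2) * Lambda(t)) dt,
    Lambda(t) = int_0^t ds / (2 N(s)),

which are evaluated analytically on constant pieces and by Gauss-Legendre
quadrature (in coalescent-intensity coordinates) on exponential pieces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "FoldedSFS",
    "PiecewiseSizeHistory",
    "folded_sfs",
    "inject_singletons",
    "expected_folded_sfs",
    "expected_unfolded_sfs",
    "fold",
    "write_sfs_text",
    "read_sfs_text",
]


# ---------------------------------------------------------------------------
# Observed folded SFS
# ---------------------------------------------------------------------------

@dataclass
class FoldedSFS:
    """Folded spectrum at one timepoint: counts for minor-allele bins 1..n//2."""

    timepoint: int
    n: int  # haplotypes
    L: float  # total sites including monomorphic
    counts: np.ndarray  # length n//2

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != self.n // 2:
            raise ValueError(f"expected {self.n // 2} bins for n={self.n}")
        if np.any(self.counts < 0):
            raise ValueError("negative SFS counts")

    @property
    def n_segregating(self) -> float:
        return float(self.counts.sum())


def folded_sfs(genotypes: np.ndarray, L: float, timepoint: int = 0) -> FoldedSFS:
    """Fold diploid dosages (individuals x sites) into a minor-allele spectrum.

    Sites monomorphic within the given individuals do not enter any bin.
    """
    genotypes = np.asarray(genotypes)
    n = 2 * genotypes.shape[0]
    derived = genotypes.sum(axis=0)
    minor = np.minimum(derived, n - derived)
    minor = minor[(minor > 0)]
    counts = np.bincount(minor.astype(int), minlength=n // 2 + 1)[1 : n // 2 + 1]
    return FoldedSFS(timepoint=timepoint, n=n, L=L, counts=counts.astype(float))


def inject_singletons(
    sfs: FoldedSFS, rate: float, rng: np.random.Generator | None = None
) -> FoldedSFS:
    """Add spurious singletons at ``rate`` per site (error model).

    Deterministic mode (default) adds round(rate * L); passing an ``rng``
    draws Poisson(rate * L) instead.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    extra = rng.poisson(rate * sfs.L) if rng is not None else round(rate * sfs.L)
    counts = sfs.counts.copy()
    counts[0] += extra
    return replace(sfs, counts=counts)


# ---------------------------------------------------------------------------
# Size histories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PiecewiseSizeHistory:
    """Diploid size history N(t) backward in time (t in generations).

    Within piece i (t in [breaks[i], breaks[i+1]), last piece unbounded):
    N(t) = sizes[i] * exp(betas[i] * (t - breaks[i])).  The final piece must
    be constant so the deep-time coalescent integrals converge.
    """

    breaks: tuple[float, ...]  # piece start times; breaks[0] == 0
    sizes: tuple[float, ...]  # N at each piece start
    betas: tuple[float, ...]  # backward growth rates

    def __post_init__(self) -> None:
        if not (len(self.breaks) == len(self.sizes) == len(self.betas)):
            raise ValueError("breaks/sizes/betas must have equal length")
        if self.breaks[0] != 0:
            raise ValueError("history must start at t=0")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly increasing")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("sizes must be positive")
        if self.betas[-1] != 0:
            raise ValueError("final piece must be constant")

    @classmethod
    def constant(cls, N: float) -> "PiecewiseSizeHistory":
        return cls((0.0,), (float(N),), (0.0,))

    def size_at(self, t: float) -> float:
        i = int(np.searchsorted(self.breaks, t, side="right")) - 1
        return self.sizes[i] * np.exp(self.betas[i] * (t - self.breaks[i]))

    def shifted(self, g: float) -> "PiecewiseSizeHistory":
        """The history as seen from sampling time ``g`` generations ago."""
        if g < 0:
            raise ValueError("shift must be non-negative")
        if g == 0:
            return self
        breaks, sizes, betas = [0.0], [self.size_at(g)], []
        i = int(np.searchsorted(self.breaks, g, side="right")) - 1
        betas.append(self.betas[i])
        for j in range(i + 1, len(self.breaks)):
            breaks.append(self.breaks[j] - g)
            sizes.append(self.sizes[j])
            betas.append(self.betas[j])
        return PiecewiseSizeHistory(tuple(breaks), tuple(sizes), tuple(betas))

    def intensity_increments(self) -> np.ndarray:
        """Delta Lambda over each bounded piece (last piece is unbounded)."""
        out = []
        for i in range(len(self.breaks) - 1):
            dt = self.breaks[i + 1] - self.breaks[i]
            N, beta = self.sizes[i], self.betas[i]
            if beta == 0:
                out.append(dt / (2 * N))
            else:
                out.append((1 - np.exp(-beta * dt)) / (2 * N * beta))
        return np.asarray(out)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)
_EXP_CUTOFF = 60.0  # e-folds beyond which piece contributions are negligible


def _coalescent_integrals(history: PiecewiseSizeHistory, n: int) -> np.ndarray:
    """c_j = E-type integrals for j = 2..n lineages (vector of length n-1)."""
    j = np.arange(2, n + 1)
    a = j * (j - 1) / 2.0  # coalescent rate per unit Lambda, times 2N
    dlam = history.intensity_increments()
    lam0 = np.concatenate([[0.0], np.cumsum(dlam)])
    c = np.zeros_like(a)
    n_pieces = len(history.breaks)
    for i in range(n_pieces):
        N, beta = history.sizes[i], history.betas[i]
        pre = np.exp(-a * lam0[i])
        if i == n_pieces - 1:
            c += pre * 2 * N / a
        elif beta == 0:
            c += pre * (2 * N / a) * (1 - np.exp(-a * dlam[i]))
        else:
            # integrate in v = Lambda increments: dt = 2 N0/(1 - 2 N0 beta v) dv
            b = np.minimum(dlam[i], _EXP_CUTOFF / a)
            half = b / 2.0
            v = half[None, :] * (_GL_NODES[:, None] + 1.0)  # (nodes, j)
            integrand = np.exp(-a[None, :] * v) * (2 * N) / (1 - 2 * N * beta * v)
            c += pre * half * np.einsum("k,kj->j", _GL_WEIGHTS, integrand)
    return c


@lru_cache(maxsize=32)
def _sfs_weights(n: int) -> np.ndarray:
    """W[b-1, j-2] such that E[xi_b] = mu*L * sum_j W[b,j] c_j (stable recursion)."""
    if n < 2:
        raise ValueError("need n >= 2")
    b = np.arange(1, n)
    W = np.zeros((n - 1, n - 1))
    W[:, 0] = 6.0 / (n + 1)
    if n >= 3:
        W[:, 1] = 30.0 * (n - 2 * b) / ((n + 1) * (n + 2))
    for j in range(2, n - 1):
        # recursion producing column for j+2 from columns j and j+1
        jj = j  # current highest filled column corresponds to lineage count jj+1
        col_j = W[:, j - 2]
        col_j1 = W[:, j - 1]
        W[:, j] = (
            -(1.0 + jj) * (3.0 + 2.0 * jj) * (n - jj) / (jj * (2.0 * jj - 1.0) * (n + jj + 1.0)) * col_j
            + (3.0 + 2.0 * jj) * (n - 2.0 * b) / (jj * (n + jj + 1.0)) * col_j1
        )
    return W


def expected_unfolded_sfs(
    history: PiecewiseSizeHistory, n: int, L: float, mu: float
) -> np.ndarray:
    """Expected counts of sites with derived-allele count b = 1..n-1."""
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    c = _coalescent_integrals(history, n)
    W = _sfs_weights(n)
    return mu * L * (W @ c)


def fold(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded spectrum (bins 1..n-1) into minor-allele bins 1..n//2."""
    n = unfolded.shape[0] + 1
    half = n // 2
    folded = np.empty(half)
    for b in range(1, half + 1):
        if b == n - b:
            folded[b - 1] = unfolded[b - 1]
        else:
            folded[b - 1] = unfolded[b - 1] + unfolded[n - b - 1]
    return folded


def expected_folded_sfs(
    history: PiecewiseSizeHistory,
    n: int,
    L: float,
    mu: float,
    sample_time_generations: float = 0.0,
    timepoint: int = 0,
) -> FoldedSFS:
    """Expected folded SFS for ``n`` haplotypes sampled at the given time.

    The history is truncated at the sampling time: what matters is N(t)
    for t at or before the sample's age.
    """
    hist = history.shifted(sample_time_generations)
    unfolded = expected_unfolded_sfs(hist, n, L, mu)
    return FoldedSFS(timepoint=timepoint, n=n, L=L, counts=fold(unfolded))


# ---------------------------------------------------------------------------
# Text round-trip (one line per timepoint)
# ---------------------------------------------------------------------------

def write_sfs_text(path, spectra: list[FoldedSFS]) -> None:
    with open(path, "w") as fh:
        fh.write("# timepoint\tn_haplotypes\tL\tcounts...\n")
        for sfs in sorted(spectra, key=lambda s: -s.timepoint):
            counts = "\t".join(repr(float(c)) for c in sfs.counts)
            fh.write(f"{sfs.timepoint}\t{sfs.n}\t{sfs.L!r}\t{counts}\n")


def read_sfs_text(path) -> list[FoldedSFS]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split("\t")
            timepoint, n = int(parts[0]), int(parts[1])
            L = float(parts[2])
            counts = np.array([float(x) for x in parts[3:]])
            out.append(FoldedSFS(timepoint=timepoint, n=n, L=L, counts=counts))
    return out
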