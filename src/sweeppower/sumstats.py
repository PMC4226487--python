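"""Summary statistics on haplotype matrices.

All statistics consume the polymorphic-site :class:`HaplotypeMatrix`; the
spectrum is unfolded (ancestral states are known by construction in the
simulation output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import HaplotypeMatrix

__all__ = [
    "SiteFrequencySpectrum",
    "LDMatrix",
    "sfs",
    "fold_spectrum",
    "pi",
    "pi_in_window",
    "watterson_theta",
    "tajimas_d",
    "r2_matrix",
    "ld_decay",
]


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """Unfolded SFS: ``counts[j-1]`` = number (or fraction) of sites at derived count j."""

    counts: np.ndarray
    n: int
    normalized: bool = False

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (self.n - 1,):
            raise ValueError(f"counts must have length n-1={self.n - 1}")
        if np.any(counts < 0):
            raise ValueError("spectrum counts must be >= 0")
        if self.normalized and counts.sum() > 0 and not np.isclose(counts.sum(), 1.0):
            raise ValueError("normalized spectrum must sum to 1")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalize(self) -> "SiteFrequencySpectrum":
        tot = self.total
        if tot == 0:
            raise ValueError("cannot normalize an empty spectrum")
        return SiteFrequencySpectrum(self.counts / tot, self.n, normalized=True)


@dataclass(frozen=True)
class LDMatrix:
    """Symmetric matrix of squared allele-frequency correlations r^2."""

    r2: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "r2", r2)
        object.__setattr__(self, "positions", pos)
        if r2.shape != (pos.size, pos.size):
            raise ValueError("r2 must be S x S with one position per site")

    @property
    def S(self) -> int:
        return self.positions.size


def sfs(h: HaplotypeMatrix) -> SiteFrequencySpectrum:
    """Unfolded site-frequency spectrum of the matrix."""
    counts = np.bincount(h.derived_counts(), minlength=h.n + 1)[1 : h.n]
    return SiteFrequencySpectrum(counts.astype(float), h.n)


def fold_spectrum(b: SiteFrequencySpectrum) -> np.ndarray:
    """Minor-allele folding helper (not used by the scan pipeline)."""
    n = b.n
    folded = np.zeros(n // 2, dtype=float)
    for j in range(1, n):
        k = min(j, n - j)
        folded[k - 1] += b.counts[j - 1] * (0.5 if 2 * j == n else 1.0)
        if 2 * j == n:
            folded[k - 1] += b.counts[j - 1] * 0.5
    return folded


def pi(h: HaplotypeMatrix) -> float:
    """Pairwise nucleotide diversity per site.

    ``sum_i 2 k_i (n - k_i) / (n (n-1)) / L`` over polymorphic sites.
    """
    n = h.n
    if n < 2:
        raise ValueError("pi requires n >= 2")
    k = h.derived_counts()
    return float(np.sum(2.0 * k * (n - k)) / (n * (n - 1)) / h.L)


def pi_in_window(h: HaplotypeMatrix, center: float, half_width: float) -> float:
    """Per-site diversity restricted to sites within ``center +- half_width``."""
    n = h.n
    mask = np.abs(h.positions - center) <= half_width
    k = h.derived_counts()[mask]
    width = 2.0 * half_width
    return float(np.sum(2.0 * k * (n - k)) / (n * (n - 1)) / width)


def _harmonic(m: int) -> float:
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def watterson_theta(h: HaplotypeMatrix, per_site: bool = True) -> float:
    """Watterson's estimator S / a_{n-1}, per site by default."""
    theta = h.S / _harmonic(h.n - 1)
    return theta / h.L if per_site else theta


def tajimas_d(h: HaplotypeMatrix) -> float:
    """Tajima's D with the standard variance normalization.

    Returns NaN when the matrix has no segregating sites (undefined, not 0).
    """
    n, S = h.n, h.S
    if S == 0:
        return float("nan")
    a1 = _harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi_region = pi(h) * h.L
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_region - S / a1) / np.sqrt(var))


def r2_matrix(h: HaplotypeMatrix) -> LDMatrix:
    """Squared correlation of allelic state for every pair of sites."""
    if h.S < 2:
        raise ValueError("r2 requires at least two sites")
    counts = h.derived_counts()
    if counts.min() < 1 or counts.max() > h.n - 1:
        raise ValueError("monomorphic columns must be filtered before LD")
    g = h.alleles.astype(float)
    g -= g.mean(axis=0)
    cov = g.T @ g
    sd = np.sqrt(np.diag(cov))
    r = cov / np.outer(sd, sd)
    return LDMatrix(r2=r * r, positions=h.positions)


def ld_decay(ld: LDMatrix, bin_edges: np.ndarray) -> "pd.DataFrame":
    """Per-distance-bin median / mean / 95th percentile of r^2.

    Bins with no site pairs are reported as NaN rows, not zeros.
    """
    import pandas as pd

    iu = np.triu_indices(ld.S, k=1)
    dist = np.abs(ld.positions[iu[1]] - ld.positions[iu[0]])
    vals = ld.r2[iu]
    bin_edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(dist, bin_edges) - 1
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = vals[which == b]
        mid = 0.5 * (bin_edges[b] + bin_edges[b + 1])
        if sel.size == 0:
            rows.append((mid, 0, np.nan, np.nan, np.nan))
        else:
            rows.append(
                (mid, sel.size, float(np.median(sel)), float(np.mean(sel)),
                 float(np.quantile(sel, 0.95)))
            )
    return pd.DataFrame(
        rows, columns=["distance_bp", "n_pairs", "median_r2", "mean_r2", "q95_r2"]
    )
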