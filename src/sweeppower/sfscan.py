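"""Composite-likelihood-ratio sweep scan against the background SFS.

The null model for each polymorphic site is the background site-frequency
spectrum ``b``.  The sweep alternative at a test position distorts the
spectrum as a function of the scaled distance ``alpha * d`` between the site
and the position: each of the ``n`` sampled lineages escapes the sweep
independently with probability ``p_e = 1 - exp(-alpha * d)``; the
non-escaping lineages collapse onto the single swept ancestor.  The
ancestral configuration of the ``e`` escapees plus the swept ancestor is
drawn from the background spectrum projected down to ``e + 1`` lineages
(hypergeometric downsampling), the swept ancestor's allele is copied to all
``n - e`` collapsed lineages, and the result is conditioned on polymorphism.
The scan statistic is

    Lambda(X) = 2 * [ max_alpha sum_i log P(k_i | alpha, d_i)
                      - sum_i log b(k_i) ]

maximized over a logarithmic grid of sweep intensities ``alpha`` that
includes the background itself (alpha -> infinity), so Lambda >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom, hypergeom

from .models import StudyConfig
from .simulate import HaplotypeMatrix
from .sumstats import SiteFrequencySpectrum, sfs

__all__ = [
    "ScanResult",
    "background_spectrum",
    "downsample_spectrum",
    "sweep_site_probability",
    "default_alpha_grid",
    "clr_scan",
]


@dataclass(frozen=True)
class ScanResult:
    """Per-position profile of a genome-scan statistic."""

    grid_positions: np.ndarray
    statistic: np.ndarray
    arg_alpha: Optional[np.ndarray]  # maximizing nuisance parameter (scan-specific)
    max_value: float
    max_position: float
    name: str = ""

    @classmethod
    def from_profile(cls, positions: np.ndarray, values: np.ndarray,
                     arg_alpha: Optional[np.ndarray] = None,
                     name: str = "") -> "ScanResult":
        values = np.asarray(values, dtype=float)
        finite = np.where(np.isnan(values), -np.inf, values)
        imax = int(np.argmax(finite))
        return cls(
            grid_positions=np.asarray(positions, dtype=float),
            statistic=values,
            arg_alpha=arg_alpha,
            max_value=float(values[imax]),
            max_position=float(positions[imax]),
            name=name,
        )


def grid_positions(L: float, spacing: float) -> np.ndarray:
    """Uniform test-position grid covering [0, L] inclusive."""
    n_steps = int(np.floor(L / spacing + 1e-9))
    return np.arange(n_steps + 1) * spacing


def background_spectrum(
    h: HaplotypeMatrix, extra: Sequence[HaplotypeMatrix] = ()
) -> SiteFrequencySpectrum:
    """Normalized unfolded SFS pooled over the focal and any extra regions."""
    counts = sfs(h).counts.copy()
    for other in extra:
        if other.n != h.n:
            raise ValueError("all pooled regions must share the sample size")
        counts += sfs(other).counts
    if counts.sum() == 0:
        raise ValueError("background spectrum is empty (no segregating sites)")
    return SiteFrequencySpectrum(counts / counts.sum(), h.n, normalized=True)


def downsample_spectrum(b: SiteFrequencySpectrum, m: int) -> np.ndarray:
    """Hypergeometric projection of the spectrum to a subsample of size m.

    Returns the full length-``m + 1`` probability vector over derived counts
    ``0..m``; the monomorphic classes are retained because the sweep mixture
    needs them.  ``P(k of m | j of n) = C(j,k) C(n-j,m-k) / C(n,m)``.
    """
    n = b.n
    if not 1 <= m <= n:
        raise ValueError(f"target size m={m} must be in [1, n={n}]")
    p = b.counts / b.counts.sum() if not b.normalized else b.counts
    out = np.zeros(m + 1)
    k = np.arange(m + 1)
    for j in range(1, n):
        if p[j - 1] == 0:
            continue
        out += p[j - 1] * hypergeom.pmf(k, n, j, m)
    return out


def _mixture_table(b: SiteFrequencySpectrum) -> np.ndarray:
    """T[e, k] = P(derived count k in the sample | e escaping lineages).

    Rows ``e = 0..n``; columns ``k = 0..n`` (unconditioned on polymorphism).
    For ``e < n``: the ancestral configuration of ``e`` escapees + 1 swept
    lineage carries ``j'`` derived copies with probability given by the
    projected background; the swept lineage is derived with probability
    ``j'/(e+1)``, in which case its allele appears in the ``n - e`` collapsed
    descendants.  ``e = n`` recovers the background itself.
    """
    n = b.n
    T = np.zeros((n + 1, n + 1))
    for e in range(n):
        m = e + 1
        q = downsample_spectrum(b, m)
        for jp in range(m + 1):
            if q[jp] == 0:
                continue
            p_swept = jp / m
            if p_swept > 0:
                k_hot = (n - e) + (jp - 1)
                T[e, k_hot] += q[jp] * p_swept
            if p_swept < 1:
                T[e, jp] += q[jp] * (1.0 - p_swept)
    p = b.counts / b.counts.sum() if not b.normalized else b.counts
    T[n, 1:n] = p
    return T


def sweep_site_probability(
    b: SiteFrequencySpectrum, d: float, alpha: float, k: int, n: int
) -> float:
    """P(derived count k | sweep at distance d with intensity alpha).

    Conditioned on the site being polymorphic in the sample.  In the limit
    ``alpha * d -> infinity`` every lineage escapes and the background
    probability ``b_k`` is recovered.
    """
    if not 1 <= k <= n - 1:
        raise ValueError(f"derived count k={k} outside [1, n-1]")
    if d < 0 or alpha < 0:
        raise ValueError("alpha and d must be >= 0")
    T = _mixture_table(b)
    dist = _site_distribution(T, n, 1.0 - np.exp(-alpha * d))
    return float(dist[k - 1])


def _site_distribution(T: np.ndarray, n: int, p_escape: float) -> np.ndarray:
    """Polymorphism-conditioned distribution over k=1..n-1 for one p_escape."""
    if p_escape <= 0.0:
        # limit alpha*d -> 0: the first-order term is the single-escapee
        # configuration (all-collapsed sites are monomorphic and condition away)
        mix = T[1]
    else:
        w = binom.pmf(np.arange(n + 1), n, p_escape)
        mix = w @ T
    poly = mix[1:n]
    tot = poly.sum()
    if tot <= 0:
        raise FloatingPointError("degenerate sweep-site distribution")
    return poly / tot


def default_alpha_grid(L: float, n_points: int = 40) -> np.ndarray:
    """Logarithmic grid of sweep intensities (per bp).

    Spans escape probabilities from ~1e-6 to ~1 at the region half-width;
    ``alpha = inf`` (the background/null model) is appended so the sweep
    family always contains the null and Lambda >= 0.
    """
    half = L / 2.0
    lo = 1e-6 / half
    hi = 20.0 / half * 1000.0  # p_e ~ 1 already ~1/1000 of the half-width away
    grid = np.geomspace(lo, hi, n_points)
    return np.append(grid, np.inf)


class _ClrTables:
    """Precomputed log-probability tables over a log-spaced alpha*d lattice."""

    def __init__(self, b: SiteFrequencySpectrum, n_lattice: int = 512):
        n = b.n
        self.n = n
        T = _mixture_table(b)
        self.ad_lattice = np.geomspace(1e-8, 60.0, n_lattice)
        self.log_ad = np.log(self.ad_lattice)
        logP = np.empty((n_lattice, n - 1))
        with np.errstate(divide="ignore"):
            for g, ad in enumerate(self.ad_lattice):
                logP[g] = np.log(_site_distribution(T, n, 1.0 - np.exp(-ad)))
        # floor so interpolation between an empty class and a populated one
        # stays finite (an empty class at some alpha just vetoes that alpha)
        self.logP = np.maximum(logP, -745.0)
        p = b.counts / b.counts.sum() if not b.normalized else b.counts
        with np.errstate(divide="ignore"):
            self.log_b = np.log(p)

    def site_loglik(self, ad: np.ndarray, k_idx: np.ndarray) -> np.ndarray:
        """log P(k | alpha*d) with linear interpolation on log(alpha*d).

        ``ad`` may be any shape; ``k_idx`` (0-based, = k-1) broadcasts with it.
        Values beyond the lattice ends saturate (below: full collapse;
        above: background).
        """
        ad = np.clip(ad, self.ad_lattice[0], self.ad_lattice[-1])
        x = np.log(ad)
        j = np.clip(np.searchsorted(self.log_ad, x), 1, len(self.log_ad) - 1)
        x0 = self.log_ad[j - 1]
        x1 = self.log_ad[j]
        w = (x - x0) / (x1 - x0)
        return (1.0 - w) * self.logP[j - 1, k_idx] + w * self.logP[j, k_idx]


def clr_scan(
    h: HaplotypeMatrix,
    b: Optional[SiteFrequencySpectrum] = None,
    study: Optional[StudyConfig] = None,
    alpha_grid: Optional[np.ndarray] = None,
) -> ScanResult:
    """Composite-likelihood-ratio profile over a uniform position grid.

    ``b`` defaults to the spectrum of ``h`` itself (single-locus scan); pass
    a pooled spectrum to emulate a genome-wide background.
    """
    if h.S < 1:
        raise ValueError("scan requires at least one segregating site")
    study = study or StudyConfig()
    if b is None:
        b = background_spectrum(h)
    if alpha_grid is None:
        alpha_grid = default_alpha_grid(h.L)
    tables = _ClrTables(b)

    positions = grid_positions(h.L, study.grid_spacing_bp)
    k_idx = h.derived_counts() - 1
    null_ll = float(tables.log_b[k_idx].sum())
    dists = np.abs(positions[:, None] - h.positions[None, :])  # (G, S)

    best = np.full(positions.shape, -np.inf)
    best_alpha = np.zeros(positions.shape)
    for alpha in alpha_grid:
        if np.isinf(alpha):
            ll = np.full(positions.shape, null_ll)
        else:
            ll = tables.site_loglik(alpha * dists, k_idx[None, :]).sum(axis=1)
        better = ll > best
        best[better] = ll[better]
        best_alpha[better] = alpha
    lam = 2.0 * (best - null_ll)
    return ScanResult.from_profile(positions, lam, best_alpha, name="lambda_sf")
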