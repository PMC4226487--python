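"""The omega statistic: sweep detection from the spatial pattern of LD.

A completed hard sweep leaves elevated linkage disequilibrium within each
flank of the swept site but reduced LD across it.  For a window of S_w sites
split into a left block of ``ell`` and a right block of ``S_w - ell`` sites,

    omega = [ (C(ell,2) + C(S_w-ell,2))^-1 * (sum r2 within left
                                              + sum r2 within right) ]
            / [ (ell * (S_w - ell))^-1 * sum r2 across ]

(the Kim-Nielsen form).  The scan maximizes omega over split points and
window extents around each grid position; the region-wide maximum is
omega_max.  A window whose across-block r2 sum is exactly zero yields an
infinite omega, reported as ``inf`` (exceeding any finite threshold).
"""

from __future__ import annotations

from typing import Optional, Sequence
import warnings

import numpy as np

from .models import StudyConfig
from .simulate import HaplotypeMatrix
from .sfscan import ScanResult, grid_positions
from .sumstats import LDMatrix, r2_matrix

__all__ = ["omega_at_split", "omega_max_scan"]

DEFAULT_MAX_HALF_WINDOW_BP = 25_000.0
DEFAULT_MAX_SITES_PER_SIDE = 50


def omega_at_split(ld: LDMatrix, window_site_indices: Sequence[int], ell: int) -> float:
    """Omega for one window (contiguous site indices) and one split point.

    The first ``ell`` window sites form the left block.  Returns ``inf``
    when the across-block r2 sum is exactly zero (perfectly dissociated
    blocks) and NaN if the within sums vanish as well.
    """
    idx = np.asarray(window_site_indices, dtype=int)
    sw = idx.size
    if sw < 4:
        raise ValueError("omega needs at least 4 sites in the window")
    if not 2 <= ell <= sw - 2:
        raise ValueError(f"split ell={ell} must be in [2, {sw - 2}]")
    sub = ld.r2[np.ix_(idx, idx)]
    left = sub[:ell, :ell]
    right = sub[ell:, ell:]
    across = sub[:ell, ell:]
    nl, nr = ell, sw - ell
    within = (left.sum() - nl) / 2.0 + (right.sum() - nr) / 2.0
    pairs_within = nl * (nl - 1) // 2 + nr * (nr - 1) // 2
    num = within / pairs_within
    den = across.sum() / (nl * nr)
    if den == 0.0:
        return float("inf") if num > 0 else float("nan")
    return float(num / den)


def _prefix2d(r2: np.ndarray) -> np.ndarray:
    P = np.zeros((r2.shape[0] + 1, r2.shape[1] + 1))
    P[1:, 1:] = r2.cumsum(axis=0).cumsum(axis=1)
    return P


def omega_max_scan(
    h: HaplotypeMatrix,
    study: Optional[StudyConfig] = None,
    max_half_window_bp: float = DEFAULT_MAX_HALF_WINDOW_BP,
    max_sites_per_side: int = DEFAULT_MAX_SITES_PER_SIDE,
    ld: Optional[LDMatrix] = None,
) -> ScanResult:
    """Profile of the split-maximized omega over a uniform position grid.

    At each grid position the split point is the position itself; the left
    (right) block is the nearest ``ell_L`` (``ell_R``) sites within
    ``max_half_window_bp``, with 2 <= ell <= ``max_sites_per_side`` searched
    exhaustively on both sides.  Positions with fewer than two sites on
    either side get NaN.
    """
    study = study or StudyConfig()
    if h.S < 4:
        warnings.warn("fewer than 4 segregating sites: omega profile is all-NaN",
                      stacklevel=2)
        positions = grid_positions(h.L, study.grid_spacing_bp)
        return ScanResult.from_profile(
            positions, np.full(positions.shape, np.nan), name="omega")
    if ld is None:
        ld = r2_matrix(h)
    pos = ld.positions
    S = pos.size
    P = _prefix2d(ld.r2)

    positions = grid_positions(h.L, study.grid_spacing_bp)
    values = np.full(positions.shape, np.nan)
    for gi, X in enumerate(positions):
        iR = int(np.searchsorted(pos, X, side="right"))  # first site right of X
        iL = iR - 1
        lo = int(np.searchsorted(pos, X - max_half_window_bp, side="left"))
        hi = int(np.searchsorted(pos, X + max_half_window_bp, side="right")) - 1
        nL = min(iL - lo + 1, max_sites_per_side)
        nR = min(hi - iR + 1, max_sites_per_side)
        if nL < 2 or nR < 2:
            continue
        ells_L = np.arange(2, nL + 1)
        ells_R = np.arange(2, nR + 1)
        starts = iL - ells_L + 1          # left-block start index per ell_L
        ends = iR + ells_R                # one past right-block end per ell_R

        # within-block sums via the diagonal rectangle identity
        wl = np.array([
            (P[iL + 1, iL + 1] - 2 * P[a, iL + 1] + P[a, a] - (iL + 1 - a)) / 2.0
            for a in starts
        ])
        wr = np.array([
            (P[e, e] - 2 * P[iR, e] + P[iR, iR] - (e - iR)) / 2.0
            for e in ends
        ])
        across = (
            P[iL + 1, ends][None, :]
            - P[starts, :][:, ends]
            - P[iL + 1, iR]
            + P[starts, iR][:, None]
        )
        pairs_l = ells_L * (ells_L - 1) / 2.0
        pairs_r = ells_R * (ells_R - 1) / 2.0
        num = (wl[:, None] + wr[None, :]) / (pairs_l[:, None] + pairs_r[None, :])
        denom_pairs = ells_L[:, None] * ells_R[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            omega = num / (across / denom_pairs)
        omega = np.where(across <= 0.0, np.where(num > 0, np.inf, np.nan), omega)
        if np.all(np.isnan(omega)):
            continue
        values[gi] = np.nanmax(omega)
    if np.all(np.isnan(values)):
        warnings.warn("no grid position had enough flanking sites for omega",
                      stacklevel=2)
    return ScanResult.from_profile(positions, values, name="omega")
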