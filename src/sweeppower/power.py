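"""Neutral-threshold calibration and the sweep-detection power study.

Significance is calibrated per demographic/selection case from neutral
simulations under the same demography with the mutation rate rescaled so the
expected number of segregating sites matches the sweep replicates (the
"theta fit to each case" convention).  The cutoff is the empirical
``(1 - alpha)`` quantile of the per-replicate maximum statistic.  A sweep
replicate counts as a true positive when some grid position inside the
target window exceeds the cutoff, and as a false positive when some
position outside the window does; one replicate can be both.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import DemographicModel, RegionConfig, StudyConfig, SweepModel
from .omegascan import omega_max_scan
from .sfscan import ScanResult, background_spectrum, clr_scan
from .simulate import (
    HaplotypeMatrix,
    simulate_neutral_sample,
    simulate_sweep_sample,
)
from .sumstats import pi, tajimas_d

logger = logging.getLogger("sweeppower")

__all__ = [
    "ThresholdSet",
    "PowerTable",
    "scan_statistic",
    "calibrate_threshold",
    "classify_replicate",
    "expected_sweep_width",
    "run_power_study",
    "rejection_window_curve",
]

STATISTICS = ("sweepfinder", "omega")


def scan_statistic(name: str) -> Callable[[HaplotypeMatrix, StudyConfig], ScanResult]:
    """Scan callable for a statistic name (``sweepfinder`` or ``omega``)."""
    if name == "sweepfinder":
        return lambda h, study: clr_scan(h, study=study)
    if name == "omega":
        return lambda h, study: omega_max_scan(h, study=study)
    raise ValueError(f"unknown statistic {name!r}; expected one of {STATISTICS}")


def _do_scan(
    h: HaplotypeMatrix,
    stat: str,
    study: StudyConfig,
    model: Optional[DemographicModel] = None,
    region: Optional[RegionConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> ScanResult:
    """One scan, honouring the extra-neutral-background-region option."""
    if stat == "sweepfinder":
        b = None
        if study.extra_neutral_regions and model is not None:
            extras = [
                simulate_neutral_sample(model, region, rng)
                for _ in range(study.extra_neutral_regions)
            ]
            b = background_spectrum(h, extras)
        return clr_scan(h, b=b, study=study)
    if stat == "omega":
        return omega_max_scan(h, study=study)
    raise ValueError(f"unknown statistic {stat!r}; expected one of {STATISTICS}")


@dataclass(frozen=True)
class ThresholdSet:
    """Empirical null cutoff for one statistic under one demography."""

    statistic: str
    cutoff: float
    alpha_level: float
    n_null_replicates: int
    model: DemographicModel
    mu_null: float  # per-site rate used for the theta-matched null

    def is_significant(self, value: float) -> bool:
        return value > self.cutoff


def _order_statistic_quantile(values: np.ndarray, q: float) -> float:
    """The ceil(q*n)-th order statistic (the '95th percentile' convention)."""
    v = np.sort(values)
    idx = min(int(np.ceil(q * v.size)) - 1, v.size - 1)
    return float(v[max(idx, 0)])


def calibrate_threshold(
    model: DemographicModel,
    region: RegionConfig,
    study: StudyConfig,
    statistic: str,
    seed,
    target_mean_segsites: Optional[float] = None,
    n_pilot: int = 20,
) -> ThresholdSet:
    """Cutoff = (1 - alpha) empirical quantile of null maxima.

    When ``target_mean_segsites`` is given (Watterson-matched calibration),
    a pilot null set estimates the expected S under the demography at the
    base mutation rate and ``mu`` is rescaled so the null matches the sweep
    replicates' segregating-site count.
    """
    if study.n_null_replicates < 20:
        raise ValueError("need at least 20 null replicates to calibrate")
    rng = np.random.default_rng(seed)
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")

    mu_null = region.mu
    if target_mean_segsites is not None:
        pilot_S = [
            simulate_neutral_sample(model, region, rng).S for _ in range(n_pilot)
        ]
        mean_pilot = float(np.mean(pilot_S))
        if mean_pilot > 0:
            mu_null = region.mu * target_mean_segsites / mean_pilot
    null_region = dataclasses.replace(region, mu=mu_null)

    maxima = np.empty(study.n_null_replicates)
    for i in range(study.n_null_replicates):
        h = simulate_neutral_sample(model, null_region, rng)
        if h.S < (4 if statistic == "omega" else 1):
            maxima[i] = -np.inf
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            maxima[i] = _do_scan(h, statistic, study, model, null_region, rng).max_value
    finite = maxima[np.isfinite(maxima)]
    if finite.size and np.all(finite == finite[0]):
        warnings.warn("degenerate null sample: all maxima identical", stacklevel=2)
    cutoff = _order_statistic_quantile(maxima, 1.0 - study.alpha_level)
    logger.info(
        "calibrated %s threshold %.4g (alpha=%.3g, %d nulls, mu_null=%.3g)",
        statistic, cutoff, study.alpha_level, study.n_null_replicates, mu_null,
    )
    return ThresholdSet(
        statistic=statistic,
        cutoff=cutoff,
        alpha_level=study.alpha_level,
        n_null_replicates=study.n_null_replicates,
        model=model,
        mu_null=mu_null,
    )


def classify_replicate(
    scan: ScanResult,
    threshold: ThresholdSet,
    x_sel: float,
    tp_window_bp: float,
) -> tuple[bool, bool]:
    """(is_TP, is_FP) for one scanned sweep replicate.

    The target window is ``tp_window_bp`` wide, centered on the selected
    site.  Both flags may be true for a single replicate.
    """
    with np.errstate(invalid="ignore"):
        sig = scan.statistic > threshold.cutoff
    inside = np.abs(scan.grid_positions - x_sel) <= tp_window_bp / 2.0
    is_tp = bool(np.any(sig & inside))
    is_fp = bool(np.any(sig & ~inside))
    return is_tp, is_fp


def expected_sweep_width(s: float, r: float) -> float:
    """Approximate physical extent of a sweep footprint: 0.01 * s / r bp."""
    if r <= 0:
        raise ValueError("recombination rate must be > 0 for the width heuristic")
    return 0.01 * s / r


@dataclass
class PowerTable:
    """TP/FP percentages per (model, selection, statistic) cell."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _replicate_scans(
    model: DemographicModel,
    sweep: SweepModel,
    region: RegionConfig,
    study: StudyConfig,
    statistics: Sequence[str],
    rng: np.random.Generator,
    fixed_trajectory_mode: str = "auto",
) -> tuple[dict[str, list[ScanResult]], list[HaplotypeMatrix]]:
    scans: dict[str, list[ScanResult]] = {s: [] for s in statistics}
    reps: list[HaplotypeMatrix] = []
    for _ in range(study.n_replicates):
        h = simulate_sweep_sample(
            model, sweep, region, rng, trajectory_mode=fixed_trajectory_mode
        )
        reps.append(h)
        for stat in statistics:
            if h.S < (4 if stat == "omega" else 1):
                scans[stat].append(None)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scans[stat].append(_do_scan(h, stat, study, model, region, rng))
    return scans, reps


def run_power_study(
    cells: Sequence[tuple[DemographicModel, SweepModel]],
    region: RegionConfig,
    study: StudyConfig,
    statistics: Sequence[str] = STATISTICS,
    master_seed: Optional[int] = None,
    neutral_fpr_mode: bool = False,
    collect_sumstats: bool = False,
) -> PowerTable:
    """Simulate, calibrate, scan and classify every (demography, sweep) cell.

    ``neutral_fpr_mode`` additionally scores fresh neutral replicates
    against the cutoffs (region-wide rejection rate), reported in the
    ``neutral_fpr`` columns.  Per-cell failures are logged and marked NaN,
    not fatal.
    """
    seed = study.seed if master_seed is None else master_seed
    rows = []
    for ci, (model, sweep) in enumerate(cells):
        row: dict = {
            "N_e": model.N_anc,
            "f": model.f,
            "s": sweep.s,
            "tau": sweep.tau,
            "n_replicates": study.n_replicates,
            "n_null": study.n_null_replicates,
        }
        try:
            if study.n_replicates == 0:
                rows.append(row)
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(ci,))
            )
            scans, reps = _replicate_scans(model, sweep, region, study, statistics, rng)
            mean_S = float(np.mean([h.S for h in reps])) if reps else 0.0
            if collect_sumstats:
                pis = [pi(h) for h in reps]
                ds = [tajimas_d(h) for h in reps if h.S > 0]
                row["median_pi"] = float(np.median(pis)) if pis else np.nan
                row["median_tajimas_d"] = float(np.median(ds)) if ds else np.nan
            for stat in statistics:
                thr = calibrate_threshold(
                    model, region, study, stat, rng, target_mean_segsites=mean_S
                )
                flags = [
                    classify_replicate(sc, thr, sweep.x_sel, study.tp_window_bp)
                    if sc is not None else (False, False)
                    for sc in scans[stat]
                ]
                n = max(len(flags), 1)
                row[f"{stat}_tp_pct"] = 100.0 * sum(tp for tp, _ in flags) / n
                row[f"{stat}_fp_pct"] = 100.0 * sum(fp for _, fp in flags) / n
                row[f"{stat}_cutoff"] = thr.cutoff
                if neutral_fpr_mode:
                    null_region = dataclasses.replace(region, mu=thr.mu_null)
                    hits = 0
                    for _ in range(study.n_replicates):
                        hn = simulate_neutral_sample(model, null_region, rng)
                        if hn.S < (4 if stat == "omega" else 1):
                            continue
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            sc = _do_scan(hn, stat, study, model, null_region, rng)
                        if thr.is_significant(sc.max_value):
                            hits += 1
                    row[f"{stat}_neutral_fpr_pct"] = (
                        100.0 * hits / study.n_replicates
                    )
        except Exception:  # pragma: no cover - defensive per-cell isolation
            logger.exception("power-study cell %d failed", ci)
            row["failed"] = True
        rows.append(row)
    return PowerTable(pd.DataFrame(rows))


def rejection_window_curve(
    scans: Sequence[ScanResult],
    threshold: ThresholdSet,
    x_sel: float,
    window_widths_bp: Sequence[float],
) -> pd.DataFrame:
    """Fraction of replicates with a significant point within windows of
    increasing width around the target (the rejection-rate-vs-window view)."""
    rows = []
    for w in window_widths_bp:
        hits = 0
        total = 0
        for sc in scans:
            if sc is None:
                continue
            total += 1
            tp, _ = classify_replicate(sc, threshold, x_sel, w)
            hits += tp
        rows.append((w, 100.0 * hits / total if total else np.nan))
    return pd.DataFrame(rows, columns=["window_bp", "fraction_rejecting_pct"])
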