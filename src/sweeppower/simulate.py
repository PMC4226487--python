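"""Coalescent simulation of bottlenecked samples with and without hard sweeps.

The generator is a backward-in-time ancestral-recombination-graph (ARG)
simulation under the piecewise-constant demography of
:class:`~sweeppower.models.DemographicModel`.  Outside the sweep phase it is
the standard coalescent with recombination (Hudson-style: lineages carry
intervals of ancestral material, recombination splits a lineage at a point
drawn uniformly on its material span, coalescence merges two lineages and
stops tracking any interval whose sample subtree is complete).  During the
sweep phase the population is structured by the beneficial allele: lineages
are labelled B (linked to the beneficial copy) or b (wild type), coalescence
is Wright-Fisher parent sampling within the background's current chromosome
count, and recombination between a lineage's material and the selected site
re-samples the background from the current allele frequency.  The
allele-frequency path itself is a Wright-Fisher trajectory in the
bottleneck-phase population, conditioned on fixation exactly at ``tau``.

Mutations follow the infinite-sites model: Poisson on branch length times
material length, positions uniform on the material, ancestral states known.
The output is the polymorphic-site 0/1 haplotype matrix.

The event loops are numba-compiled (:mod:`sweeppower._argcore`); this module
owns the state buffers, phase scheduling, and the public API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import _argcore as core
from .models import DemographicModel, RegionConfig, SweepModel

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]

__all__ = [
    "TrajectoryPath",
    "HaplotypeMatrix",
    "simulate_trajectory",
    "simulate_sweep_sample",
    "simulate_neutral_sample",
    "equilibrium_model",
    "replicate_seeds",
]


def _rng_of(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def replicate_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Per-replicate seed streams: child ``i`` is ``SeedSequence(master, spawn_key=(i,))``."""
    return [np.random.SeedSequence(master_seed, spawn_key=(i,)) for i in range(n)]


def equilibrium_model(N: float) -> DemographicModel:
    """A constant-size population expressed in the bottleneck parameterization."""
    return DemographicModel(N_anc=N, f=1.0, c_recovery=1.0, d=1e9, t_r=0.0)


# ---------------------------------------------------------------------------
# Beneficial-allele trajectory
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryPath:
    """Beneficial-allele frequency path, conditioned on fixation at ``tau``.

    ``times`` (2*N_anc-generation units before sampling) increase from the
    fixation time to the origin of the mutation; ``freqs[i]`` is the allele
    frequency at ``times[i]``, falling from 1 at fixation to ``1/(2*N_b)``
    at the generation the mutation arose.
    """

    times: np.ndarray
    freqs: np.ndarray
    origin_time: float
    fixation_time: float
    n_chromosomes: int  # 2*N_b, the bottleneck-phase chromosome count
    mode: str = "stochastic"

    def __post_init__(self) -> None:
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing (pastward)")

    @property
    def duration_generations(self) -> int:
        return len(self.freqs) - 1


def _wf_forward_path(two_nb: int, s: float, rng: np.random.Generator,
                     max_attempts: int = 100_000) -> np.ndarray:
    """Forward Wright-Fisher path from 1/(2N_b), rejected until fixation.

    Rejection sampling of the unconditioned walk yields exactly the
    fixation-conditioned path law.
    """
    for _ in range(max_attempts):
        x = 1.0 / two_nb
        path = [x]
        while 0.0 < x < 1.0:
            p = x * (1.0 + s) / (1.0 + s * x)
            x = rng.binomial(two_nb, p) / two_nb
            path.append(x)
        if x == 1.0:
            return np.asarray(path)
    raise RuntimeError(
        f"no fixation in {max_attempts} Wright-Fisher attempts "
        f"(2*N_b={two_nb}, s={s}); selection may be too weak to condition on"
    )


def _logistic_path(two_nb: int, s: float) -> np.ndarray:
    """Deterministic logistic sweep sampled at integer generations."""
    x0 = 1.0 / two_nb
    path = [x0]
    x = x0
    t = 0
    while x < 1.0 - x0:
        t += 1
        x = x0 / (x0 + (1.0 - x0) * math.exp(-s * t))
        path.append(x)
    path.append(1.0)
    return np.asarray(path)


def simulate_trajectory(
    model: DemographicModel,
    sweep: SweepModel,
    seed: SeedLike,
    mode: str = "auto",
) -> TrajectoryPath:
    """Sample the frequency path of the beneficial allele.

    The sweep runs in the bottleneck-phase population of ``N_b = f * N_anc``
    diploids.  ``mode`` is ``"stochastic"`` (conditioned Wright-Fisher, the
    default whenever drift matters), ``"deterministic"`` (logistic), or
    ``"auto"`` (deterministic only when ``2*N_b*s > 100``).
    """
    two_nb = int(round(2.0 * model.N_bottleneck))
    if two_nb < 2:
        raise ValueError(
            f"bottleneck population has fewer than one diploid "
            f"(2*N_b={2 * model.N_bottleneck:.3g}); increase f or N_anc"
        )
    if mode == "auto":
        mode = "deterministic" if two_nb * sweep.s > 100.0 else "stochastic"
    if mode == "deterministic":
        forward = _logistic_path(two_nb, sweep.s)
    elif mode == "stochastic":
        forward = _wf_forward_path(two_nb, sweep.s, _rng_of(seed))
    else:
        raise ValueError(f"unknown trajectory mode {mode!r}")

    dur = len(forward) - 1
    tau_gen = model.to_generations(sweep.tau)
    origin_time = model.from_generations(tau_gen + dur)
    if origin_time > model.d:
        raise ValueError(
            f"sweep origin at {origin_time:.4g} (2N gens) predates the divergence "
            f"d={model.d}: the sweep does not fit in the post-divergence epoch; "
            "raise s or shorten tau"
        )
    times = model.from_generations(tau_gen + np.arange(dur + 1, dtype=float))
    return TrajectoryPath(
        times=times,
        freqs=forward[::-1].copy(),  # pastward: 1 -> 1/(2*N_b)
        origin_time=origin_time,
        fixation_time=sweep.tau,
        n_chromosomes=two_nb,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Haplotype matrix
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeMatrix:
    """n x S matrix of 0/1 alleles with physical positions in base pairs."""

    alleles: np.ndarray
    positions: np.ndarray
    L: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("one position per column required")
        if np.any((self.positions < 0) | (self.positions >= self.L)):
            raise ValueError("positions must lie in [0, L)")
        if self.S and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def S(self) -> int:
        return self.alleles.shape[1]

    def derived_counts(self) -> np.ndarray:
        return self.alleles.sum(axis=0).astype(int)

    def validate(self) -> None:
        """Raise if any column is monomorphic (invariant of the generator)."""
        counts = self.derived_counts()
        if self.S and (counts.min() < 1 or counts.max() > self.n - 1):
            raise ValueError("monomorphic column in haplotype matrix")


# ---------------------------------------------------------------------------
# ARG state wrapper
# ---------------------------------------------------------------------------


class _CapacityError(RuntimeError):
    pass


class _ARG:
    """Owns the flat-array state consumed by the compiled kernels."""

    def __init__(self, region: RegionConfig, rng: np.random.Generator,
                 cap_seg: int = 1 << 20, cap_lin: int = 1 << 14,
                 cap_mut: int = 1 << 19):
        n = region.n
        if n > 128:
            raise ValueError("at most 128 chromosomes are supported")
        if cap_lin <= 2 * n:
            raise ValueError("lineage capacity too small")
        self.region = region
        self.rng = rng
        self.full0 = np.uint64((1 << min(n, 64)) - 1)
        self.full1 = np.uint64((1 << max(n - 64, 0)) - 1)

        self.seg_l = np.zeros(cap_seg)
        self.seg_r = np.zeros(cap_seg)
        self.seg_m0 = np.zeros(cap_seg, dtype=np.uint64)
        self.seg_m1 = np.zeros(cap_seg, dtype=np.uint64)
        self.seg_next = np.full(cap_seg, -1, dtype=np.int64)

        self.lin_head = np.full(cap_lin, -1, dtype=np.int64)
        self.lin_birth = np.zeros(cap_lin)
        self.lin_bg = np.zeros(cap_lin, dtype=np.uint8)
        self.lin_left = np.zeros(cap_lin)
        self.lin_right = np.zeros(cap_lin)
        self.lin_stamp = np.zeros(cap_lin, dtype=np.int64)
        self.active = np.zeros(cap_lin, dtype=np.int64)
        self.pos_in_active = np.zeros(cap_lin, dtype=np.int64)
        self.lin_free = np.zeros(cap_lin, dtype=np.int64)
        self.fen_n = cap_lin  # power of two
        self.fen = np.zeros(cap_lin + 1)

        self.mut_pos = np.zeros(cap_mut)
        self.mut_m0 = np.zeros(cap_mut, dtype=np.uint64)
        self.mut_m1 = np.zeros(cap_mut, dtype=np.uint64)

        self.sf = np.zeros(1)
        self.si = np.zeros(6, dtype=np.int64)

        # initial sample: one full-region segment per chromosome
        for i in range(n):
            self.seg_l[i] = 0.0
            self.seg_r[i] = region.L
            if i < 64:
                self.seg_m0[i] = np.uint64(1) << np.uint64(i)
            else:
                self.seg_m1[i] = np.uint64(1) << np.uint64(i - 64)
            self.seg_next[i] = -1
            self.lin_head[i] = i
            self.lin_left[i] = 0.0
            self.lin_right[i] = region.L
            self.lin_stamp[i] = i
            self.active[i] = i
            self.pos_in_active[i] = i
        self.seg_next[n:cap_seg - 1] = np.arange(n + 1, cap_seg)
        self.seg_next[cap_seg - 1] = -1
        self.lin_free[: cap_lin - n] = np.arange(n, cap_lin)
        self.si[core.SI_NACT] = n
        self.si[core.SI_SEGFREE] = n
        self.si[core.SI_LINFREE] = cap_lin - n
        self.si[core.SI_STAMP] = n
        core._fen_rebuild(self.fen, self.fen_n, self.active, n,
                          self.lin_left, self.lin_right)

    @property
    def n_lineages(self) -> int:
        return int(self.si[core.SI_NACT])

    def _state(self) -> tuple:
        return (self.seg_l, self.seg_r, self.seg_m0, self.seg_m1, self.seg_next,
                self.lin_head, self.lin_birth, self.lin_bg, self.lin_left,
                self.lin_right, self.lin_stamp, self.active, self.pos_in_active,
                self.lin_free, self.fen, self.fen_n,
                self.mut_pos, self.mut_m0, self.mut_m1, self.sf, self.si)

    def _check(self, status: int) -> None:
        if status == -1:
            raise _CapacityError(
                f"simulation pool exhausted (code {int(self.si[core.SI_ERR])})"
            )

    def run_neutral(self, t_end: float, N_dip: float) -> None:
        status = core.run_neutral(
            *self._state(), t_end, N_dip, self.region.r, self.region.mu,
            self.full0, self.full1, self.rng,
        )
        self._check(status)

    def run_sweep(self, traj: TrajectoryPath, x_sel: float) -> None:
        freqs_forward = np.ascontiguousarray(traj.freqs[::-1])
        status = core.run_sweep(
            *self._state(), freqs_forward, traj.n_chromosomes, x_sel,
            self.region.r, self.region.mu, self.full0, self.full1, self.rng,
        )
        self._check(status)

    def finish(self, metadata: Optional[dict] = None) -> HaplotypeMatrix:
        n = self.region.n
        L = self.region.L
        n_mut = int(self.si[core.SI_NMUT])
        pos = self.mut_pos[:n_mut].copy()
        m0 = self.mut_m0[:n_mut].copy()
        m1 = self.mut_m1[:n_mut].copy()
        order = np.argsort(pos, kind="stable")
        pos, m0, m1 = pos[order], m0[order], m1[order]
        # measure-zero position collisions: nudge upward minimally
        for i in range(1, n_mut):
            if pos[i] <= pos[i - 1]:
                pos[i] = np.nextafter(pos[i - 1], math.inf)
        keep = pos < L
        pos, m0, m1 = pos[keep], m0[keep], m1[keep]
        if n <= 64:
            shifts = np.arange(n, dtype=np.uint64)
            alleles = ((m0[:, None] >> shifts[None, :]) & np.uint64(1)).T
        else:
            s0 = np.arange(64, dtype=np.uint64)
            s1 = np.arange(n - 64, dtype=np.uint64)
            a0 = (m0[:, None] >> s0[None, :]) & np.uint64(1)
            a1 = (m1[:, None] >> s1[None, :]) & np.uint64(1)
            alleles = np.hstack([a0, a1]).T
        return HaplotypeMatrix(
            alleles=alleles.astype(np.uint8),
            positions=pos,
            L=L,
            metadata=metadata or {},
        )


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def _seed_repr(seed: SeedLike) -> str:
    if isinstance(seed, np.random.SeedSequence):
        return f"SeedSequence({seed.entropy}, spawn_key={seed.spawn_key})"
    return repr(seed)


_CAPACITY_STEPS = ((1 << 20, 1 << 14, 1 << 19), (1 << 23, 1 << 16, 1 << 21))


def _run_phases(region: RegionConfig, rng: np.random.Generator,
                phases: list[tuple]) -> _ARG:
    """Run the phase schedule, retrying once with larger pools if exhausted."""
    for cap_seg, cap_lin, cap_mut in _CAPACITY_STEPS:
        try:
            arg = _ARG(region, rng, cap_seg, cap_lin, cap_mut)
            for phase in phases:
                if phase[0] == "neutral":
                    arg.run_neutral(phase[1], phase[2])
                else:
                    if arg.n_lineages > 1:
                        arg.run_sweep(phase[1], phase[2])
            return arg
        except _CapacityError:
            continue
    raise RuntimeError("simulation pools exhausted even at maximum capacity")


def simulate_neutral_sample(
    model: DemographicModel,
    region: RegionConfig,
    seed: SeedLike,
) -> HaplotypeMatrix:
    """One neutral replicate under the piecewise-constant demography."""
    rng = _rng_of(seed)
    arg = _run_phases(region, rng, [
        ("neutral", model.to_generations(model.t_r), model.N_contemporary),
        ("neutral", model.to_generations(model.d), model.N_bottleneck),
        ("neutral", math.inf, model.N_anc),
    ])
    return arg.finish(
        {"kind": "neutral", "model": model, "region": region, "seed": _seed_repr(seed)}
    )


def simulate_sweep_sample(
    model: DemographicModel,
    sweep: SweepModel,
    region: RegionConfig,
    seed: SeedLike,
    trajectory: Optional[TrajectoryPath] = None,
    trajectory_mode: str = "auto",
) -> HaplotypeMatrix:
    """One replicate with a hard sweep completing at ``sweep.tau``."""
    sweep.validate_against(model, region)
    rng = _rng_of(seed)
    if trajectory is None:
        trajectory = simulate_trajectory(model, sweep, rng, mode=trajectory_mode)
    arg = _run_phases(region, rng, [
        ("neutral", model.to_generations(model.t_r), model.N_contemporary),
        ("neutral", model.to_generations(sweep.tau), model.N_bottleneck),
        ("sweep", trajectory, sweep.x_sel),
        ("neutral", model.to_generations(model.d), model.N_bottleneck),
        ("neutral", math.inf, model.N_anc),
    ])
    return arg.finish(
        {
            "kind": "sweep",
            "model": model,
            "sweep": sweep,
            "region": region,
            "seed": _seed_repr(seed),
            "trajectory_mode": trajectory.mode,
            "trajectory_generations": trajectory.duration_generations,
        }
    )
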