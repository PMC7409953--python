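"""Sub-ensemble sampling and Monte Carlo conformer-swap optimization.

A working ensemble is a size-N multiset of pool indices drawn with
replacement.  Each exchange attempt replaces one member with a uniformly
chosen pool conformer and is accepted greedily (strict score increase) or
by a Metropolis rule with inverse-temperature-like hyperparameter beta.

Scores are maintained incrementally: the state caches per-restraint running
sums of the back-calculated observables (sums of values, of cos/cos^2 terms
for J-couplings, of d^-6 for NOE/PRE), so the cost of one swap is
independent of the ensemble size N.  Floating-point drift is bounded by a
full recomputation every ``refresh_every`` accepted swaps, and
:meth:`EnsembleState.audit` checks the cache against a from-scratch pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .likelihood import TypeScore, _norm_const, score_type
from .restraints import (
    BackCalcTable,
    DataType,
    DISTANCE_TYPES,
    RestraintSet,
    UncertaintyConfig,
)

__all__ = [
    "OptimizerConfig",
    "EnsembleState",
    "OptimizationResult",
    "ReplicateSummary",
    "sample_subensemble",
    "propose_swap",
    "accept_greedy",
    "accept_metropolis",
    "run_optimization",
    "run_replicates",
]


@dataclass
class OptimizerConfig:
    """Settings of one optimization run.

    Defaults follow the reference protocol: ensembles of N = 100 drawn with
    replacement, 10,000 exchange attempts, greedy acceptance, and (for the
    Metropolis variant) beta = 0.1; replicate studies repeat this from 1000
    independent initial draws.
    """

    n_steps: int = 10_000
    mode: str = "greedy"                       # "greedy" | "metropolis"
    beta: float = 0.1
    ensemble_size: int = 100
    n_replicates: int = 1000
    active: tuple[DataType, ...] | None = None  # None -> every supplied type
    seed: int | None = None
    refresh_every: int = 1000                  # full recompute cadence (accepted swaps)

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.mode not in ("greedy", "metropolis"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "metropolis" and self.beta <= 0:
            raise ValueError("beta must be positive in metropolis mode")
        if self.active is not None:
            self.active = tuple(DataType(a) for a in self.active)


# ---------------------------------------------------------------------------
# Internal per-type scorers (hot loop)
# ---------------------------------------------------------------------------


class _OffsetScorer:
    """Offset-model total from running sums; V is values (or d^-6)."""

    __slots__ = ("V", "targets", "inv_2s2", "nc_total", "nc_vec", "is_distance",
                 "weight", "residual_only")

    def __init__(self, restraints: RestraintSet, table: BackCalcTable,
                 cfg: UncertaintyConfig, weight: float = 1.0, residual_only: bool = False):
        self.is_distance = restraints.datatype in DISTANCE_TYPES
        self.V = table.values ** -6.0 if self.is_distance else table.values
        self.targets = restraints.target
        sigma_q = np.array([cfg.sigma_q(restraints.datatype, rid) for rid in restraints.ids])
        s2 = sigma_q ** 2 + restraints.sigma_exp ** 2
        self.inv_2s2 = 1.0 / (2.0 * s2)
        nc_vec = np.where(sigma_q > 0,
                          _norm_const(np.where(sigma_q > 0, sigma_q, 1.0)), 0.0) \
            + _norm_const(restraints.sigma_exp)
        self.nc_vec = nc_vec
        self.nc_total = float(nc_vec.sum())
        self.weight = weight
        self.residual_only = residual_only

    def init_sums(self, members: np.ndarray) -> np.ndarray:
        return self.V[members].sum(axis=0)

    def delta_rows(self, in_idx: int, out_idx: int) -> np.ndarray:
        return self.V[in_idx] - self.V[out_idx]

    def total(self, sums: np.ndarray, n: int) -> float:
        avg = sums / n
        if self.is_distance:
            avg = avg ** (-1.0 / 6.0)
        delta = self.targets - avg
        penalty = float(np.dot(delta * delta, self.inv_2s2))
        if self.residual_only:
            return self.nc_total - self.weight * penalty
        return self.weight * (self.nc_total - penalty)


class _KarplusScorer:
    """Karplus-model total from running sums of cos and cos^2 terms."""

    __slots__ = ("V1", "V2", "targets", "mu_a", "mu_b", "mu_c",
                 "sa2", "sb2", "sc2_plus_sex2", "nc_total")

    def __init__(self, restraints: RestraintSet, table: BackCalcTable, cfg: UncertaintyConfig):
        self.V1 = table.values
        self.V2 = table.cos2
        self.targets = restraints.target
        p = cfg.karplus
        self.mu_a, self.mu_b, self.mu_c = p.mu_a, p.mu_b, p.mu_c
        self.sa2, self.sb2 = p.sigma_a ** 2, p.sigma_b ** 2
        self.sc2_plus_sex2 = p.sigma_c ** 2 + cfg.jc_sigma_exp ** 2
        nc = (_norm_const(p.sigma_a) + _norm_const(p.sigma_b)
              + _norm_const(p.sigma_c) + _norm_const(cfg.jc_sigma_exp))
        self.nc_total = float(nc * len(restraints))

    def init_sums(self, members: np.ndarray) -> np.ndarray:
        return np.stack([self.V1[members].sum(axis=0), self.V2[members].sum(axis=0)])

    def delta_rows(self, in_idx: int, out_idx: int) -> np.ndarray:
        return np.stack([self.V1[in_idx] - self.V1[out_idx],
                         self.V2[in_idx] - self.V2[out_idx]])

    def total(self, sums: np.ndarray, n: int) -> float:
        a1 = sums[0] / n
        a2 = sums[1] / n
        eps0 = self.targets - (self.mu_a * a2 + self.mu_b * a1 + self.mu_c)
        denom = self.sa2 * a2 * a2 + self.sb2 * a1 * a1 + self.sc2_plus_sex2
        return self.nc_total - float(np.sum(eps0 * eps0 / (2.0 * denom)))


def _build_scorers(tables: Mapping[DataType, BackCalcTable],
                   restraints: Mapping[DataType, RestraintSet],
                   cfg: UncertaintyConfig,
                   active: Sequence[DataType]) -> dict:
    from .likelihood import saxs_shannon_weight

    scorers: dict = {}
    for dt in active:
        dt = DataType(dt)
        rset, table = restraints[dt], tables[dt]
        if table.restraint_ids != list(rset.ids):
            table = table.align_to(rset)
        if dt is DataType.JC:
            scorers[dt] = _KarplusScorer(rset, table, cfg)
        elif dt is DataType.SAXS:
            w = saxs_shannon_weight(rset, cfg)
            scorers[dt] = _OffsetScorer(rset, table, cfg, weight=w,
                                        residual_only=cfg.saxs.weight_residual_only)
        else:
            scorers[dt] = _OffsetScorer(rset, table, cfg)
    return scorers


# ---------------------------------------------------------------------------
# Ensemble state
# ---------------------------------------------------------------------------


class EnsembleState:
    """A size-N multiset of pool indices with cached running sums and scores."""

    def __init__(self, members, tables: Mapping[DataType, BackCalcTable],
                 restraints: Mapping[DataType, RestraintSet],
                 cfg: UncertaintyConfig | None = None,
                 active: Sequence[DataType] | None = None):
        self.member_indices = np.asarray(members, dtype=int).copy()
        if self.member_indices.ndim != 1 or self.member_indices.size == 0:
            raise ValueError("members must be a non-empty 1-D index multiset")
        self.cfg = cfg or UncertaintyConfig()
        self.tables = {DataType(k): v for k, v in tables.items()}
        self.restraints = {DataType(k): v for k, v in restraints.items()}
        sizes = {t.n_conformers for t in self.tables.values()}
        if len(sizes) != 1:
            raise ValueError("back-calculation tables disagree on pool size")
        self.pool_size = sizes.pop()
        if np.any((self.member_indices < 0) | (self.member_indices >= self.pool_size)):
            raise ValueError("member index out of pool range")
        if active is None:
            active = tuple(self.tables)
        self.active = tuple(DataType(a) for a in active)
        missing = [a for a in self.active if a not in self.tables or a not in self.restraints]
        if missing:
            raise ValueError(f"active types without tables/restraints: {missing}")
        self._scorers = _build_scorers(self.tables, self.restraints, self.cfg, self.active)
        self.recompute()

    # -- cache maintenance -------------------------------------------------

    @property
    def n(self) -> int:
        return self.member_indices.size

    def recompute(self) -> None:
        """Rebuild running sums and scores from scratch."""
        self._sums = {dt: sc.init_sums(self.member_indices) for dt, sc in self._scorers.items()}
        self._rescore()

    def _rescore(self) -> None:
        self.type_totals = {dt: sc.total(self._sums[dt], self.n)
                            for dt, sc in self._scorers.items()}
        self.objective = float(sum(self.type_totals.values()))

    def audit(self) -> float:
        """Max |cached sum - from-scratch sum| over all active restraints."""
        worst = 0.0
        for dt, sc in self._scorers.items():
            fresh = sc.init_sums(self.member_indices)
            dev = np.max(np.abs(self._sums[dt] - fresh)) if fresh.size else 0.0
            worst = max(worst, float(dev))
        return worst

    # -- swaps ---------------------------------------------------------------

    def proposal_objective(self, out_position: int, in_pool_index: int) -> float:
        """Objective after the hypothetical swap, without modifying the state."""
        out_idx = int(self.member_indices[out_position])
        total = 0.0
        for dt, sc in self._scorers.items():
            total += sc.total(self._sums[dt] + sc.delta_rows(in_pool_index, out_idx), self.n)
        return total

    def apply_swap(self, out_position: int, in_pool_index: int) -> None:
        """Replace the member at ``out_position`` and update sums incrementally."""
        if not (0 <= out_position < self.n):
            raise IndexError("out_position out of range")
        if not (0 <= in_pool_index < self.pool_size):
            raise IndexError("in_pool_index out of range")
        out_idx = int(self.member_indices[out_position])
        for dt, sc in self._scorers.items():
            self._sums[dt] += sc.delta_rows(in_pool_index, out_idx)
        self.member_indices[out_position] = in_pool_index
        self._rescore()

    def copy(self) -> "EnsembleState":
        clone = object.__new__(EnsembleState)
        clone.__dict__.update(self.__dict__)
        clone.member_indices = self.member_indices.copy()
        clone._sums = {dt: s.copy() for dt, s in self._sums.items()}
        clone.type_totals = dict(self.type_totals)
        return clone

    # -- full reporting ------------------------------------------------------

    def full_scores(self, types: Sequence[DataType] | None = None) -> dict[DataType, TypeScore]:
        """From-scratch per-type TypeScores (all supplied types by default)."""
        types = tuple(DataType(t) for t in (types or self.tables))
        return {dt: score_type(self.restraints[dt], self.tables[dt],
                               self.member_indices, self.cfg) for dt in types}


# ---------------------------------------------------------------------------
# Sampling and acceptance rules
# ---------------------------------------------------------------------------


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_subensemble(pool_size: int, n: int, rng=None) -> np.ndarray:
    """N uniform draws with replacement from the pool; reproducible given seed."""
    if pool_size < 1:
        raise ValueError("pool must contain at least one conformer")
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    return _as_rng(rng).integers(0, pool_size, size=n)


def propose_swap(state: EnsembleState, rng) -> tuple[int, int]:
    """Uniform member position to evict and uniform pool conformer to insert."""
    rng = _as_rng(rng)
    return int(rng.integers(0, state.n)), int(rng.integers(0, state.pool_size))


def accept_greedy(score_old: float, score_new: float) -> bool:
    """Accept only strict improvements (ties rejected)."""
    return score_new > score_old


def accept_metropolis(score_old: float, score_new: float, beta: float, rng) -> bool:
    """Accept with probability min(1, exp(beta * (score_new - score_old)))."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    delta = score_new - score_old
    if delta > 0:
        return True
    return _as_rng(rng).random() < math.exp(beta * delta)


# ---------------------------------------------------------------------------
# Optimization driver
# ---------------------------------------------------------------------------


@dataclass
class OptimizationResult:
    state: EnsembleState
    initial_members: np.ndarray
    initial_objective: float
    trace: np.ndarray          # objective after each exchange attempt
    accepted: np.ndarray       # boolean mask over exchange attempts
    n_accepted: int

    @property
    def final_objective(self) -> float:
        return self.state.objective


def run_optimization(tables: Mapping[DataType, BackCalcTable],
                     restraints: Mapping[DataType, RestraintSet],
                     cfg: OptimizerConfig,
                     uncertainty: UncertaintyConfig | None = None,
                     rng=None,
                     initial_members: np.ndarray | None = None) -> OptimizationResult:
    """One MCMC conformer-swap run; a pure function of (inputs, rng seed)."""
    rng = _as_rng(rng if rng is not None else cfg.seed)
    active = cfg.active if cfg.active is not None else tuple(tables)
    probe = next(iter(tables.values()))
    pool_size = probe.n_conformers
    if initial_members is None:
        initial_members = sample_subensemble(pool_size, cfg.ensemble_size, rng)
    state = EnsembleState(initial_members, tables, restraints, uncertainty, active)
    initial_objective = state.objective

    n_steps = cfg.n_steps
    trace = np.empty(n_steps)
    accepted_mask = np.zeros(n_steps, dtype=bool)
    n_accepted = 0
    if n_steps:
        # pre-drawn randomness keeps the loop light and the run reproducible
        out_positions = rng.integers(0, state.n, size=n_steps)
        in_indices = rng.integers(0, state.pool_size, size=n_steps)
        uniforms = rng.random(n_steps) if cfg.mode == "metropolis" else None
        beta = cfg.beta
        greedy = cfg.mode == "greedy"
        for step in range(n_steps):
            out_pos = int(out_positions[step])
            in_idx = int(in_indices[step])
            new_obj = state.proposal_objective(out_pos, in_idx)
            delta = new_obj - state.objective
            if greedy:
                accept = delta > 0
            else:
                accept = delta > 0 or uniforms[step] < math.exp(beta * delta)
            if accept:
                state.apply_swap(out_pos, in_idx)
                n_accepted += 1
                accepted_mask[step] = True
            trace[step] = state.objective
            if accept and cfg.refresh_every and n_accepted % cfg.refresh_every == 0:
                state.recompute()  # bound floating-point drift in the running sums
    return OptimizationResult(state, np.asarray(initial_members).copy(),
                              initial_objective, trace, accepted_mask, n_accepted)


@dataclass
class ReplicateSummary:
    results: list[OptimizationResult]
    objective_mean: float
    objective_sd: float
    initial_objective_mean: float

    def member_matrix(self) -> np.ndarray:
        return np.stack([r.state.member_indices for r in self.results])


def run_replicates(tables: Mapping[DataType, BackCalcTable],
                   restraints: Mapping[DataType, RestraintSet],
                   cfg: OptimizerConfig,
                   uncertainty: UncertaintyConfig | None = None) -> ReplicateSummary:
    """Independently seeded optimization replicates with aggregate statistics.

    Each replicate draws a fresh initial sub-ensemble from the pool; streams
    are spawned from the master seed so the whole study is reproducible and
    replicates are independent.
    """
    if cfg.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates)
    results = [run_optimization(tables, restraints, cfg, uncertainty,
                                rng=np.random.default_rng(s)) for s in seeds]
    finals = np.array([r.final_objective for r in results])
    initials = np.array([r.initial_objective for r in results])
    sd = float(finals.std(ddof=1)) if len(results) > 1 else 0.0
    return ReplicateSummary(results, float(finals.mean()), sd, float(initials.mean()))
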