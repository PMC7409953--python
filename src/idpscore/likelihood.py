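"""Per-data-type maximum log-likelihood with closed-form nuisance optimization.

Every data type is scored as a product of Gaussians over nuisance parameters
and an experimental residual, maximized in closed form:

*Offset model* (chemical shifts, NOE/PRE distances, RDCs, R_h, smFRET <E>,
SAXS intensity points).  For a restraint with target ``d``, ensemble-averaged
back-calculation ``m``, back-calculation prior N(q; 0, sigma_q) and
experimental residual N(d - q - m; 0, sigma_ex), the optimum is

    q* = sigma_q^2 (d - m) / (sigma_q^2 + sigma_ex^2),   eps* = d - m - q*

and the maximal logp collapses to ``nc - (d - m)^2 / (2 (sigma_q^2 +
sigma_ex^2))`` where ``nc`` is the sum of the Gaussian normalization
constants (which are kept, not dropped).

*Karplus model* (J-couplings).  J = A<cos^2> + B<cos> + C with independent
Gaussian priors on (A, B, C) and a Gaussian experimental residual; the
optimum is linear in the prior deviations (see :func:`optimize_karplus`).

NOE/PRE ensemble averages use the r^-6 convention; SAXS per-point sums are
scaled by the Shannon-channel factor min(1, N_s / N_q).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .restraints import (
    BackCalcTable,
    DataType,
    DISTANCE_TYPES,
    KarplusPriors,
    RestraintSet,
    UncertaintyConfig,
)

__all__ = [
    "NuisanceSolution",
    "TypeScore",
    "optimize_offset",
    "optimize_karplus",
    "offset_solution",
    "karplus_solution",
    "ensemble_average_distance",
    "ensemble_averages",
    "score_type",
    "score_saxs",
    "shannon_channels",
    "total_score",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _norm_const(sigma) -> np.ndarray:
    """-log(sigma * sqrt(2 pi)), the peak log-density of N(.; mu, sigma)."""
    return -(np.log(sigma) + _LOG_SQRT_2PI)


@dataclass(frozen=True)
class NuisanceSolution:
    """Optimized nuisance parameters for one restraint.

    ``offset`` is q* for the offset model; ``abc`` is (A*, B*, C*) for the
    Karplus model; exactly one of the two is set.  ``eps_star`` is the
    experimental residual at the optimum and ``logp`` the maximal
    log-likelihood including normalization constants.
    """

    datatype: DataType
    restraint_id: str
    logp: float
    eps_star: float
    offset: float | None = None
    abc: tuple[float, float, float] | None = None


@dataclass
class TypeScore:
    """Summed log-likelihood of one data type over its restraints.

    ``logp``, ``eps_star`` and the nuisance arrays are per-restraint;
    ``total`` is their sum times the Shannon weight (1 except for SAXS).
    ``calc`` holds the ensemble-averaged back-calculated values used both in
    the residuals and in RMSD reporting.
    """

    datatype: DataType
    restraint_ids: list[str]
    total: float
    logp: np.ndarray
    eps_star: np.ndarray
    calc: np.ndarray
    offsets: np.ndarray | None = None          # q* (offset model)
    abc: np.ndarray | None = None              # (M, 3) Karplus optima
    shannon_weight: float = 1.0

    def solutions(self) -> list[NuisanceSolution]:
        out = []
        for j, rid in enumerate(self.restraint_ids):
            out.append(NuisanceSolution(
                self.datatype, rid, float(self.logp[j]), float(self.eps_star[j]),
                offset=None if self.offsets is None else float(self.offsets[j]),
                abc=None if self.abc is None else tuple(float(v) for v in self.abc[j]),
            ))
        return out


# ---------------------------------------------------------------------------
# Closed-form nuisance optima
# ---------------------------------------------------------------------------


def offset_solution(target, ens_avg, sigma_q, sigma_ex):
    """Vectorized offset-model optimum.

    Returns ``(logp, q_star, eps_star)`` arrays.  ``sigma_q`` may be 0, in
    which case q is pinned at 0 and the (degenerate) prior contributes
    nothing to logp.
    """
    target = np.asarray(target, dtype=float)
    ens_avg = np.asarray(ens_avg, dtype=float)
    sigma_q = np.asarray(sigma_q, dtype=float)
    sigma_ex = np.asarray(sigma_ex, dtype=float)
    if np.any(sigma_ex <= 0):
        raise ValueError("sigma_ex must be positive")
    if np.any(sigma_q < 0):
        raise ValueError("sigma_q must be non-negative")
    delta = target - ens_avg
    s2 = sigma_q ** 2 + sigma_ex ** 2
    q_star = np.where(sigma_q > 0, sigma_q ** 2 * delta / s2, 0.0)
    eps_star = delta - q_star
    prior_nc = np.where(sigma_q > 0, _norm_const(np.where(sigma_q > 0, sigma_q, 1.0)), 0.0)
    nc = prior_nc + _norm_const(sigma_ex)
    logp = nc - delta ** 2 / (2.0 * s2)
    return logp, q_star, eps_star


def optimize_offset(target: float, ens_avg: float, sigma_q: float, sigma_ex: float,
                    datatype: DataType = DataType.CS, restraint_id: str = "") -> NuisanceSolution:
    """Closed-form maximum of log N(q; 0, sigma_q) + log N(d - q - m; 0, sigma_ex)."""
    logp, q_star, eps_star = offset_solution(target, ens_avg, sigma_q, sigma_ex)
    return NuisanceSolution(DataType(datatype), restraint_id, float(logp),
                            float(eps_star), offset=float(q_star))


def karplus_solution(a1, a2, target, priors: KarplusPriors, sigma_ex: float):
    """Vectorized Karplus-model optimum.

    ``a1`` = <cos(phi - phi0)>, ``a2`` = <cos^2(phi - phi0)> ensemble
    averages.  Returns ``(logp, abc, eps_star)`` where ``abc`` is (M, 3).
    """
    a1 = np.atleast_1d(np.asarray(a1, dtype=float))
    a2 = np.atleast_1d(np.asarray(a2, dtype=float))
    target = np.atleast_1d(np.asarray(target, dtype=float))
    if sigma_ex <= 0:
        raise ValueError("sigma_ex must be positive")
    tol = 1e-9
    if np.any(np.abs(a1) > 1 + tol) or np.any(a2 < -tol) or np.any(a2 > 1 + tol):
        raise ValueError("ensemble-averaged cos terms out of bounds")
    if np.any(a2 < a1 ** 2 - 1e-9):
        raise ValueError("a2 < a1^2 violates Jensen's inequality for ensemble averages")

    p = priors
    eps0 = target - (p.mu_a * a2 + p.mu_b * a1 + p.mu_c)
    s = (p.sigma_a * a2) ** 2 + (p.sigma_b * a1) ** 2 + p.sigma_c ** 2
    denom = sigma_ex ** 2 + s
    k = eps0 / denom
    a_star = p.mu_a + p.sigma_a ** 2 * a2 * k
    b_star = p.mu_b + p.sigma_b ** 2 * a1 * k
    c_star = p.mu_c + p.sigma_c ** 2 * k
    eps_star = sigma_ex ** 2 * k
    nc = (_norm_const(p.sigma_a) + _norm_const(p.sigma_b)
          + _norm_const(p.sigma_c) + _norm_const(sigma_ex))
    # quadratic penalty at the optimum collapses to eps0^2 / (2 (sigma_ex^2 + S))
    logp = nc - eps0 ** 2 / (2.0 * denom)
    abc = np.stack([a_star, b_star, c_star], axis=-1)
    return logp, abc, eps_star


def optimize_karplus(a1: float, a2: float, target_j: float, priors: KarplusPriors,
                     sigma_ex: float, restraint_id: str = "") -> NuisanceSolution:
    """Closed-form maximum of the four-Gaussian J-coupling objective."""
    logp, abc, eps_star = karplus_solution(a1, a2, target_j, priors, sigma_ex)
    return NuisanceSolution(DataType.JC, restraint_id, float(logp[0]),
                            float(eps_star[0]), abc=tuple(float(v) for v in abc[0]))


def ensemble_average_distance(distances: Sequence[float] | np.ndarray) -> float:
    """r^-6 ensemble-averaged distance: (mean d_i^-6)^(-1/6).

    Lies between min and max of the inputs, weighted toward the minimum.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("cannot average an empty distance list")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    return float(np.mean(d ** -6.0) ** (-1.0 / 6.0))


# ---------------------------------------------------------------------------
# Per-type scoring
# ---------------------------------------------------------------------------


def _members_of(state) -> np.ndarray:
    members = getattr(state, "member_indices", state)
    return np.asarray(members, dtype=int)


def ensemble_averages(table: BackCalcTable, members) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Ensemble-averaged observables of a sub-ensemble (with multiplicity).

    Arithmetic mean for CS/RDC/R_h/FRET-efficiency/SAXS intensities, the
    r^-6 mean for NOE/PRE distances; for JC returns the (a1, a2) pair of
    averaged cos and cos^2 terms.
    """
    members = _members_of(members)
    if members.size == 0:
        raise ValueError("empty ensemble")
    if np.any((members < 0) | (members >= table.n_conformers)):
        raise ValueError("member index out of range")
    if table.datatype is DataType.JC:
        return table.values[members].mean(axis=0), table.cos2[members].mean(axis=0)
    if table.datatype in DISTANCE_TYPES:
        return np.mean(table.values[members] ** -6.0, axis=0) ** (-1.0 / 6.0)
    return table.values[members].mean(axis=0)


def _sigma_q_vector(cfg: UncertaintyConfig, restraints: RestraintSet) -> np.ndarray:
    return np.array([cfg.sigma_q(restraints.datatype, rid) for rid in restraints.ids])


def score_type(restraints: RestraintSet, table: BackCalcTable, state,
               cfg: UncertaintyConfig | None = None) -> TypeScore:
    """Maximum log-likelihood of one data type for a sub-ensemble.

    ``state`` may be an EnsembleState or a plain sequence of pool indices
    (with multiplicity).  SAXS sets are dispatched to :func:`score_saxs`.
    """
    cfg = cfg or UncertaintyConfig()
    if table.datatype is not restraints.datatype:
        raise ValueError(f"table type {table.datatype.value} does not match "
                         f"restraint type {restraints.datatype.value}")
    if table.restraint_ids != list(restraints.ids):
        raise ValueError("table is not aligned to the restraint set (call align_to first)")
    if len(restraints) == 0:
        return TypeScore(restraints.datatype, [], 0.0, np.empty(0), np.empty(0), np.empty(0))
    if restraints.datatype is DataType.SAXS:
        return score_saxs(restraints, table, state, cfg)
    members = _members_of(state)

    if restraints.datatype is DataType.JC:
        a1, a2 = ensemble_averages(table, members)
        logp, abc, eps_star = karplus_solution(a1, a2, restraints.target,
                                               cfg.karplus, cfg.jc_sigma_exp)
        calc = cfg.karplus.back_calc(a1, a2)
        return TypeScore(restraints.datatype, list(restraints.ids), float(logp.sum()),
                         logp, eps_star, calc, abc=abc)

    avg = ensemble_averages(table, members)
    sigma_q = _sigma_q_vector(cfg, restraints)
    logp, q_star, eps_star = offset_solution(restraints.target, avg, sigma_q, restraints.sigma_exp)
    return TypeScore(restraints.datatype, list(restraints.ids), float(logp.sum()),
                     logp, eps_star, avg, offsets=q_star)


def shannon_channels(d_max: float, q_min: float, q_max: float) -> float:
    """Number of Shannon channels N_s = D_max (q_max - q_min) / pi."""
    if q_max <= q_min:
        raise ValueError("q_max must exceed q_min")
    if q_min < 0 or d_max < 0:
        raise ValueError("d_max and q_min must be non-negative")
    return d_max * (q_max - q_min) / math.pi


def saxs_shannon_weight(restraints: RestraintSet, cfg: UncertaintyConfig) -> float:
    """min(1, N_s / N_q) for a SAXS restraint set under the configured geometry."""
    n_q = len(restraints)
    if n_q == 0:
        raise ValueError("empty SAXS restraint set")
    if cfg.saxs.ns_override is not None:
        n_s = float(cfg.saxs.ns_override)
    else:
        qv = restraints.q
        q_min = cfg.saxs.q_min if cfg.saxs.q_min is not None else float(qv.min())
        q_max = cfg.saxs.q_max if cfg.saxs.q_max is not None else float(qv.max())
        n_s = shannon_channels(cfg.saxs.d_max, q_min, q_max)
    if n_s <= 0:
        raise ValueError("number of Shannon channels must be positive")
    return min(1.0, n_s / n_q)


def score_saxs(restraints: RestraintSet, table: BackCalcTable, state,
               cfg: UncertaintyConfig | None = None) -> TypeScore:
    """Per-point offset scoring of a SAXS curve with Shannon-channel weighting.

    Each intensity point is scored as an independent offset-model restraint;
    the per-point sum is multiplied by min(1, N_s / N_q) to correct for
    oversampling of the continuous scattering curve.  With
    ``cfg.saxs.weight_residual_only`` the factor scales only the quadratic
    residual part, leaving the normalization constants whole.
    """
    cfg = cfg or UncertaintyConfig()
    members = _members_of(state)
    weight = saxs_shannon_weight(restraints, cfg)
    avg = table.values[members].mean(axis=0)
    logp, q_star, eps_star = offset_solution(restraints.target, avg,
                                             cfg.saxs_sigma_q, restraints.sigma_exp)
    if cfg.saxs.weight_residual_only:
        nc = _norm_const(cfg.saxs_sigma_q) + _norm_const(restraints.sigma_exp)
        total = float(np.sum(nc + weight * (logp - nc)))
    else:
        total = weight * float(logp.sum())
    return TypeScore(DataType.SAXS, list(restraints.ids), total, logp, eps_star,
                     avg, offsets=q_star, shannon_weight=weight)


def total_score(type_scores: Iterable[TypeScore],
                active: Iterable[DataType] | None = None) -> float:
    """Sum of per-type totals over the active data types.

    ``active=None`` sums everything; inactive types are simply excluded
    (they can still be reported alongside).
    """
    scores = list(type_scores)
    if active is None:
        return float(sum(ts.total for ts in scores))
    active_set = {DataType(a) for a in active}
    return float(sum(ts.total for ts in scores if ts.datatype in active_set))
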