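"""Synthetic conformer pools and pseudo-experimental restraints.

The generator emulates the study design used for the drkN SH3 unfolded
state: a pool of conformers drawn from labelled sub-populations with
distinct observable distributions (a compact, helix-like population and an
extended, coil-like one), back-calculation tables for all eight data types,
and pseudo-experimental targets formed as ensemble averages under chosen
mixture weights plus Gaussian noise at the per-type experimental sigmas.

Observables are kept physically coherent with the back-calculation chain:
phi angles are drawn (wrapped normal) and J-coupling terms derived from
them, distances are log-normal (positive), FRET efficiencies are induced
from distances through the linker-scaled Forster curve, and SAXS curves are
Guinier-like functions of a per-conformer radius of gyration - never drawn
directly.  Restraint counts default to the drkN set sizes (267 CS, 47 JC,
93 NOE, 68 PRE, 28 RDC, 37 SAXS points, one R_h, one <E>).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import fret_distance_scaled, fret_efficiency
from .restraints import (
    BackCalcTable,
    DataType,
    DISTANCE_TYPES,
    RestraintSet,
    UncertaintyConfig,
)

__all__ = ["Population", "SyntheticTruth", "SyntheticPool",
           "default_truth", "make_pool", "make_experimental"]

#: Typical random-coil chemical shifts (ppm) per atom name used for CS ids.
_CS_BASELINE = {"CA": 55.0, "CB": 38.0, "C": 176.0, "H": 8.2, "HA": 4.3}
_CS_ATOM_CYCLE = ("CA", "CB", "C", "H", "HA")

#: drkN SH3 unfolded-state restraint counts.
DEFAULT_COUNTS = {
    DataType.CS: 267, DataType.JC: 47, DataType.NOE: 93, DataType.PRE: 68,
    DataType.RDC: 28, DataType.SAXS: 37, DataType.RH: 1, DataType.FRET: 1,
}


@dataclass(frozen=True)
class Population:
    """Ground-truth observable distributions of one conformer sub-population.

    Per-restraint population means are themselves drawn once per truth
    (``*_center_spread`` controls how much they vary across restraints);
    ``*_spread`` is the conformer-to-conformer scatter within the
    population.  ``rg_mean``/``rg_spread`` (A) drive R_h, the SAXS curve and
    the FRET inter-label distance.
    """

    label: str
    weight: float
    phi_center: float            # deg
    phi_center_spread: float     # deg, across restraints
    phi_spread: float            # deg, within population
    log_dist_center: float       # log A
    log_dist_center_spread: float
    log_dist_spread: float
    cs_offset: float             # ppm on the carbon scale (x0.1 for H)
    cs_spread: float
    rdc_offset: float            # Hz
    rdc_spread: float
    rg_mean: float               # A
    rg_spread: float


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a synthetic study deterministically."""

    n_pool: int = 1000
    populations: tuple[Population, ...] = ()
    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    seed: int = 0
    phi0: float = 60.0
    saxs_q_range: tuple[float, float] = (0.01, 0.30)
    fret_n_residues: int = 55    # sequence separation of the two dye sites
    rh_spread: float = 1.0       # A, scatter of R_h around R_g per conformer
    rdc_baseline_spread: float = 2.5  # Hz, across restraints (shared)
    fret_dist_factor: float = 2.2     # Calpha-Calpha distance ~ factor * R_g
    fret_dist_logspread: float = 0.15

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("at least one population required")
        total = sum(p.weight for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population weights sum to {total}, not 1")
        self.counts = {DataType(k): int(v) for k, v in self.counts.items()}

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.populations]


def default_truth(n_pool: int = 1000, seed: int = 0) -> SyntheticTruth:
    """The default two-population study: compact/helix-like vs extended/coil.

    Population contrasts are sized so that local (phi-derived J-couplings)
    and long-range (log-normal NOE/PRE distances) observables both separate
    the populations, while within-population scatter keeps individual
    conformers heterogeneous.
    """
    compact = Population(
        label="compact", weight=0.5,
        phi_center=-65.0, phi_center_spread=25.0, phi_spread=20.0,
        log_dist_center=math.log(9.0), log_dist_center_spread=0.25, log_dist_spread=0.25,
        cs_offset=0.4, cs_spread=0.6, rdc_offset=1.0, rdc_spread=1.5,
        rg_mean=16.0, rg_spread=1.2,
    )
    extended = Population(
        label="extended", weight=0.5,
        phi_center=-120.0, phi_center_spread=25.0, phi_spread=25.0,
        log_dist_center=math.log(18.0), log_dist_center_spread=0.25, log_dist_spread=0.30,
        cs_offset=-0.4, cs_spread=0.6, rdc_offset=-1.0, rdc_spread=1.5,
        rg_mean=24.0, rg_spread=1.8,
    )
    return SyntheticTruth(n_pool=n_pool, populations=(compact, extended), seed=seed)


@dataclass
class SyntheticPool:
    """Labelled synthetic pool: observable tables plus per-conformer R_g."""

    conformer_ids: list
    labels: list[str]
    rg: np.ndarray
    tables: dict

    @property
    def n_conformers(self) -> int:
        return len(self.conformer_ids)

    def label_fractions(self) -> dict[str, float]:
        n = self.n_conformers
        return {lab: self.labels.count(lab) / n for lab in sorted(set(self.labels))}


def _wrap_angle(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180]."""
    out = (phi + 180.0) % 360.0 - 180.0
    return np.where(out == -180.0, 180.0, out)


def make_pool(truth: SyntheticTruth, rng=None) -> SyntheticPool:
    """Draw a labelled conformer pool and its back-calculation tables."""
    rng = np.random.default_rng(truth.seed if rng is None else rng)
    n = truth.n_pool
    pops = truth.populations
    pop_idx = rng.choice(len(pops), size=n, p=[p.weight for p in pops])
    labels = [pops[k].label for k in pop_idx]
    conformer_ids = list(range(n))
    counts = truth.counts
    tables: dict = {}

    # chemical shifts: shared per-restraint baseline + population offset
    m = counts.get(DataType.CS, 0)
    if m:
        atom_names = [_CS_ATOM_CYCLE[j % len(_CS_ATOM_CYCLE)] for j in range(m)]
        ids = [f"{j + 1}.{atom_names[j]}" for j in range(m)]
        scale = np.array([0.1 if a.startswith("H") else 1.0 for a in atom_names])
        baseline = np.array([_CS_BASELINE[a] for a in atom_names]) + rng.normal(0, 1, m) * scale
        pop_means = np.stack([baseline + p.cs_offset * scale for p in pops])
        spread = np.stack([p.cs_spread * scale for p in pops])
        values = pop_means[pop_idx] + rng.normal(0, 1, (n, m)) * spread[pop_idx]
        tables[DataType.CS] = BackCalcTable(DataType.CS, conformer_ids, ids, values)

    # J-couplings: wrapped-normal phi per restraint, Karplus terms derived
    m = counts.get(DataType.JC, 0)
    if m:
        ids = [f"{j + 2}.3JHNHA" for j in range(m)]
        centers = np.stack([rng.normal(p.phi_center, p.phi_center_spread, m) for p in pops])
        spreads = np.array([p.phi_spread for p in pops])
        phi = centers[pop_idx] + rng.normal(0, 1, (n, m)) * spreads[pop_idx, None]
        tables[DataType.JC] = BackCalcTable.from_phi(
            DataType.JC, conformer_ids, ids, _wrap_angle(phi), phi0=truth.phi0)

    # NOE / PRE: log-normal distances with population-specific medians
    for dt, prefix in ((DataType.NOE, "noe"), (DataType.PRE, "pre")):
        m = counts.get(dt, 0)
        if not m:
            continue
        ids = [f"{prefix}.{j + 1}" for j in range(m)]
        log_med = np.stack([rng.normal(p.log_dist_center, p.log_dist_center_spread, m)
                            for p in pops])
        log_spread = np.array([p.log_dist_spread for p in pops])
        d = np.exp(log_med[pop_idx] + rng.normal(0, 1, (n, m)) * log_spread[pop_idx, None])
        tables[dt] = BackCalcTable(dt, conformer_ids, ids, d)

    # RDCs: shared baseline + population offset
    m = counts.get(DataType.RDC, 0)
    if m:
        ids = [f"{j + 2}.NH" for j in range(m)]
        baseline = rng.normal(0, truth.rdc_baseline_spread, m)
        pop_means = np.stack([baseline + p.rdc_offset for p in pops])
        spreads = np.array([p.rdc_spread for p in pops])
        values = pop_means[pop_idx] + rng.normal(0, 1, (n, m)) * spreads[pop_idx, None]
        tables[DataType.RDC] = BackCalcTable(DataType.RDC, conformer_ids, ids, values)

    # per-conformer R_g drives the global observables
    rg = np.empty(n)
    for k, p in enumerate(pops):
        mask = pop_idx == k
        rg[mask] = rng.normal(p.rg_mean, p.rg_spread, int(mask.sum()))
    rg = np.clip(rg, 5.0, None)

    if counts.get(DataType.RH, 0):
        values = (rg + rng.normal(0, truth.rh_spread, n))[:, None]
        tables[DataType.RH] = BackCalcTable(DataType.RH, conformer_ids, ["Rh"], values)

    if counts.get(DataType.FRET, 0):
        cfg = UncertaintyConfig()
        r_caca = truth.fret_dist_factor * rg * np.exp(
            rng.normal(0, truth.fret_dist_logspread, n))
        r_da = np.array([fret_distance_scaled(v, truth.fret_n_residues,
                                              cfg.fret.n_linker, cfg.fret.upsilon)
                         for v in r_caca])
        eff = fret_efficiency(r_da, cfg.fret.r0)
        tables[DataType.FRET] = BackCalcTable(DataType.FRET, conformer_ids, ["E.1"],
                                              np.asarray(eff)[:, None])

    m = counts.get(DataType.SAXS, 0)
    if m:
        q = np.linspace(truth.saxs_q_range[0], truth.saxs_q_range[1], m)
        ids = [format(v, ".8g") for v in q]
        intensity = np.exp(-np.outer(rg, q) ** 2 / 3.0)  # Guinier-like curves
        tables[DataType.SAXS] = BackCalcTable(DataType.SAXS, conformer_ids, ids, intensity)

    return SyntheticPool(conformer_ids, labels, rg, tables)


def _group_means(values: np.ndarray, labels: list[str], order: list[str]) -> np.ndarray:
    lab = np.asarray(labels)
    return np.stack([values[lab == name].mean(axis=0) for name in order])


def make_experimental(truth: SyntheticTruth, pool: SyntheticPool,
                      target_weights, rng=None, noise: bool = True,
                      cfg: UncertaintyConfig | None = None) -> dict:
    """Pseudo-experimental restraint sets for a ground-truth mixture.

    Each target is the ensemble average of the pool's population means under
    ``target_weights`` (r^-6 convention for NOE/PRE, efficiency averaging
    for FRET, prior-mean Karplus back-calculation for J-couplings), plus
    Gaussian noise at the per-type experimental sigma when ``noise`` is on.
    With ``noise=False`` and weights equal to the pool's empirical label
    fractions, scoring the full pool gives exactly zero residuals.
    """
    cfg = cfg or UncertaintyConfig()
    rng = np.random.default_rng(truth.seed + 1 if rng is None else rng)
    order = truth.labels
    if isinstance(target_weights, dict):
        w = np.array([target_weights[name] for name in order], dtype=float)
    else:
        w = np.asarray(target_weights, dtype=float)
    if w.shape != (len(order),):
        raise ValueError("target_weights must cover every population")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("target_weights must sum to 1")

    out: dict = {}
    for dt, table in pool.tables.items():
        ids = list(table.restraint_ids)
        if dt is DataType.JC:
            a1 = w @ _group_means(table.values, pool.labels, order)
            a2 = w @ _group_means(table.cos2, pool.labels, order)
            target = cfg.karplus.back_calc(a1, a2)
            sigma = np.full(len(ids), cfg.jc_sigma_exp)
        elif dt in DISTANCE_TYPES:
            inv6 = w @ _group_means(table.values ** -6.0, pool.labels, order)
            target = inv6 ** (-1.0 / 6.0)
            default = (cfg.noe_default_sigma_exp if dt is DataType.NOE
                       else cfg.pre_default_sigma_exp)
            sigma = np.full(len(ids), default)
            if dt is DataType.NOE:
                # mirror the two experimental distance classes (sigma 4 or 5 A)
                sigma = np.where(np.arange(len(ids)) % 2 == 0, 4.0, 5.0)
        elif dt is DataType.SAXS:
            target = w @ _group_means(table.values, pool.labels, order)
            sigma = cfg.saxs_sigma_exp(np.array([float(i) for i in ids]))
        else:
            target = w @ _group_means(table.values, pool.labels, order)
            sigma = np.array([cfg.default_sigma_exp(dt, rid) for rid in ids])
        if noise:
            target = target + rng.normal(0, 1, len(ids)) * sigma
        out[dt] = RestraintSet(dt, ids, target, sigma, provenance={
            "synthetic": True,
            "target_weights": {name: float(v) for name, v in zip(order, w)},
            "noise": bool(noise),
        })
    return out
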