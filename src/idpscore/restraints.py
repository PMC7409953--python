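"""Restraint records, back-calculation tables, and uncertainty configuration.

Experimental restraints are kept per data type as a :class:`RestraintSet`
(identifier, target value, experimental uncertainty, optional range bounds),
and per-conformer predicted observables as a :class:`BackCalcTable` aligned
column-for-column to a restraint set.  All nuisance-prior constants live in
:class:`UncertaintyConfig`, whose defaults are the values used for the drkN
SH3 unfolded-state study (Vuister–Bax Karplus priors, per-type back-calculation
and experimental sigmas).

File formats are deliberately plain: tab-separated tables with a header line
and ``#`` comments, plus the conventional 3-column ``.dat`` for experimental
SAXS curves.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DataType",
    "DISTANCE_TYPES",
    "KarplusPriors",
    "FretParams",
    "SaxsParams",
    "UncertaintyConfig",
    "RestraintSet",
    "BackCalcTable",
    "RestraintParseError",
    "AlignmentError",
    "load_restraints",
    "write_restraints",
    "load_saxs_dat",
    "load_backcalc",
    "write_backcalc",
]


class DataType(str, enum.Enum):
    """Experimental data types the scorer understands."""

    CS = "CS"        # chemical shifts (ppm)
    JC = "JC"        # three-bond scalar J-couplings (Hz)
    NOE = "NOE"      # homonuclear NOE distance restraints (A)
    PRE = "PRE"      # paramagnetic relaxation enhancement distances (A)
    RDC = "RDC"      # residual dipolar couplings (Hz)
    RH = "RH"        # hydrodynamic radius (A)
    FRET = "FRET"    # mean smFRET transfer efficiency (dimensionless)
    SAXS = "SAXS"    # scattering intensity I(Q) (relative units)


#: Types whose observable is a distance and whose ensemble average uses the
#: r^-6 convention.
DISTANCE_TYPES = frozenset({DataType.NOE, DataType.PRE})

#: Range -> sigma_exp divisor per distance data type (range/2 for NOE,
#: range/4 for PRE).
RANGE_SIGMA_DIVISOR = {DataType.NOE: 2.0, DataType.PRE: 4.0}


class RestraintParseError(ValueError):
    """Malformed restraint file; carries the offending line number."""


class AlignmentError(ValueError):
    """Back-calculation table does not cover the paired restraint set."""


@dataclass(frozen=True)
class KarplusPriors:
    """Gaussian priors on the Karplus coefficients, J = A<cos^2> + B<cos> + C.

    Defaults are the Vuister–Bax parameters for 3J(HN-Ha) with phi0 = 60 deg.
    """

    mu_a: float = 6.51
    sigma_a: float = 0.14
    mu_b: float = -1.76
    sigma_b: float = 0.03
    mu_c: float = 1.60
    sigma_c: float = 0.08
    phi0: float = 60.0  # degrees

    def back_calc(self, a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
        """Prior-mean J from ensemble-averaged cos (a1) and cos^2 (a2) terms."""
        return self.mu_a * np.asarray(a2) + self.mu_b * np.asarray(a1) + self.mu_c


@dataclass(frozen=True)
class FretParams:
    """Forster radius and linker scaling used to back-calculate <E>.

    ``r_da = r_ca_ca * ((N + n_linker) / N) ** upsilon`` with ``upsilon`` the
    Flory scaling exponent.
    """

    r0: float = 54.0          # A
    n_linker: int = 9         # residues added by the two dye linkers
    upsilon: float = 0.55     # Flory exponent for a disordered chain


@dataclass(frozen=True)
class SaxsParams:
    """SAXS information-content settings.

    ``n_s = d_max * (q_max - q_min) / pi`` Shannon channels; ``q_min``/``q_max``
    default to the experimental Q-grid bounds when left as None.  When
    ``weight_residual_only`` is set, the Shannon factor scales only the
    chi-square residual part of the per-point log-likelihood instead of the
    whole sum.
    """

    d_max: float = 60.0                 # A
    q_min: float | None = None          # A^-1
    q_max: float | None = None          # A^-1
    ns_override: float | None = None
    weight_residual_only: bool = False


_ID_TOKEN_RE = re.compile(r"[._\-:\s]+")


def _atom_token(restraint_id: str) -> str:
    parts = [p for p in _ID_TOKEN_RE.split(str(restraint_id)) if p]
    return parts[-1] if parts else ""


@dataclass
class UncertaintyConfig:
    """All sigma constants and nuisance priors used by the likelihood.

    Defaults are the drkN SH3 unfolded-state study values.  Chemical-shift
    sigmas are banded by atom class (hydrogen vs carbon-like); the class is
    read from the trailing atom-name token of the restraint id
    (e.g. ``"12.CA"`` -> carbon band, ``"7.HA"`` -> hydrogen band).
    """

    # chemical shifts (ppm)
    cs_sigma_exp_hydrogen: float = 0.03
    cs_sigma_exp_carbon: float = 0.3
    cs_sigma_q_hydrogen: float = 0.4    # midpoint of the 0.3-0.5 ppm band
    cs_sigma_q_carbon: float = 1.3      # midpoint of the 1.2-1.4 ppm band
    # J-couplings (Hz)
    jc_sigma_exp: float = 0.5
    karplus: KarplusPriors = field(default_factory=KarplusPriors)
    # NOE / PRE distance restraints (A); the tiny back-calculation sigma is
    # the sentinel used when the back-calculation is a plain coordinate
    # distance and contributes a large constant per restraint.
    noe_sigma_q: float = 1e-4
    pre_sigma_q: float = 1e-4
    noe_default_sigma_exp: float = 4.5
    pre_default_sigma_exp: float = 4.0
    # RDCs (Hz)
    rdc_sigma_q: float = 0.9
    rdc_sigma_exp: float = 1.0
    # hydrodynamic radius (A)
    rh_sigma_q: float = 0.8
    rh_sigma_exp: float = 0.30
    # smFRET efficiency (dimensionless; see docs - the source values are
    # printed with length units but are used on the efficiency scale)
    fret_sigma_q: float = 0.007
    fret_sigma_exp: float = 0.02
    fret: FretParams = field(default_factory=FretParams)
    # SAXS intensities (relative units)
    saxs_sigma_q: float = 0.006
    saxs_sigma_exp_low_q: float = 0.002     # near Q = 0
    saxs_sigma_exp_high_q: float = 0.0008   # toward q_max
    saxs: SaxsParams = field(default_factory=SaxsParams)

    # -- sigma lookups ----------------------------------------------------

    def sigma_q(self, datatype: DataType, restraint_id: str | None = None) -> float:
        """Back-calculation sigma for one restraint of the given type."""
        datatype = DataType(datatype)
        if datatype is DataType.CS:
            if restraint_id is not None and _atom_token(restraint_id).upper().startswith("H"):
                return self.cs_sigma_q_hydrogen
            return self.cs_sigma_q_carbon
        return {
            DataType.NOE: self.noe_sigma_q,
            DataType.PRE: self.pre_sigma_q,
            DataType.RDC: self.rdc_sigma_q,
            DataType.RH: self.rh_sigma_q,
            DataType.FRET: self.fret_sigma_q,
            DataType.SAXS: self.saxs_sigma_q,
            DataType.JC: 0.0,  # JC uncertainty lives in the Karplus priors
        }[datatype]

    def default_sigma_exp(self, datatype: DataType, restraint_id: str | None = None) -> float:
        """Experimental sigma used when a restraint row does not provide one."""
        datatype = DataType(datatype)
        if datatype is DataType.CS:
            if restraint_id is not None and _atom_token(restraint_id).upper().startswith("H"):
                return self.cs_sigma_exp_hydrogen
            return self.cs_sigma_exp_carbon
        return {
            DataType.JC: self.jc_sigma_exp,
            DataType.NOE: self.noe_default_sigma_exp,
            DataType.PRE: self.pre_default_sigma_exp,
            DataType.RDC: self.rdc_sigma_exp,
            DataType.RH: self.rh_sigma_exp,
            DataType.FRET: self.fret_sigma_exp,
            DataType.SAXS: self.saxs_sigma_exp_low_q,
        }[datatype]

    def saxs_sigma_exp(self, q: np.ndarray) -> np.ndarray:
        """Per-point experimental sigma, interpolated linearly in Q.

        Larger uncertainties sit near Q = 0 and decrease toward q_max.
        """
        q = np.asarray(q, dtype=float)
        if q.size == 0:
            return np.empty(0)
        lo, hi = float(q.min()), float(q.max())
        if hi == lo:
            return np.full(q.shape, self.saxs_sigma_exp_low_q)
        t = (q - lo) / (hi - lo)
        return self.saxs_sigma_exp_low_q + t * (self.saxs_sigma_exp_high_q - self.saxs_sigma_exp_low_q)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "UncertaintyConfig":
        data = dict(data)
        kwargs = {}
        if "karplus" in data:
            kwargs["karplus"] = KarplusPriors(**data.pop("karplus"))
        if "fret" in data:
            kwargs["fret"] = FretParams(**data.pop("fret"))
        if "saxs" in data:
            kwargs["saxs"] = SaxsParams(**data.pop("saxs"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown uncertainty-config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "UncertaintyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# Restraint sets
# ---------------------------------------------------------------------------


@dataclass
class RestraintSet:
    """The experimental data D for one data type.

    ``target`` and ``sigma_exp`` are parallel to ``ids``; ``range_lo`` /
    ``range_hi`` are present only when the restraints were given as ranges
    (distance restraint classes), in which case the target is the mid-range
    value by convention.
    """

    datatype: DataType
    ids: list[str]
    target: np.ndarray
    sigma_exp: np.ndarray
    range_lo: np.ndarray | None = None
    range_hi: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.datatype = DataType(self.datatype)
        self.ids = [str(i) for i in self.ids]
        self.target = np.asarray(self.target, dtype=float)
        self.sigma_exp = np.asarray(self.sigma_exp, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def q(self) -> np.ndarray:
        """Q grid (A^-1) for SAXS sets, parsed from the restraint ids."""
        if self.datatype is not DataType.SAXS:
            raise ValueError("Q grid is defined only for SAXS restraint sets")
        return np.array([float(i) for i in self.ids])

    def validate(self) -> None:
        n = len(self.ids)
        if self.target.shape != (n,) or self.sigma_exp.shape != (n,):
            raise ValueError("target/sigma_exp must be parallel to ids")
        if len(set(self.ids)) != n:
            raise ValueError(f"duplicate restraint ids in {self.datatype.value} set")
        if n and not np.all(self.sigma_exp > 0):
            bad = [self.ids[i] for i in np.flatnonzero(~(self.sigma_exp > 0))]
            raise ValueError(f"non-positive sigma_exp for {self.datatype.value} restraints {bad}")
        if self.range_lo is not None or self.range_hi is not None:
            if self.range_lo is None or self.range_hi is None:
                raise ValueError("range_lo and range_hi must be given together")
            self.range_lo = np.asarray(self.range_lo, dtype=float)
            self.range_hi = np.asarray(self.range_hi, dtype=float)
            if not np.all(self.range_lo < self.range_hi):
                raise ValueError("range_lo must be < range_hi")
            mid = 0.5 * (self.range_lo + self.range_hi)
            if n and not np.allclose(self.target, mid, rtol=0, atol=1e-9):
                raise ValueError("range-bound restraints must use the mid-range target")
        if self.datatype is DataType.SAXS and n:
            qv = self.q
            if not np.all(np.diff(qv) > 0):
                raise ValueError("SAXS restraints must be sorted by strictly increasing Q")


def _convert_range(datatype: DataType, lo: float, hi: float) -> tuple[float, float]:
    """Range bounds -> (mid-range target, sigma_exp) per the distance-class rule."""
    if hi <= lo:
        raise ValueError(f"invalid range [{lo}, {hi}]")
    divisor = RANGE_SIGMA_DIVISOR[datatype]
    return 0.5 * (lo + hi), (hi - lo) / divisor


def load_restraints(
    path: str | Path,
    datatype: DataType,
    config: UncertaintyConfig | None = None,
) -> RestraintSet:
    """Read a tab-separated restraint table.

    Required header column: ``id``.  Either ``target`` or the range pair
    ``lo``/``hi`` must be present.  ``sigma_exp`` is optional: it is filled
    from the range rule (NOE range/2, PRE range/4) when ranges are given,
    else from the :class:`UncertaintyConfig` defaults.
    """
    datatype = DataType(datatype)
    config = config or UncertaintyConfig()
    path = Path(path)

    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields_ = raw.rstrip("\n").split("\t")
        if header is None:
            header = [h.strip() for h in fields_]
            continue
        rows.append((lineno, fields_))

    if header is None:
        # completely empty file -> empty set
        return RestraintSet(datatype, [], np.empty(0), np.empty(0))
    if "id" not in header:
        raise RestraintParseError(f"{path}: header must contain an 'id' column")
    col = {name: i for i, name in enumerate(header)}
    has_range = "lo" in col and "hi" in col

    def _get(fields_: list[str], name: str) -> str | None:
        i = col.get(name)
        if i is None or i >= len(fields_):
            return None
        v = fields_[i].strip()
        return v if v not in ("", "NA", "nan") else None

    ids: list[str] = []
    targets: list[float] = []
    sigmas: list[float] = []
    los: list[float] = []
    his: list[float] = []
    for lineno, fields_ in rows:
        try:
            rid = _get(fields_, "id")
            if rid is None:
                raise ValueError("missing id")
            lo = _get(fields_, "lo")
            hi = _get(fields_, "hi")
            tgt = _get(fields_, "target")
            sig = _get(fields_, "sigma_exp")
            if lo is not None and hi is not None:
                lo_f, hi_f = float(lo), float(hi)
                mid, range_sigma = _convert_range(datatype, lo_f, hi_f)
                target = float(tgt) if tgt is not None else mid
                sigma = float(sig) if sig is not None else range_sigma
                los.append(lo_f)
                his.append(hi_f)
            else:
                if tgt is None:
                    raise ValueError("missing target (and no lo/hi range)")
                target = float(tgt)
                sigma = float(sig) if sig is not None else config.default_sigma_exp(datatype, rid)
            if not math.isfinite(target) or not math.isfinite(sigma):
                raise ValueError("non-finite value")
            if sigma <= 0:
                raise ValueError(f"non-positive sigma_exp {sigma}")
        except ValueError as exc:
            raise RestraintParseError(f"{path}:{lineno}: {exc}") from exc
        ids.append(rid)
        targets.append(target)
        sigmas.append(sigma)

    range_lo = np.array(los) if los and len(los) == len(ids) else None
    range_hi = np.array(his) if range_lo is not None else None
    provenance = {"source": str(path)}
    if range_lo is not None:
        provenance["range_rule"] = f"target = mid-range; sigma_exp = range/{RANGE_SIGMA_DIVISOR[datatype]:g}"
    return RestraintSet(datatype, ids, np.array(targets), np.array(sigmas),
                        range_lo, range_hi, provenance)


def write_restraints(rset: RestraintSet, path: str | Path) -> None:
    """Write a restraint set in the TSV format :func:`load_restraints` reads."""
    lines = [f"# {rset.datatype.value} restraints"]
    if rset.range_lo is not None:
        lines.append("id\ttarget\tsigma_exp\tlo\thi")
        for i, rid in enumerate(rset.ids):
            lines.append("\t".join([rid] + [repr(float(v)) for v in
                         (rset.target[i], rset.sigma_exp[i], rset.range_lo[i], rset.range_hi[i])]))
    else:
        lines.append("id\ttarget\tsigma_exp")
        for i, rid in enumerate(rset.ids):
            lines.append("\t".join([rid, repr(float(rset.target[i])), repr(float(rset.sigma_exp[i]))]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_saxs_dat(path: str | Path, config: UncertaintyConfig | None = None) -> RestraintSet:
    """Read an experimental SAXS curve from a standard 3-column .dat file.

    Columns: Q (A^-1), I(Q), sigma(I).  A missing third column falls back to
    the configured low/high-Q sigma interpolation.
    """
    config = config or UncertaintyConfig()
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise RestraintParseError(f"{path}: expected at least 2 columns (Q, I)")
    order = np.argsort(data[:, 0])
    data = data[order]
    q, intensity = data[:, 0], data[:, 1]
    sigma = data[:, 2] if data.shape[1] >= 3 else config.saxs_sigma_exp(q)
    ids = [format(v, ".8g") for v in q]
    return RestraintSet(DataType.SAXS, ids, intensity, sigma,
                        provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# Back-calculation tables
# ---------------------------------------------------------------------------


@dataclass
class BackCalcTable:
    """Per-conformer predicted observables aligned to a restraint set.

    ``values`` is conformer x restraint.  Semantics per type:

    * CS/RDC/RH/SAXS - the predicted observable itself;
    * NOE/PRE - the per-conformer distance in A (must be > 0);
    * FRET - the per-conformer transfer efficiency;
    * JC - ``values`` holds cos(phi - phi0) and ``cos2`` holds its square
      (the single-conformer identity cos2 = values**2 holds cell-wise);
      ``phi`` (degrees) is retained when the table came from angles.
    """

    datatype: DataType
    conformer_ids: list
    restraint_ids: list[str]
    values: np.ndarray
    cos2: np.ndarray | None = None
    phi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.datatype = DataType(self.datatype)
        self.restraint_ids = [str(i) for i in self.restraint_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.conformer_ids), len(self.restraint_ids)):
            raise ValueError("values must be (n_conformers, n_restraints)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.datatype.value} back-calculation table contains non-finite cells")
        if self.datatype in DISTANCE_TYPES and self.values.size and not np.all(self.values > 0):
            raise ValueError("NOE/PRE distances must be > 0")
        if self.datatype is DataType.JC:
            if self.cos2 is None:
                self.cos2 = self.values ** 2
            self.cos2 = np.asarray(self.cos2, dtype=float)
            if self.cos2.shape != self.values.shape:
                raise ValueError("cos2 must match the cos term matrix shape")
            if self.values.size:
                if np.max(np.abs(self.values)) > 1 + 1e-12:
                    raise ValueError("JC cos terms must lie in [-1, 1]")
                if not np.allclose(self.cos2, self.values ** 2, atol=1e-10):
                    raise ValueError("JC cos2 term must equal cos term squared per conformer")
        elif self.cos2 is not None:
            raise ValueError("cos2 is meaningful only for JC tables")

    @property
    def n_conformers(self) -> int:
        return len(self.conformer_ids)

    @classmethod
    def from_phi(cls, datatype: DataType, conformer_ids: Sequence, restraint_ids: Sequence[str],
                 phi_deg: np.ndarray, phi0: float = 60.0) -> "BackCalcTable":
        """Build a JC table from per-conformer phi dihedrals (degrees)."""
        phi_deg = np.asarray(phi_deg, dtype=float)
        cos_term = np.cos(np.deg2rad(phi_deg - phi0))
        return cls(DataType(datatype), list(conformer_ids), list(restraint_ids),
                   cos_term, cos_term ** 2, phi=phi_deg)

    def align_to(self, restraints: RestraintSet) -> "BackCalcTable":
        """Return a copy whose columns follow the restraint set order."""
        if self.datatype is not restraints.datatype:
            raise AlignmentError(
                f"table type {self.datatype.value} != restraint type {restraints.datatype.value}")
        pos = {rid: i for i, rid in enumerate(self.restraint_ids)}
        missing = [rid for rid in restraints.ids if rid not in pos]
        if missing:
            raise AlignmentError(
                f"{self.datatype.value} table is missing columns for restraints: {missing}")
        idx = np.array([pos[rid] for rid in restraints.ids], dtype=int)
        if list(restraints.ids) == self.restraint_ids:
            return self
        return BackCalcTable(
            self.datatype, self.conformer_ids, list(restraints.ids),
            self.values[:, idx],
            None if self.cos2 is None else self.cos2[:, idx],
            None if self.phi is None else self.phi[:, idx],
        )


def load_backcalc(
    path: str | Path,
    datatype: DataType,
    restraints: RestraintSet,
    phi0: float = 60.0,
) -> BackCalcTable:
    """Read a conformer x restraint TSV and align it to ``restraints``.

    First column is the conformer id; remaining columns are named by
    restraint id.  Columns may appear in any order; columns not present in
    the restraint set are rejected.  JC tables store phi angles in degrees,
    from which the Karplus cos/cos^2 terms are derived.
    """
    datatype = DataType(datatype)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str},
                     float_precision="round_trip")
    if df.shape[1] < 1 or df.columns[0] != "conformer":
        raise RestraintParseError(f"{path}: first column must be 'conformer'")
    conformer_ids = df.iloc[:, 0].tolist()
    cols = list(df.columns[1:])
    unknown = [c for c in cols if c not in set(restraints.ids)]
    if unknown:
        raise AlignmentError(
            f"{path}: columns not present in the {datatype.value} restraint set: {unknown}")
    matrix = df.iloc[:, 1:].to_numpy(dtype=float)
    if matrix.size and not np.all(np.isfinite(matrix)):
        raise ValueError(f"{path}: table contains NaN/inf cells")
    if datatype is DataType.JC:
        table = BackCalcTable.from_phi(datatype, conformer_ids, cols, matrix, phi0=phi0)
    else:
        table = BackCalcTable(datatype, conformer_ids, cols, matrix)
    return table.align_to(restraints)


def write_backcalc(table: BackCalcTable, path: str | Path) -> None:
    """Write a back-calculation table in the TSV format :func:`load_backcalc` reads.

    JC tables are written as phi angles (degrees) so that the cos^2 = cos^2
    identity survives the round trip exactly; a JC table without stored
    angles cannot be serialized.
    """
    if table.datatype is DataType.JC:
        if table.phi is None:
            raise ValueError("JC table has no stored phi angles to serialize")
        matrix = table.phi
    else:
        matrix = table.values
    header = "conformer\t" + "\t".join(table.restraint_ids)
    lines = [header]
    for cid, row in zip(table.conformer_ids, matrix):
        lines.append(str(cid) + "\t" + "\t".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
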