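"""RMSD metrics, replicate aggregation, composition and R_g summaries.

Scores are log-likelihoods of mixed sign and magnitude across data types,
so reports also carry a plain RMSD between ensemble-averaged back-calculated
values and the experimental targets (an absolute deviation when a type has a
single restraint, e.g. <E> and R_h), presented as replicate mean (sd).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .likelihood import score_type
from .optimizer import EnsembleState, ReplicateSummary
from .restraints import BackCalcTable, DataType, RestraintSet, UncertaintyConfig

__all__ = [
    "ScoreReport",
    "rmsd",
    "pool_composition",
    "aggregate",
    "replicate_report",
    "rg_histogram",
]

RG_BIN_WIDTH = 0.5  # A; fixed so histograms are comparable across runs


def rmsd(calc: Sequence[float], exp: Sequence[float]) -> float:
    """sqrt(sum((calc - exp)^2) / M); equals |calc - exp| for M = 1."""
    calc = np.asarray(calc, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if calc.shape != exp.shape or calc.ndim != 1 or calc.size == 0:
        raise ValueError("calc and exp must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((calc - exp) ** 2)))


def aggregate(values: Sequence[float]) -> tuple[float, float]:
    """Replicate mean and sample (N-1) standard deviation; sd = 0 for N = 1."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def pool_composition(states: Iterable, labels: Sequence[str | None]) -> dict[str, float]:
    """Multiset-counted label fractions averaged over ensemble states.

    ``states`` may be EnsembleStates or plain member-index arrays; ``labels``
    maps every pool index to its parent-population label.
    """
    labels = list(labels)
    per_state: list[dict[str, float]] = []
    keys: set[str] = set()
    for state in states:
        members = np.asarray(getattr(state, "member_indices", state), dtype=int)
        counts: dict[str, int] = {}
        for idx in members:
            lab = labels[idx]
            if lab is None:
                raise ValueError(f"pool conformer {idx} has no population label")
            counts[lab] = counts.get(lab, 0) + 1
        total = members.size
        per_state.append({k: v / total for k, v in counts.items()})
        keys.update(counts)
    if not per_state:
        raise ValueError("no states given")
    return {k: float(np.mean([fr.get(k, 0.0) for fr in per_state])) for k in sorted(keys)}


def rg_histogram(rg_values: Sequence[float]) -> dict:
    """R_g histogram at the fixed 0.5-A binning, plus mean and sd."""
    rg = np.asarray(list(rg_values), dtype=float)
    if rg.size == 0:
        raise ValueError("no R_g values")
    lo = np.floor(rg.min() / RG_BIN_WIDTH) * RG_BIN_WIDTH
    hi = np.ceil(rg.max() / RG_BIN_WIDTH) * RG_BIN_WIDTH + RG_BIN_WIDTH
    edges = np.arange(lo, hi + 0.5 * RG_BIN_WIDTH, RG_BIN_WIDTH)
    counts, edges = np.histogram(rg, bins=edges)
    return {
        "mean": float(rg.mean()),
        "sd": float(rg.std(ddof=1)) if rg.size > 1 else 0.0,
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
    }


@dataclass
class ScoreReport:
    """Replicate-aggregated report: per-type score and RMSD mean (sd).

    ``per_type`` maps data-type name to ``{"score_mean", "score_sd",
    "rmsd_mean", "rmsd_sd", "n_restraints"}``; composition fractions and the
    R_g summary are optional extras.  Serializes losslessly to JSON.
    """

    per_type: dict[str, dict[str, float]]
    objective_mean: float
    objective_sd: float
    n_replicates: int
    composition: dict[str, float] | None = None
    rg: dict | None = None
    propensity_tables: dict | None = None   # hook for external per-residue tables

    def __post_init__(self) -> None:
        if self.composition is not None and self.composition:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition fractions sum to {total}, not 1")
        for name, row in self.per_type.items():
            if row["rmsd_mean"] < 0:
                raise ValueError(f"negative RMSD for {name}")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScoreReport":
        if isinstance(source, Path) or (isinstance(source, str)
                                        and not source.lstrip().startswith("{")):
            text = Path(source).read_text()
        else:
            text = str(source)
        return cls(**json.loads(text))


def replicate_report(summary: ReplicateSummary,
                     tables: Mapping[DataType, BackCalcTable],
                     restraints: Mapping[DataType, RestraintSet],
                     cfg: UncertaintyConfig | None = None,
                     labels: Sequence[str | None] | None = None,
                     rg_per_conformer: Sequence[float] | None = None) -> ScoreReport:
    """Score | RMSD table over optimization replicates.

    Every supplied data type is scored from scratch for every replicate's
    final state (whether or not it was active in the objective), mirroring
    the cross-validation reading of single/dual optimization studies.
    """
    cfg = cfg or UncertaintyConfig()
    types = [DataType(t) for t in tables]
    scores: dict[DataType, list[float]] = {t: [] for t in types}
    rmsds: dict[DataType, list[float]] = {t: [] for t in types}
    for result in summary.results:
        members = result.state.member_indices
        for dt in types:
            ts = score_type(restraints[dt], tables[dt], members, cfg)
            scores[dt].append(ts.total)
            rmsds[dt].append(rmsd(ts.calc, restraints[dt].target))
    per_type = {}
    for dt in types:
        s_mean, s_sd = aggregate(scores[dt])
        r_mean, r_sd = aggregate(rmsds[dt])
        per_type[dt.value] = {
            "score_mean": s_mean, "score_sd": s_sd,
            "rmsd_mean": r_mean, "rmsd_sd": r_sd,
            "n_restraints": len(restraints[dt]),
        }
    composition = None
    if labels is not None:
        composition = pool_composition([r.state for r in summary.results], labels)
    rg = None
    if rg_per_conformer is not None:
        rg_arr = np.asarray(list(rg_per_conformer), dtype=float)
        member_rg = np.concatenate([rg_arr[r.state.member_indices] for r in summary.results])
        rg = rg_histogram(member_rg)
    return ScoreReport(per_type, summary.objective_mean, summary.objective_sd,
                       len(summary.results), composition, rg)
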