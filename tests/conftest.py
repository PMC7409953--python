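"""Shared fixtures: scaled-down synthetic studies and a tiny multi-model PDB."""

from __future__ import annotations

import numpy as np
import pytest

import idpscore as ip
from idpscore import DataType


@pytest.fixture(scope="session")
def truth_small():
    """Two-population truth at reduced pool/restraint counts for fast tests."""
    truth = ip.default_truth(n_pool=200, seed=3)
    truth.counts = {
        DataType.CS: 20, DataType.JC: 12, DataType.NOE: 15, DataType.PRE: 15,
        DataType.RDC: 8, DataType.SAXS: 10, DataType.RH: 1, DataType.FRET: 1,
    }
    return truth


@pytest.fixture(scope="session")
def pool_small(truth_small):
    return ip.make_pool(truth_small)


@pytest.fixture(scope="session")
def restraints_small(truth_small, pool_small):
    """Noisy pseudo-experimental data for a 0.75/0.25 compact/extended mixture."""
    return ip.make_experimental(truth_small, pool_small,
                                {"compact": 0.75, "extended": 0.25},
                                rng=np.random.default_rng(17), noise=True)


def _pdb_atom_line(serial, name, resname, resseq, xyz, element):
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {padded:<4s} {resname:<3s} A{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2s}")


#: Atom template of one tripeptide residue: (name, element, local offset).
_RESIDUE_ATOMS = [
    ("N", "N", (0.0, 0.0, 0.0)),
    ("H", "H", (-0.5, 0.9, 0.0)),
    ("CA", "C", (1.45, 0.0, 0.0)),
    ("HA", "H", (1.8, -0.9, 0.6)),
    ("CB", "C", (2.0, 1.2, 0.75)),
    ("C", "C", (2.0, -0.4, -1.35)),
    ("O", "O", (1.4, -1.2, -2.0)),
]


def make_pdb_text(n_models: int, seed: int = 0, n_res: int = 3) -> str:
    """A small multi-model poly-ALA PDB with per-model random jitter."""
    rng = np.random.default_rng(seed)
    lines = []
    for model in range(1, n_models + 1):
        lines.append(f"MODEL     {model:4d}")
        serial = 0
        jitter = rng.normal(0, 0.35, size=(n_res, len(_RESIDUE_ATOMS), 3))
        for r in range(n_res):
            base = np.array([3.6 * r, 0.4 * r, -0.2 * r])
            for a, (name, element, offset) in enumerate(_RESIDUE_ATOMS):
                serial += 1
                xyz = base + np.asarray(offset) + jitter[r, a]
                lines.append(_pdb_atom_line(serial, name, "ALA", r + 1, xyz, element))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def pdb_pool(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "pool.pdb"
    path.write_text(make_pdb_text(n_models=6, seed=2))
    return ip.ConformerPool.from_pdb(path)


def random_rigid_transform(rng):
    """Random rotation matrix (QR-based) and translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=20.0, size=3)
    return q, t
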