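"""Simplified local mutational frustration analysis.

For every native residue-residue contact, the native pair energy under a
20x20 statistical contact potential is compared with a decoy distribution
obtained by resampling the two residue identities from the chain's own
composition.  The frustration index is the z-score

    F_ij = (<E_decoy> - E_native) / SD(E_decoy)

so positive F means the native pair is more favorable than typical
alternatives (minimally frustrated) and strongly negative F flags highly
frustrated contacts.  This is a deliberately simplified desk-scale variant
of the energy-landscape frustration analysis: it uses a plain contact
potential with no distance-, density- or electrostatics-dependent terms,
which reproduces the qualitative minimal/neutral/high patterning but not
any particular published index value.

The default potential is a hydrophobicity-product matrix (Kyte-Doolittle
scale, outer product, sign chosen so hydrophobic-hydrophobic pairs are most
favorable), which orders pair energies the way classical knowledge-based
contact matrices do; any 20x20 symmetric matrix can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ContactMap, contact_map
from .io import StructureEnsemble

__all__ = [
    "AMINO_ACIDS",
    "StatPotential",
    "default_potential",
    "native_contact_energy",
    "mutational_frustration_index",
    "classify",
    "frustration_map",
    "compare_states",
    "FrustrationMap",
]

AMINO_ACIDS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

# Kyte-Doolittle hydropathy, residue order as AMINO_ACIDS
_KD = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}


@dataclass
class StatPotential:
    """Symmetric 20x20 residue-pair contact energies (lower = more favorable)."""

    matrix: np.ndarray
    name: str = "custom"
    residues: tuple[str, ...] = tuple(AMINO_ACIDS)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (20, 20):
            raise ValueError("potential must be 20x20")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("potential must be symmetric")
        self._index = {r: i for i, r in enumerate(self.residues)}

    def energy(self, res_a: str, res_b: str) -> float:
        try:
            ia, ib = self._index[res_a], self._index[res_b]
        except KeyError as exc:
            raise KeyError(f"no potential entry for residue {exc.args[0]!r}") from None
        return float(self.matrix[ia, ib])

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "StatPotential":
        df = pd.read_csv(path, index_col=0)
        mat = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)].to_numpy(float)
        return cls(matrix=mat, name=name or Path(path).stem)


def default_potential() -> StatPotential:
    """Hydrophobicity-product contact potential (see module docstring)."""
    h = np.array([(_KD[r] + 4.5) / 9.0 for r in AMINO_ACIDS])  # scaled to [0, 1]
    return StatPotential(matrix=-np.outer(h, h), name="kd-hydrophobicity-product")


def native_contact_energy(
    ens: StructureEnsemble,
    potential: StatPotential,
    contacts: ContactMap,
) -> pd.DataFrame:
    """Native pair energy E(res_i, res_j) for every contact."""
    names = ens.residue_names()
    rows = []
    for row in contacts.contacts.itertuples(index=False):
        e = potential.energy(names[row.i], names[row.j])
        rows.append({"i": row.i, "j": row.j, "distance": row.distance, "E_native": e})
    return pd.DataFrame(rows, columns=["i", "j", "distance", "E_native"])


def _composition(ens: StructureEnsemble) -> tuple[list[str], np.ndarray]:
    names = ens.residue_names()
    vals, counts = np.unique(names.to_numpy(), return_counts=True)
    return list(vals), counts / counts.sum()


def mutational_frustration_index(
    ens: StructureEnsemble,
    pair: tuple[int, int],
    potential: StatPotential,
    n_decoys: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Frustration z-score for one contact.

    Decoys keep the contact but resample both residue identities
    independently from the chain composition.  Raises if the decoy energy
    distribution is degenerate (zero variance).
    """
    if n_decoys < 100:
        raise ValueError("n_decoys must be >= 100")
    names = ens.residue_names()
    e_native = potential.energy(names[pair[0]], names[pair[1]])
    alphabet, probs = _composition(ens)
    rng = rng if rng is not None else np.random.default_rng(seed)
    ra = rng.choice(alphabet, size=n_decoys, p=probs)
    rb = rng.choice(alphabet, size=n_decoys, p=probs)
    e_decoy = np.array([potential.energy(a, b) for a, b in zip(ra, rb)])
    sd = float(e_decoy.std())
    if sd == 0.0:
        raise ValueError("degenerate decoy distribution (SD = 0)")
    return float((e_decoy.mean() - e_native) / sd)


def classify(F: float, hi_cut: float = 0.78, lo_cut: float = -1.0) -> str:
    """Three-way frustration class; cuts follow the common convention
    (minimal >= 0.78, high <= -1.0) and are configuration, not claims."""
    if hi_cut <= lo_cut:
        raise ValueError("hi_cut must exceed lo_cut")
    if not np.isfinite(F):
        raise ValueError("frustration index must be finite")
    if F >= hi_cut:
        return "minimal"
    if F <= lo_cut:
        return "high"
    return "neutral"


@dataclass
class FrustrationMap:
    table: pd.DataFrame  # i, j, distance, E_native, decoy_mean, decoy_sd, F, cls
    mode: str
    potential: str
    meta: dict = field(default_factory=dict)

    def pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.table["i"].astype(int), self.table["j"].astype(int)))

    def class_of(self) -> dict[tuple[int, int], str]:
        return {
            (int(r.i), int(r.j)): r.cls for r in self.table.itertuples(index=False)
        }


def frustration_map(
    ens: StructureEnsemble,
    potential: StatPotential | None = None,
    contact_mode: str = "calpha-5A",
    n_decoys: int = 1000,
    seed: int = 0,
    hi_cut: float = 0.78,
    lo_cut: float = -1.0,
    model: int | None = 0,
) -> FrustrationMap:
    """Per-contact frustration indices and classes for a structure."""
    potential = potential or default_potential()
    cm = contact_map(ens, mode=contact_mode, model=model)
    names = ens.residue_names()
    alphabet, probs = _composition(ens)
    rng = np.random.default_rng(seed)
    rows = []
    for row in cm.contacts.itertuples(index=False):
        e_native = potential.energy(names[row.i], names[row.j])
        ra = rng.choice(alphabet, size=n_decoys, p=probs)
        rb = rng.choice(alphabet, size=n_decoys, p=probs)
        e_decoy = np.array([potential.energy(a, b) for a, b in zip(ra, rb)])
        sd = float(e_decoy.std())
        if sd == 0.0:
            raise ValueError(f"degenerate decoy distribution for pair {(row.i, row.j)}")
        F = float((e_decoy.mean() - e_native) / sd)
        rows.append({
            "i": row.i, "j": row.j, "distance": row.distance,
            "E_native": e_native, "decoy_mean": float(e_decoy.mean()),
            "decoy_sd": sd, "F": F, "cls": classify(F, hi_cut, lo_cut),
        })
    cols = ["i", "j", "distance", "E_native", "decoy_mean", "decoy_sd", "F", "cls"]
    return FrustrationMap(
        table=pd.DataFrame(rows, columns=cols),
        mode=contact_mode,
        potential=potential.name,
        meta={"n_decoys": n_decoys, "seed": seed, "hi_cut": hi_cut, "lo_cut": lo_cut},
    )


def compare_states(maps: dict[str, FrustrationMap]) -> pd.DataFrame:
    """Per-pair class transitions across labelled conformational states.

    E.g. a contact classified ``high`` in the closed state and absent in the
    open state appears as ``high -> absent``; summary counts come from
    ``value_counts`` on the transition column.
    """
    labels = list(maps)
    if len(labels) < 2:
        raise ValueError("need at least two labelled states")
    modes = {m.mode for m in maps.values()}
    if len(modes) != 1:
        raise ValueError("maps use inconsistent contact definitions")
    class_tables = {lab: maps[lab].class_of() for lab in labels}
    all_pairs = sorted(set().union(*[m.pairs() for m in maps.values()]))
    rows = []
    for pair in all_pairs:
        states = [class_tables[lab].get(pair, "absent") for lab in labels]
        rows.append({
            "i": pair[0], "j": pair[1],
            **{lab: st for lab, st in zip(labels, states)},
            "transition": " -> ".join(states),
        })
    return pd.DataFrame(rows)
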