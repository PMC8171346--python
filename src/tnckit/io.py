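"""Coordinate and tabular I/O, run configuration.

Conformational ensembles travel as multi-model PDB files (one frame == one
MODEL); residue identifiers are the author-assigned numbers in the file and
are never renumbered, so the cTnC ranges used throughout (helix A 14-25,
helix B 38-47, core 4-85, backbone 1-100) refer to author numbering.
Coordinates are in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StructureEnsemble",
    "TableSpec",
    "RunConfig",
    "parse_structure",
    "write_structure",
    "read_table",
    "write_table",
    "load_config",
]


@dataclass
class StructureEnsemble:
    """Multi-model atomic coordinates with a shared atom roster.

    ``atoms`` holds one row per atom (resnum, resname, atom, chain) in file
    order; ``coords`` is (n_models, n_atoms, 3) in Angstrom.  Every model must
    share the same roster — that is what makes per-atom statistics over
    models (RMSF, PCA) well defined.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom roster and coordinate array disagree in length")
        if self.n_models < 1:
            raise ValueError("ensemble needs at least one model")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_mask(
        self,
        residues: Sequence[int] | None = None,
        atom_names: Sequence[str] | None = None,
        chain: str | None = None,
    ) -> np.ndarray:
        """Boolean mask over the atom roster."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residues is not None:
            mask &= self.atoms["resnum"].isin(list(residues)).to_numpy()
        if atom_names is not None:
            mask &= self.atoms["atom"].isin(list(atom_names)).to_numpy()
        if chain is not None:
            mask &= (self.atoms["chain"] == chain).to_numpy()
        return mask

    def calpha(self, residues: Sequence[int]) -> np.ndarray:
        """Cα coordinates for ``residues`` (in the given order), all models.

        Raises if any requested residue lacks a Cα, listing the culprits.
        """
        ca = self.atoms[self.atoms["atom"] == "CA"]
        lookup = dict(zip(ca["resnum"], ca.index))
        missing = [r for r in residues if r not in lookup]
        if missing:
            raise ValueError(f"missing CA for residues: {missing}")
        idx = [lookup[r] for r in residues]
        return self.coords[:, idx, :]

    def residue_names(self) -> pd.Series:
        """Residue name per residue number (first occurrence wins)."""
        per_res = self.atoms.drop_duplicates("resnum")
        return pd.Series(
            per_res["resname"].to_numpy(), index=per_res["resnum"].to_numpy()
        )


def parse_structure(path: str | Path, model_selection="all") -> StructureEnsemble:
    """Read a (multi-model) PDB file into a :class:`StructureEnsemble`.

    ``model_selection`` is ``"all"`` or a list of 0-based model positions.
    Atom ordering and residue numbering are preserved exactly as in the file.
    Models with a roster differing from model 1 are a hard error naming the
    offending MODEL record.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")

    def roster_and_xyz(model):
        rows, xyz = [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    rows.append(
                        (res.seqid.num, res.name, atom.name, chain.name)
                    )
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        return rows, np.array(xyz, dtype=float)

    models = list(st)
    if model_selection != "all":
        models = [models[i] for i in model_selection]

    ref_rows, xyz0 = roster_and_xyz(models[0])
    coords = [xyz0]
    for model in models[1:]:
        rows, xyz = roster_and_xyz(model)
        if rows != ref_rows:
            raise ValueError(
                f"model {model.num} atom roster differs from model "
                f"{models[0].num} ({len(rows)} vs {len(ref_rows)} atoms "
                "or mismatched identities)"
            )
        coords.append(xyz)

    atoms = pd.DataFrame(ref_rows, columns=["resnum", "resname", "atom", "chain"])
    return StructureEnsemble(atoms=atoms, coords=np.stack(coords), meta={"source": str(path)})


def write_structure(ens: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (one MODEL per frame)."""
    st = gemmi.Structure()
    st.name = "tnckit"
    for imodel in range(ens.n_models):
        model = gemmi.Model(imodel + 1)
        chain_order: list[str] = []
        chain_map: dict[str, gemmi.Chain] = {}
        res_map: dict[tuple, gemmi.Residue] = {}
        for iatom, row in enumerate(ens.atoms.itertuples(index=False)):
            if row.chain not in chain_map:
                chain_map[row.chain] = gemmi.Chain(row.chain)
                chain_order.append(row.chain)
            key = (row.chain, row.resnum, row.resname)
            if key not in res_map:
                res = gemmi.Residue()
                res.name = row.resname
                res.seqid = gemmi.SeqId(int(row.resnum), " ")
                res_map[key] = res
            atom = gemmi.Atom()
            atom.name = row.atom
            atom.element = gemmi.Element(row.atom[0])
            x, y, z = ens.coords[imodel, iatom]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            res_map[key].add_atom(atom)
        # assemble bottom-up: gemmi add_* copy their argument, so residues
        # and chains must be complete before insertion
        grouped: dict[str, list[gemmi.Residue]] = {c: [] for c in chain_order}
        for (cname, _, _), res in res_map.items():
            grouped[cname].append(res)
        for cname in chain_order:
            chain = chain_map[cname]
            for res in grouped[cname]:
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


@dataclass
class TableSpec:
    """Schema for a delimited table: required columns, units, NA sentinel."""

    columns: dict[str, str]  # name -> unit ("" for dimensionless/labels)
    sentinel: str = "NA"


def read_table(path: str | Path, spec: TableSpec | None = None) -> pd.DataFrame:
    """Read a header-ful CSV; with a ``spec``, enforce required columns and
    treat the sentinel as missing (never coerced to a number)."""
    na = [spec.sentinel] if spec is not None else ["NA"]
    df = pd.read_csv(path, na_values=na, keep_default_na=True)
    if spec is not None:
        missing = [c for c in spec.columns if c not in df.columns]
        if missing:
            raise ValueError(f"table {path} missing required columns: {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


_CONFIG_KEYS = {"stage", "inputs", "parameters", "seed", "outdir"}


@dataclass
class RunConfig:
    stage: str
    inputs: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    outdir: str = "results"


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown top-level keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stage" not in raw:
        raise ValueError("config must name a stage")
    return RunConfig(**raw)
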