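"""Conformational-ensemble analytics for EF-hand domains.

Implements the standard trajectory/ensemble observables used to characterise
N-domain opening of cardiac troponin C: interhelical angle between helices A
(residues 14-25) and B (residues 38-47) from SVD helix axes, open-state
fraction (strict angle < 110 deg), RMSF after Kabsch superposition on the
backbone of residues 1-100, residue contact maps (heavy-atom 7 A with >=6
sequence separation, or Calpha 5 A), Calpha PCA over the core region
(residues 4-85) and one-dimensional free-energy landscapes over PC1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.transform import Rotation

from .io import StructureEnsemble

__all__ = [
    "HelixSpec",
    "ContactMap",
    "PCAResult",
    "FEL1D",
    "helix_axis",
    "ab_angle",
    "ensemble_ab_angles",
    "open_fraction",
    "rmsf",
    "contact_map",
    "diff_contact_map",
    "pca",
    "fel_1d",
    "welch_t",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class HelixSpec:
    """Residue ranges (inclusive, author numbering) defining helices A and B."""

    helix_a: tuple[int, int] = (14, 25)
    helix_b: tuple[int, int] = (38, 47)

    def __post_init__(self):
        ra, rb = self.residues_a(), self.residues_b()
        if len(ra) < 4 or len(rb) < 4:
            raise ValueError("each helix needs at least 4 residues")
        if set(ra) & set(rb):
            raise ValueError("helix ranges must be disjoint")

    def residues_a(self):
        return list(range(self.helix_a[0], self.helix_a[1] + 1))

    def residues_b(self):
        return list(range(self.helix_b[0], self.helix_b[1] + 1))


def helix_axis(calpha_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Helix axis as the principal direction of the Calpha trace.

    Returns (unit axis, centroid).  The axis is oriented N->C: its projection
    on the last-minus-first Calpha vector is positive.
    """
    X = np.asarray(calpha_coords, float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected (n, 3) coordinates")
    if len(X) < 4:
        raise ValueError("need at least 4 Calpha positions for an axis")
    centroid = X.mean(axis=0)
    _, _, vt = np.linalg.svd(X - centroid)
    axis = vt[0]
    nc = X[-1] - X[0]
    if float(axis @ nc) < 0:
        axis = -axis
    return axis, centroid


def ab_angle(ens: StructureEnsemble, model: int, spec: HelixSpec | None = None) -> float:
    """AB interhelical angle (degrees, [0, 180]) for one model."""
    spec = spec or HelixSpec()
    ca_a = ens.calpha(spec.residues_a())[model]
    ca_b = ens.calpha(spec.residues_b())[model]
    ax_a, _ = helix_axis(ca_a)
    ax_b, _ = helix_axis(ca_b)
    cosang = float(np.clip(ax_a @ ax_b, -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def ensemble_ab_angles(ens: StructureEnsemble, spec: HelixSpec | None = None) -> np.ndarray:
    """AB angle for every model of the ensemble."""
    spec = spec or HelixSpec()
    ca_a = ens.calpha(spec.residues_a())
    ca_b = ens.calpha(spec.residues_b())
    out = np.empty(ens.n_models)
    for i in range(ens.n_models):
        ax_a, _ = helix_axis(ca_a[i])
        ax_b, _ = helix_axis(ca_b[i])
        out[i] = np.degrees(np.arccos(np.clip(ax_a @ ax_b, -1.0, 1.0)))
    return out


def open_fraction(
    angles,
    threshold: float = 110.0,
    replicate_labels=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Fraction of models with angle strictly below ``threshold``.

    Returns the pooled fraction, a seeded bootstrap percentile CI over
    models, and — when replicate labels are given — per-replicate fractions
    (both poolings of the published per-replicate convention are thereby
    available).
    """
    a = np.asarray(angles, float)
    if a.size == 0:
        raise ValueError("need at least one angle")
    frac = float(np.mean(a < threshold))
    rng = np.random.default_rng(seed)
    boot = np.array([
        np.mean(rng.choice(a, size=a.size, replace=True) < threshold)
        for _ in range(n_boot)
    ])
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    result = {"fraction": frac, "ci": ci, "threshold": threshold}
    if replicate_labels is not None:
        labels = np.asarray(replicate_labels)
        result["per_replicate"] = {
            str(lab): float(np.mean(a[labels == lab] < threshold))
            for lab in np.unique(labels)
        }
    return result


def _kabsch_align(ens: StructureEnsemble, selection_mask: np.ndarray) -> np.ndarray:
    """Superpose every model onto model 1 over ``selection_mask`` atoms.

    Least-squares (Kabsch) rotation + translation; returns aligned coords of
    shape (n_models, n_atoms, 3)."""
    if selection_mask.sum() == 0:
        raise ValueError("alignment selection is empty")
    ref = ens.coords[0, selection_mask]
    ref_c = ref - ref.mean(axis=0)
    aligned = np.empty_like(ens.coords)
    for i in range(ens.n_models):
        mob = ens.coords[i, selection_mask]
        shift = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mob - shift)
        aligned[i] = rot.apply(ens.coords[i] - shift) + ref.mean(axis=0)
    return aligned


def rmsf(
    ens: StructureEnsemble,
    align_residues=range(1, 101),
    align_atoms=BACKBONE_ATOMS,
) -> pd.DataFrame:
    """Per-residue Calpha RMSF after superposition onto the first model.

    All frames are first aligned to frame 1 over the backbone atoms of the
    alignment selection (default: residues 1-100), then the fluctuation of
    each Calpha about its mean position is reported in Angstrom.
    """
    if ens.n_models < 2:
        raise ValueError("RMSF needs at least two models")
    mask = ens.atom_mask(residues=list(align_residues), atom_names=list(align_atoms))
    aligned = _kabsch_align(ens, mask)
    ca_mask = ens.atom_mask(atom_names=["CA"])
    ca = aligned[:, ca_mask]
    mean = ca.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((ca - mean) ** 2, axis=2), axis=0))
    resnums = ens.atoms.loc[ca_mask, "resnum"].to_numpy()
    return pd.DataFrame({"resnum": resnums, "rmsf": fluct})


CONTACT_MODES = {
    # mode -> (atom class, cutoff A, min |i-j|)
    "heavy-7A-sep6": ("heavy", 7.0, 6),
    "calpha-5A": ("calpha", 5.0, 3),
}


@dataclass
class ContactMap:
    contacts: pd.DataFrame  # columns: i, j, distance (+ occupancy for ensembles)
    mode: str
    cutoff: float
    min_sep: int
    meta: dict = field(default_factory=dict)

    def pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.contacts["i"].astype(int), self.contacts["j"].astype(int)))


_HYDROGEN_PREFIXES = ("H", "1H", "2H", "3H")


def _is_heavy(name: str) -> bool:
    return not name.strip().startswith(_HYDROGEN_PREFIXES)


def contact_map(
    ens: StructureEnsemble,
    mode: str = "heavy-7A-sep6",
    model: int | None = None,
    occupancy_cutoff: float = 0.0,
) -> ContactMap:
    """Residue-residue contact map.

    ``heavy-7A-sep6``: any heavy-atom pair within 7 A for residues separated
    by at least 6 positions.  ``calpha-5A``: Calpha pairs within 5 A.  For a
    multi-model ensemble (``model=None``) the per-pair occupancy over models
    is reported and the minimum distance is the per-pair ensemble minimum.
    """
    if mode not in CONTACT_MODES:
        raise ValueError(f"unknown contact mode: {mode!r}")
    atom_class, cutoff, min_sep = CONTACT_MODES[mode]

    if atom_class == "calpha":
        mask = ens.atom_mask(atom_names=["CA"])
    else:
        mask = ens.atoms["atom"].map(_is_heavy).to_numpy()
    sub = ens.atoms.loc[mask]
    resnums = sub["resnum"].to_numpy()
    models = range(ens.n_models) if model is None else [model]

    per_model_pairs: list[dict[tuple[int, int], float]] = []
    for im in models:
        xyz = ens.coords[im, mask]
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
        ii, jj = np.where(d <= cutoff)
        found: dict[tuple[int, int], float] = {}
        for a, b in zip(ii, jj):
            ri, rj = int(resnums[a]), int(resnums[b])
            if rj - ri < min_sep:
                continue
            key = (ri, rj)
            dist = float(d[a, b])
            if key not in found or dist < found[key]:
                found[key] = dist
        per_model_pairs.append(found)

    all_pairs = sorted(set().union(*[set(p) for p in per_model_pairs]))
    rows = []
    nm = len(per_model_pairs)
    for key in all_pairs:
        occ = sum(key in p for p in per_model_pairs) / nm
        if occ < occupancy_cutoff:
            continue
        dmin = min(p[key] for p in per_model_pairs if key in p)
        rows.append({"i": key[0], "j": key[1], "distance": dmin, "occupancy": occ})
    df = pd.DataFrame(rows, columns=["i", "j", "distance", "occupancy"])
    return ContactMap(contacts=df, mode=mode, cutoff=cutoff, min_sep=min_sep,
                      meta={"n_models": nm})


def diff_contact_map(map_a: ContactMap, map_b: ContactMap) -> dict:
    """Set algebra on contact pairs: gained/lost/persistent from A to B."""
    if (map_a.mode, map_a.cutoff, map_a.min_sep) != (map_b.mode, map_b.cutoff, map_b.min_sep):
        raise ValueError("contact definitions differ between maps")
    pa, pb = map_a.pairs(), map_b.pairs()
    occ_a = dict(zip(map_a.pairs(), map_a.contacts["occupancy"])) if len(map_a.contacts) else {}
    occ_b = dict(zip(map_b.pairs(), map_b.contacts["occupancy"])) if len(map_b.contacts) else {}
    persistent = sorted(pa & pb)
    return {
        "gained": sorted(pb - pa),
        "lost": sorted(pa - pb),
        "persistent": persistent,
        "occupancy_delta": {p: occ_b.get(p, 0.0) - occ_a.get(p, 0.0) for p in persistent},
    }


@dataclass
class PCAResult:
    mean: np.ndarray            # (n_atoms_sel, 3)
    eigenvectors: np.ndarray    # (n_modes, n_atoms_sel*3)
    eigenvalues: np.ndarray     # A^2, non-increasing
    projections: np.ndarray     # (n_models, n_modes)
    variance_fractions: np.ndarray


def pca(
    ens: StructureEnsemble,
    residues=range(4, 86),
    align_residues=range(1, 101),
) -> PCAResult:
    """Calpha principal component analysis over the core region.

    Frames are Kabsch-aligned to frame 1 (backbone, residues 1-100 by
    default, intersected with what the ensemble actually contains), then the
    covariance of the selected Calpha coordinates is eigendecomposed.
    Projections are centered; variance fractions sum to 1.
    """
    if ens.n_models < 3:
        raise ValueError("PCA needs at least 3 models")
    present = set(ens.atoms["resnum"])
    align_sel = [r for r in align_residues if r in present]
    mask = ens.atom_mask(residues=align_sel, atom_names=list(BACKBONE_ATOMS))
    if mask.sum() == 0:  # Calpha-only fixtures
        mask = ens.atom_mask(residues=align_sel, atom_names=["CA"])
    aligned = _kabsch_align(ens, mask)

    sel = [r for r in residues if r in present]
    ca_mask = ens.atom_mask(residues=sel, atom_names=["CA"])
    X = aligned[:, ca_mask].reshape(ens.n_models, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered data matrix == eigendecomposition of the covariance
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (ens.n_models - 1)
    proj = Xc @ vt.T
    total = eigvals.sum()
    return PCAResult(
        mean=mean.reshape(-1, 3),
        eigenvectors=vt,
        eigenvalues=eigvals,
        projections=proj,
        variance_fractions=eigvals / total if total > 0 else eigvals,
    )


@dataclass
class FEL1D:
    centers: np.ndarray
    delta_g: np.ndarray   # kT units; NaN where the bin is empty
    counts: np.ndarray
    temperature: float


def fel_1d(projections, temperature: float = 310.0, bins: int = 50) -> FEL1D:
    """One-dimensional free-energy landscape by Boltzmann inversion.

    dG(bin) = -kT ln(count / max count), reported in kT units so the
    temperature only labels the result; empty bins are masked (NaN), never
    assigned zero energy.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    p = np.asarray(projections, float)
    counts, edges = np.histogram(p, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dg = np.full(bins, np.nan)
    nz = counts > 0
    dg[nz] = -np.log(counts[nz] / counts.max())
    return FEL1D(centers=centers, delta_g=dg, counts=counts, temperature=temperature)


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch t-test on per-replicate statistics.

    Degenerate case (zero variance in both groups, equal means) returns
    t=0, p=1 by convention.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return np.inf * np.sign(np.mean(a) - np.mean(b)), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
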