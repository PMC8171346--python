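"""Seeded synthetic-data generators for every input class of the pipeline.

The generators emulate the statistical structure of the study conditions —
replicate-level force-pCa curves at S.E.M.-scale noise with the genotype
pCa50 values of the permeabilized-muscle experiments, 3-state-consistent
force/kTR pairs, two-helix coordinate ensembles with prescribed (possibly
bimodal) interhelical-angle distributions, 1:1 titration peak lists,
mono-exponential relaxation decays, two-regime CPMG dispersion, one/two
transition CD melts, and folded/unfolded SAXS mixtures.  Every generator is
a pure function of (spec, seed) and records its ground-truth parameters in
the output so the matching estimator can be tested as an inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics
from .io import StructureEnsemble
from .kinetics import CaActivation, KineticParams, hill_curve
from .nmr import bound_fraction

__all__ = [
    "GenotypeMechSpec",
    "GENOTYPES",
    "AngleDistSpec",
    "gen_force_pca",
    "gen_mechanics_3state",
    "gen_two_helix_ensemble",
    "gen_titration_peaklists",
    "gen_relaxation_decays",
    "gen_cpmg",
    "gen_melting_curve",
    "gen_saxs_profiles",
    "R1_DELAYS_S",
    "R2_DELAYS_S",
    "TITRATION_CONCS_UM",
]

#: relaxation delay ladders of the R1 / R2 experiments (seconds)
R1_DELAYS_S = (0.020, 0.050, 0.100, 0.200, 0.250, 0.500, 0.750, 1.000, 1.500)
R2_DELAYS_S = (0.016, 0.048, 0.080, 0.112, 0.144, 0.176, 0.208, 0.240, 0.272, 0.304)
#: peptide titration ladder (uM), plus the peptide-free reference point
TITRATION_CONCS_UM = (0.0, 15.0, 40.0, 70.0, 120.0, 150.0, 200.0)


@dataclass(frozen=True)
class GenotypeMechSpec:
    """Hill-curve parameters of one genotype's force-pCa relation."""

    label: str
    pCa50: float
    nHill: float = 3.0
    Fmax: float = 1.0
    Fmin: float = 0.0
    noise_sd: float = 0.04  # S.E.M.-scale additive noise on normalized force
    replicates: int = 6

    def __post_init__(self):
        if not self.Fmax > self.Fmin >= 0:
            raise ValueError("need Fmax > Fmin >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


#: default genotype map mirroring the measured pCa50 estimates
GENOTYPES = {
    "WT": GenotypeMechSpec(label="WT", pCa50=5.56),
    "C84Y": GenotypeMechSpec(label="C84Y", pCa50=5.72),
}

DEFAULT_PCA_GRID = tuple(np.round(np.arange(7.0, 3.99, -0.25), 3))


def gen_force_pca(spec: GenotypeMechSpec, grid=DEFAULT_PCA_GRID, seed: int = 0) -> pd.DataFrame:
    """Replicate force-pCa observations on a Hill curve with Gaussian noise.

    Returns a long table (pCa, force, genotype, replicate); the noiseless
    curve and generating parameters live in ``attrs['truth']``.
    """
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("pCa grid is empty")
    rng = np.random.default_rng(seed)
    clean = hill_curve(grid, spec.pCa50, spec.nHill, spec.Fmin, spec.Fmax)
    rows = []
    for rep in range(spec.replicates):
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=grid.size)
        for p, fo in zip(grid, noisy):
            rows.append({"pCa": p, "force": fo, "genotype": spec.label, "replicate": rep})
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "pCa50": spec.pCa50, "nHill": spec.nHill, "Fmax": spec.Fmax,
        "Fmin": spec.Fmin, "noise_sd": spec.noise_sd, "clean": clean,
    }
    return df


def gen_mechanics_3state(
    params: KineticParams,
    grid=DEFAULT_PCA_GRID,
    noise: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Force and kTR observations drawn from the 3-state model.

    Multiplicative Gaussian noise of fractional SD ``noise`` on both
    columns.  The noiseless model curves are the oracle for fit inversion.
    """
    for name in ("kON", "kOFF", "f", "g"):
        if getattr(params, name) <= 0:
            raise ValueError(f"rate {name} must be positive for generation")
    grid = np.asarray(grid, float)
    rng = np.random.default_rng(seed)
    clean = kinetics.model_curves(params, grid)
    rows = []
    for rep in range(replicates):
        eps_f = rng.normal(0.0, noise, size=len(clean)) if noise > 0 else 0.0
        eps_k = rng.normal(0.0, noise, size=len(clean)) if noise > 0 else 0.0
        force = clean["force"].to_numpy() * (1.0 + eps_f)
        ktr_v = clean["ktr"].to_numpy() * (1.0 + eps_k)
        for p, fo, kt in zip(grid, force, ktr_v):
            rows.append({"pCa": p, "force": fo, "ktr": kt, "replicate": rep})
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {"params": params, "clean": clean}
    return df


@dataclass(frozen=True)
class AngleDistSpec:
    """Mixture of normal components over the AB interhelical angle."""

    components: tuple[tuple[float, float, float], ...]  # (mean deg, SD deg, weight)
    n_models: int = 100

    def __post_init__(self):
        w = sum(c[2] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        for mean, _, _ in self.components:
            if not (0.0 <= mean < 180.0):
                raise ValueError("component means must lie in [0, 180)")


# textbook alpha-helix Calpha geometry
HELIX_RISE = 1.5    # A per residue
HELIX_RADIUS = 2.3  # A
HELIX_TWIST = 100.0  # deg per residue


def _ideal_helix(n_res: int) -> np.ndarray:
    """Calpha trace of an ideal alpha helix with its axis along +z."""
    i = np.arange(n_res)
    phi = np.radians(HELIX_TWIST * i)
    return np.column_stack([
        HELIX_RADIUS * np.cos(phi),
        HELIX_RADIUS * np.sin(phi),
        HELIX_RISE * i,
    ])


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b (Rodrigues)."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        K = np.array([[0, -perp[2], perp[1]], [perp[2], 0, -perp[0]], [-perp[1], perp[0], 0]])
        return np.eye(3) + 2.0 * K @ K
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * (1.0 / (1.0 + c))


def gen_two_helix_ensemble(spec: AngleDistSpec, seed: int = 0) -> StructureEnsemble:
    """Calpha-only two-helix models with prescribed interhelical angles.

    Helix A (residues 14-25) is a fixed ideal helix; helix B (residues
    38-47) is an ideal helix oriented so that the angle between the two
    helices' principal (SVD) axes equals the per-model draw exactly.  The
    principal axis of a short ideal helix tilts a few degrees away from the
    geometric screw axis (finite, non-integer number of turns), so the
    prescription is applied to the measured axis — the ground truth stored
    in ``meta['truth_angles_deg']`` is exactly what an SVD-axis estimator
    should recover.
    """
    from .geometry import helix_axis  # local import: geometry imports io only

    rng = np.random.default_rng(seed)
    means = np.array([c[0] for c in spec.components])
    sds = np.array([c[1] for c in spec.components])
    weights = np.array([c[2] for c in spec.components])
    comp = rng.choice(len(means), size=spec.n_models, p=weights)
    thetas = np.clip(rng.normal(means[comp], sds[comp]), 0.0, 180.0)

    res_a = list(range(14, 26))
    res_b = list(range(38, 48))
    helix_a = _ideal_helix(len(res_a))
    helix_b0 = _ideal_helix(len(res_b))
    helix_b0 = helix_b0 - helix_b0.mean(axis=0)

    axis_a, _ = helix_axis(helix_a)
    axis_b0, _ = helix_axis(helix_b0)
    # u: unit vector perpendicular to axis_a, in-plane direction for opening
    u = np.cross(axis_a, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)

    models = []
    for theta in thetas:
        t = np.radians(theta)
        target = np.cos(t) * axis_a + np.sin(t) * u  # makes angle theta with axis_a
        rot = _minimal_rotation(axis_b0, target)
        helix_b = helix_b0 @ rot.T + np.array([10.0, 0.0, helix_a[:, 2].mean()])
        models.append(np.vstack([helix_a, helix_b]))

    atoms = pd.DataFrame({
        "resnum": res_a + res_b,
        "resname": ["ALA"] * (len(res_a) + len(res_b)),
        "atom": ["CA"] * (len(res_a) + len(res_b)),
        "chain": ["A"] * (len(res_a) + len(res_b)),
    })
    return StructureEnsemble(
        atoms=atoms,
        coords=np.stack(models),
        meta={"truth_angles_deg": thetas, "spec": spec},
    )


def gen_titration_peaklists(
    Kd: float,
    csp_max: dict[int, float],
    ligand_concs=TITRATION_CONCS_UM,
    Pt: float = 100.0,
    noise: float = 0.0,
    seed: int = 0,
) -> dict[float, pd.DataFrame]:
    """Peak lists along a 1:1 titration.

    Per-residue displacements follow the quadratic bound-fraction isotherm
    scaled by ``csp_max`` (ppm), split sqrt(0.7)/sqrt(3) between dH and dN
    so the combined CSP formula recovers exactly the total displacement.
    Returns {ligand concentration: peak list}.
    """
    if Pt <= 0:
        raise ValueError("Pt must be positive")
    concs = np.asarray(ligand_concs, float)
    if np.any(concs < 0):
        raise ValueError("ligand concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    residues = sorted(csp_max)
    base_h = {r: 8.0 + 0.01 * r for r in residues}
    base_n = {r: 115.0 + 0.1 * r for r in residues}
    out = {}
    for L in concs:
        fb = float(bound_fraction(L, Pt, Kd))
        rows = []
        for r in residues:
            total = csp_max[r] * fb + (rng.normal(0.0, noise) if noise > 0 else 0.0)
            rows.append({
                "residue": r,
                "dH_ppm": base_h[r] + np.sqrt(0.7) * total,
                "dN_ppm": base_n[r] + np.sqrt(3.0) * total,
            })
        out[float(L)] = pd.DataFrame(rows)
    return out


def gen_relaxation_decays(
    rates: dict[int, float],
    delays=R1_DELAYS_S,
    noise: float = 0.0,
    I0: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mono-exponential decay table (residue, delay_s, intensity)."""
    delays = np.asarray(delays, float)
    if np.any(delays <= 0):
        raise ValueError("delays must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for res, rate in sorted(rates.items()):
        clean = I0 * np.exp(-rate * delays)
        eps = rng.normal(0.0, noise, size=delays.size) if noise > 0 else 0.0
        for t, inten in zip(delays, clean * (1.0 + eps)):
            rows.append({"residue": res, "delay_s": t, "intensity": inten})
    df = pd.DataFrame(rows)
    df.attrs["truth"] = dict(rates)
    return df


def luz_meiboom_r2eff(nu, R20: float, Rex: float, kex: float):
    """Fast-exchange dispersion: R2eff(nu) = R20 + Rex (1 - (4nu/kex) tanh(kex/4nu))."""
    nu = np.asarray(nu, float)
    x = 4.0 * nu / kex
    return R20 + Rex * (1.0 - x * np.tanh(1.0 / x))


def gen_cpmg(
    R20: float,
    Rex: float,
    kex: float,
    nu_list=(50.0, 1000.0),
    T: float = 0.04,
    I0: float = 1000.0,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """CPMG intensities consistent with Luz-Meiboom dispersion.

    Intensities are back-computed through I = I0 exp(-R2eff T) so the
    analyzer's R2eff formula inverts them exactly.  Returns a table
    (nu_hz, intensity, I0, T_s) with the generating R2eff in attrs.
    """
    if T <= 0:
        raise ValueError("relaxation period must be positive")
    nu = np.asarray(nu_list, float)
    r2 = luz_meiboom_r2eff(nu, R20, Rex, kex) if Rex > 0 else np.full(nu.shape, R20)
    rng = np.random.default_rng(seed)
    inten = I0 * np.exp(-r2 * T)
    if noise > 0:
        inten = inten * (1.0 + rng.normal(0.0, noise, size=nu.size))
    df = pd.DataFrame({"nu_hz": nu, "intensity": inten})
    df.attrs["truth"] = {"R20": R20, "Rex": Rex, "kex": kex, "R2eff": r2}
    df.attrs["I0"] = I0
    df.attrs["T_s"] = T
    return df


def gen_melting_curve(
    transitions,
    baseline=(0.0, 0.0),
    grid=None,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """CD melt: linear baseline + sum of two-state sigmoids + noise.

    ``transitions``: list of (Tm degC, amplitude, width degC); 1 or 2 of
    them.  Default grid 20-90 degC every 0.2 degC (the thermogram
    acquisition grid).
    """
    if not 1 <= len(transitions) <= 2:
        raise ValueError("1 or 2 transitions supported")
    T = np.arange(20.0, 90.0 + 1e-9, 0.2) if grid is None else np.asarray(grid, float)
    rng = np.random.default_rng(seed)
    y = baseline[0] + baseline[1] * T
    for tm, amp, width in transitions:
        y = y + amp / (1.0 + np.exp((tm - T) / width))
    if noise > 0:
        y = y + rng.normal(0.0, noise, size=T.size)
    df = pd.DataFrame({"temperature_C": T, "signal": y})
    df.attrs["truth"] = {"transitions": list(transitions), "baseline": baseline}
    return df


def gen_saxs_profiles(
    Rg: float = 15.0,
    folded_fraction: float = 1.0,
    s_grid=None,
    I0: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mixture of a compact (Guinier) and an unfolded (Debye) scatterer.

    folded: I(s) = I0 exp(-(s Rg)^2 / 3); unfolded: Debye chain with the
    same Rg.  folded_fraction = 1 gives a bell-shaped Kratky curve peaking
    at sRg = sqrt(3); 0 gives a monotone plateau approach.
    """
    if not 0.0 <= folded_fraction <= 1.0:
        raise ValueError("folded_fraction must be in [0, 1]")
    s = np.linspace(0.005, 0.5, 300) if s_grid is None else np.asarray(s_grid, float)
    if np.any(s <= 0):
        raise ValueError("s grid must be positive")
    rng = np.random.default_rng(seed)
    x2 = (s * Rg) ** 2
    folded = np.exp(-x2 / 3.0)
    debye = 2.0 * (np.exp(-x2) - 1.0 + x2) / x2**2
    I = I0 * (folded_fraction * folded + (1.0 - folded_fraction) * debye)
    if noise > 0:
        I = I * (1.0 + rng.normal(0.0, noise, size=s.size))
    df = pd.DataFrame({"s": s, "I": I})
    df.attrs["truth"] = {"Rg": Rg, "folded_fraction": folded_fraction, "I0": I0}
    return df
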