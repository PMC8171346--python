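"""Ensemble geometry: axes, angles, open fractions, RMSF, contacts, PCA,
free-energy landscapes and the replicate comparison test."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from tnckit import geometry as geo
from tnckit import synth
from tnckit.io import StructureEnsemble

from conftest import make_toy_structure


def ideal_helix(n=12):
    return synth._ideal_helix(n)


class TestHelixAxis:
    def test_axis_along_z(self):
        ax, _ = geo.helix_axis(ideal_helix())
        # principal axis of a finite helix tilts slightly off the screw axis
        assert abs(ax @ [0, 0, 1]) > 0.99

    def test_orientation_follows_chain_direction(self):
        coords = ideal_helix()
        ax_fwd, _ = geo.helix_axis(coords)
        ax_rev, _ = geo.helix_axis(coords[::-1])
        np.testing.assert_allclose(ax_rev, -ax_fwd, atol=1e-9)

    def test_equivariance_under_rotation(self):
        coords = ideal_helix()
        ax0, _ = geo.helix_axis(coords)
        R = Rotation.from_euler("xyz", [20, -35, 70], degrees=True).as_matrix()
        ax_rot, _ = geo.helix_axis(coords @ R.T)
        np.testing.assert_allclose(ax_rot, R @ ax0, atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="4"):
            geo.helix_axis(ideal_helix(3))


class TestABAngle:
    @pytest.mark.parametrize("angle", [90.0, 110.0])
    def test_constructed_fixture(self, angle):
        ens = synth.gen_two_helix_ensemble(
            synth.AngleDistSpec(components=((angle, 0.0, 1.0),), n_models=1), seed=0)
        assert geo.ab_angle(ens, 0) == pytest.approx(angle, abs=0.5)

    def test_rigid_motion_invariance(self, rng):
        ens = synth.gen_two_helix_ensemble(
            synth.AngleDistSpec(components=((123.0, 0.0, 1.0),), n_models=1), seed=1)
        a0 = geo.ab_angle(ens, 0)
        R = Rotation.random(random_state=5).as_matrix()
        moved = StructureEnsemble(
            atoms=ens.atoms,
            coords=(ens.coords @ R.T) + np.array([13.0, -4.0, 99.0]),
        )
        assert geo.ab_angle(moved, 0) == pytest.approx(a0, abs=1e-6)

    def test_missing_residue_reported(self):
        ens = synth.gen_two_helix_ensemble(
            synth.AngleDistSpec(components=((100.0, 0.0, 1.0),), n_models=1), seed=0)
        trimmed = StructureEnsemble(
            atoms=ens.atoms[ens.atoms["resnum"] != 20].reset_index(drop=True),
            coords=ens.coords[:, (ens.atoms["resnum"] != 20).to_numpy()],
        )
        with pytest.raises(ValueError, match="20"):
            geo.ab_angle(trimmed, 0)


class TestOpenFraction:
    def test_all_below(self):
        assert geo.open_fraction([100.0] * 5)["fraction"] == 1.0

    def test_boundary_is_strict(self):
        assert geo.open_fraction([110.0] * 5)["fraction"] == 0.0

    def test_bimodal_matches_mixture_cdf(self):
        """For the (110, 5)/(150, 5) equal mixture the expected fraction
        below 110 is the mixture CDF there: 0.5*0.5 + 0.5*~0 = 0.25."""
        spec = synth.AngleDistSpec(
            components=((110.0, 5.0, 0.5), (150.0, 5.0, 0.5)), n_models=4000)
        ens = synth.gen_two_helix_ensemble(spec, seed=5)
        res = geo.open_fraction(geo.ensemble_ab_angles(ens), seed=1)
        assert res["ci"][0] <= 0.25 <= res["ci"][1]
        assert res["fraction"] == pytest.approx(0.25, abs=0.03)

    def test_per_replicate_fractions(self):
        angles = [100.0, 100.0, 120.0, 120.0]
        res = geo.open_fraction(angles, replicate_labels=["a", "a", "b", "b"])
        assert res["per_replicate"] == {"a": 1.0, "b": 0.0}


class TestRmsf:
    def _helix_ensemble(self, n_models, jitter=None):
        base = ideal_helix(20)
        resnums = list(range(1, 21))
        atoms = pd.DataFrame({"resnum": resnums, "resname": ["ALA"] * 20,
                              "atom": ["CA"] * 20, "chain": ["A"] * 20})
        coords = np.repeat(base[None], n_models, axis=0).astype(float)
        if jitter is not None:
            model, atom, d = jitter
            coords[model, atom, 0] += d
        return StructureEnsemble(atoms=atoms, coords=coords)

    def test_identical_models_zero(self):
        ens = self._helix_ensemble(5)
        assert geo.rmsf(ens, align_residues=range(1, 21), align_atoms=["CA"])["rmsf"].max() < 1e-12

    def test_rigid_rotations_removed_by_alignment(self):
        ens = self._helix_ensemble(4)
        coords = ens.coords.copy()
        for i in range(1, 4):
            R = Rotation.random(random_state=i).as_matrix()
            coords[i] = coords[i] @ R.T + i * 5.0
        moved = StructureEnsemble(atoms=ens.atoms, coords=coords)
        out = geo.rmsf(moved, align_residues=range(1, 21), align_atoms=["CA"])
        assert out["rmsf"].max() < 1e-9

    def test_single_jitter_closed_form(self):
        """One atom displaced by d in one model of N: fluctuation about the
        mean is d*sqrt((N-1)/N^2), provided the alignment selection excludes
        the jittered atom."""
        N, d = 5, 0.8
        ens = self._helix_ensemble(N, jitter=(2, 19, d))
        out = geo.rmsf(ens, align_residues=range(1, 19), align_atoms=["CA"])
        expected = d * np.sqrt((N - 1) / N**2)
        assert out.loc[out["resnum"] == 20, "rmsf"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert out.loc[out["resnum"] == 1, "rmsf"].iloc[0] < 1e-12

    def test_empty_alignment_selection(self):
        ens = self._helix_ensemble(3)
        with pytest.raises(ValueError, match="empty"):
            geo.rmsf(ens, align_residues=[99])


def brute_force_contacts(ens, model, atom_class, cutoff, min_sep):
    """Independent O(N^2) double-loop oracle over atoms."""
    found = {}
    atoms = ens.atoms
    for a in range(ens.n_atoms):
        for b in range(ens.n_atoms):
            na, nb = atoms["atom"].iloc[a], atoms["atom"].iloc[b]
            if atom_class == "calpha" and (na != "CA" or nb != "CA"):
                continue
            if atom_class == "heavy" and (na.startswith("H") or nb.startswith("H")):
                continue
            ri, rj = int(atoms["resnum"].iloc[a]), int(atoms["resnum"].iloc[b])
            if rj - ri < min_sep:
                continue
            dist = float(np.linalg.norm(ens.coords[model, a] - ens.coords[model, b]))
            if dist <= cutoff and ((ri, rj) not in found or dist < found[(ri, rj)]):
                found[(ri, rj)] = dist
    return found


class TestContactMap:
    def test_calpha_cutoff_inclusion(self):
        ens = make_toy_structure(n_res=10, seed=1, spread=50.0)
        coords = ens.coords.copy()
        coords[0, 0] = [0.0, 0.0, 0.0]
        coords[0, 7] = [4.9, 0.0, 0.0]
        ens2 = StructureEnsemble(atoms=ens.atoms, coords=coords)
        cm = geo.contact_map(ens2, mode="calpha-5A", model=0)
        assert (1, 8) in cm.pairs()

    def test_sequence_separation_rule(self):
        ens = make_toy_structure(n_res=10, atoms_per_res=2, seed=1, spread=50.0)
        coords = ens.coords.copy()
        coords[0, 0] = [0.0, 0.0, 0.0]   # res 1
        coords[0, 10] = [4.9, 0.0, 0.0]  # res 6: |i-j| = 5 < 6
        ens2 = StructureEnsemble(atoms=ens.atoms, coords=coords)
        cm = geo.contact_map(ens2, mode="heavy-7A-sep6", model=0)
        assert (1, 6) not in cm.pairs()

    @pytest.mark.parametrize("mode,atom_class,atoms_per_res", [
        ("calpha-5A", "calpha", 1),
        ("heavy-7A-sep6", "heavy", 3),
    ])
    def test_equals_brute_force_oracle(self, mode, atom_class, atoms_per_res):
        for seed in range(3):
            ens = make_toy_structure(n_res=40, atoms_per_res=atoms_per_res,
                                     seed=seed, spread=7.0)
            cm = geo.contact_map(ens, mode=mode, model=0)
            cutoff, min_sep = cm.cutoff, cm.min_sep
            oracle = brute_force_contacts(ens, 0, atom_class, cutoff, min_sep)
            assert cm.pairs() == set(oracle)
            got = {(int(r.i), int(r.j)): r.distance
                   for r in cm.contacts.itertuples(index=False)}
            for k, v in oracle.items():
                assert got[k] == pytest.approx(v, rel=1e-9)

    def test_unknown_mode(self):
        ens = make_toy_structure(n_res=5)
        with pytest.raises(ValueError, match="mode"):
            geo.contact_map(ens, mode="nope")


class TestDiffContactMap:
    def test_identical_maps_all_persistent(self):
        ens = make_toy_structure(n_res=30, seed=2, spread=6.0)
        cm = geo.contact_map(ens, mode="calpha-5A", model=0)
        d = geo.diff_contact_map(cm, cm)
        assert d["gained"] == [] and d["lost"] == []
        assert set(d["persistent"]) == cm.pairs()

    def test_engineered_toggle(self):
        ens = make_toy_structure(n_res=30, seed=2, spread=6.0)
        cm_a = geo.contact_map(ens, mode="calpha-5A", model=0)
        moved = ens.coords.copy()
        pair = sorted(cm_a.pairs())[0]
        idx = ens.atoms.index[ens.atoms["resnum"] == pair[0]][0]
        moved[0, idx] += 100.0  # break every contact of that residue
        cm_b = geo.contact_map(StructureEnsemble(atoms=ens.atoms, coords=moved),
                               mode="calpha-5A", model=0)
        d = geo.diff_contact_map(cm_a, cm_b)
        assert all(p[0] == pair[0] or p[1] == pair[0] for p in d["lost"])
        assert pair in d["lost"]

    def test_definition_mismatch(self):
        ens = make_toy_structure(n_res=30, atoms_per_res=2, seed=2)
        a = geo.contact_map(ens, mode="calpha-5A", model=0)
        b = geo.contact_map(ens, mode="heavy-7A-sep6", model=0)
        with pytest.raises(ValueError, match="definitions"):
            geo.diff_contact_map(a, b)


class TestPca:
    def _breathing_mode(self, n_models=12):
        """Models differing only by a uniform breathing (scaling) pattern —
        a single configuration-space direction that rigid-body superposition
        cannot remove."""
        base = ideal_helix(30)
        base = base - base.mean(axis=0)
        atoms = pd.DataFrame({"resnum": range(4, 34), "resname": ["ALA"] * 30,
                              "atom": ["CA"] * 30, "chain": ["A"] * 30})
        coords = np.stack([base * (1.0 + 0.005 * k) for k in range(n_models)])
        return StructureEnsemble(atoms=atoms, coords=coords)

    def test_single_mode_gives_pc1_everything(self):
        res = geo.pca(self._breathing_mode(), residues=range(4, 34),
                      align_residues=range(4, 34))
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_projections_centered_and_variance_sums(self, rng):
        ens = make_toy_structure(n_res=20, n_models=15, seed=4, spread=5.0)
        res = geo.pca(ens, residues=range(1, 21), align_residues=range(1, 21))
        np.testing.assert_allclose(res.projections.mean(axis=0), 0.0, atol=1e-9)
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_reconstruction_from_all_modes(self):
        ens = make_toy_structure(n_res=15, n_models=10, seed=5, spread=4.0)
        res = geo.pca(ens, residues=range(1, 16), align_residues=range(1, 16))
        recon = res.projections @ res.eigenvectors
        aligned = geo._kabsch_align(ens, ens.atom_mask(atom_names=["CA"]))
        X = aligned[:, ens.atom_mask(atom_names=["CA"])].reshape(10, -1)
        np.testing.assert_allclose(recon, X - X.mean(axis=0), atol=1e-9)

    def test_too_few_models(self):
        ens = make_toy_structure(n_res=10, n_models=2, seed=0)
        with pytest.raises(ValueError, match="3 models"):
            geo.pca(ens, residues=range(1, 11), align_residues=range(1, 11))


class TestFel:
    def test_uniform_flat(self):
        fel = geo.fel_1d(np.repeat(np.linspace(0, 1, 10), 20), bins=10)
        np.testing.assert_allclose(fel.delta_g[~np.isnan(fel.delta_g)], 0.0, atol=1e-12)

    def test_two_state_boltzmann_inversion(self):
        p = 0.8
        proj = np.concatenate([np.zeros(8000), np.ones(2000)])
        fel = geo.fel_1d(proj, bins=2)
        ddg = fel.delta_g[1] - fel.delta_g[0]
        assert ddg == pytest.approx(-np.log((1 - p) / p), rel=1e-9)

    def test_max_bin_zero_and_empty_masked(self):
        proj = np.concatenate([np.zeros(50), np.full(10, 5.0)])
        fel = geo.fel_1d(proj, bins=5)
        assert np.nanmin(fel.delta_g) == 0.0
        assert fel.delta_g[fel.counts.argmax()] == 0.0
        assert np.isnan(fel.delta_g[fel.counts == 0]).all()

    def test_bins_guard(self):
        with pytest.raises(ValueError, match="bins"):
            geo.fel_1d([0.0, 1.0], bins=1)


class TestWelchT:
    def test_identical_groups(self):
        t, p = geo.welch_t([0.4, 0.4, 0.4], [0.4, 0.4, 0.4])
        assert (t, p) == (0.0, 1.0)

    def test_textbook_case(self):
        """Equal-variance balanced case where Welch reduces to Student:
        t = -1.0, p = 0.3466 with 8 degrees of freedom."""
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 3.0, 4.0, 5.0, 6.0]
        t, p = geo.welch_t(a, b)
        assert t == pytest.approx(-1.0, abs=1e-12)
        assert p == pytest.approx(0.3466, abs=5e-4)

    def test_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 7)
        t1, p1 = geo.welch_t(a, b)
        t2, p2 = geo.welch_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)
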