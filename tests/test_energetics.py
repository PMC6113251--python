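"""MM terms, GB/SASA solvation, binding free energy, quasi-harmonic entropy."""

import numpy as np
import pandas as pd
import pytest

from allodyn.energetics import (
    COULOMB_CONSTANT,
    TERM_COLUMNS,
    alpha_for_sigma2,
    binding_free_energy,
    decompose_single_trajectory,
    mm_terms,
    mode_entropy,
    nonpolar_solvation,
    polar_solvation,
    quasiharmonic_entropy,
    read_term_table,
    write_term_table,
)
from allodyn.synthetic import generate_energy_tables
from allodyn.trajio import AtomSelection, Trajectory

from conftest import make_structure, make_trajectory, random_rotation

_R_KCAL = 1.987204259e-3


def charged_structure(coords, charges, radius=1.7, epsilon=0.0):
    s = make_structure(coords)
    for a, q in zip(s.atoms, charges):
        a.charge = q
        a.vdw_radius = radius
        a.lj_epsilon = epsilon
    return s


class TestMMTerms:
    def test_coulomb_pair_closed_form(self):
        coords = np.array([[0.0, 0, 0], [3.32, 0, 0]])
        s = charged_structure(coords, [1.0, 1.0])
        e_elec, e_vdw = mm_terms(coords, s, AtomSelection(indices=np.arange(2)))
        assert e_elec == pytest.approx(COULOMB_CONSTANT / 3.32, abs=1e-9)
        assert e_elec == pytest.approx(100.02, abs=0.01)
        assert e_vdw == 0.0

    def test_single_atom_subset_zero(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        s = charged_structure(coords, [1.0, -1.0])
        assert mm_terms(coords, s, AtomSelection(indices=np.array([0]))) == (0.0, 0.0)

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.normal(scale=4.0, size=(6, 3))
        charges = rng.uniform(-1, 1, 6)
        s = charged_structure(coords, charges, radius=1.9, epsilon=0.12)
        e_elec, e_vdw = mm_terms(coords, s, AtomSelection(indices=np.arange(6)))
        oe, ov = 0.0, 0.0
        for i in range(6):
            for j in range(i + 1, 6):
                r = np.linalg.norm(coords[i] - coords[j])
                oe += COULOMB_CONSTANT * charges[i] * charges[j] / r
                rmin = 1.9 + 1.9
                eps = np.sqrt(0.12 * 0.12)
                ov += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert e_elec == pytest.approx(oe, abs=1e-10)
        assert e_vdw == pytest.approx(ov, abs=1e-10)

    def test_overlapping_atoms_rejected(self):
        coords = np.zeros((2, 3))
        s = charged_structure(coords, [1.0, 1.0])
        with pytest.raises(ValueError, match="zero distance"):
            mm_terms(coords, s, AtomSelection(indices=np.arange(2)))


class TestSolvation:
    def test_nonpolar_single_sphere(self):
        coords = np.zeros((1, 3))
        s = charged_structure(coords, [0.0], radius=1.6)
        g = nonpolar_solvation(coords, s, AtomSelection(indices=np.array([0])))
        sphere = 4 * np.pi * 3.0**2
        assert g == pytest.approx(0.00542 * sphere + 0.92, rel=1e-3)
        assert g == pytest.approx(1.533, abs=0.002)

    def test_nonpolar_gamma_zero_gives_offset(self, rng):
        coords = rng.normal(scale=3.0, size=(4, 3))
        s = charged_structure(coords, [0.0] * 4)
        g = nonpolar_solvation(
            coords, s, AtomSelection(indices=np.arange(4)), gamma=0.0, b=0.92
        )
        assert g == 0.92

    def test_nonpolar_empty_subset_rejected(self):
        coords = np.zeros((1, 3))
        s = charged_structure(coords, [0.0])
        empty = AtomSelection(indices=np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            nonpolar_solvation(coords, s, empty)

    def test_born_ion_closed_form(self):
        coords = np.zeros((1, 3))
        s = charged_structure(coords, [1.0], radius=2.09)  # born radius 2.0
        g = polar_solvation(coords, s, AtomSelection(indices=np.array([0])))
        expected = -0.5 * (1 - 1 / 78.5) * COULOMB_CONSTANT / 2.0
        assert g == pytest.approx(expected, abs=1e-9)
        assert g == pytest.approx(-81.96, abs=0.01)

    def test_zero_charges_zero_energy(self, rng):
        coords = rng.normal(scale=3.0, size=(5, 3))
        s = charged_structure(coords, [0.0] * 5)
        assert polar_solvation(coords, s, AtomSelection(indices=np.arange(5))) == 0.0

    def test_two_charge_gb_matches_direct_formula(self):
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        s = charged_structure(coords, [0.6, -0.4], radius=1.8)
        sel = AtomSelection(indices=np.arange(2))
        g = polar_solvation(coords, s, sel)
        a = 1.8 - 0.09
        pref = -0.5 * (1 - 1 / 78.5) * COULOMB_CONSTANT
        r2 = 16.0
        f = np.sqrt(r2 + a * a * np.exp(-r2 / (4 * a * a)))
        oracle = pref * (0.6**2 / a + 0.4**2 / a + 2 * 0.6 * -0.4 / f)
        assert g == pytest.approx(oracle, abs=1e-10)

    def test_nonpositive_born_radius_rejected(self):
        coords = np.zeros((1, 3))
        s = charged_structure(coords, [1.0], radius=0.05)  # default offset -> <= 0
        with pytest.raises(ValueError, match="Born"):
            polar_solvation(coords, s, AtomSelection(indices=np.array([0])))


def two_fragment_trajectory(separation=5.0, n_frames=3, charges=(1.0, -1.0)):
    frames = np.zeros((n_frames, 2, 3))
    frames[:, 1, 0] = separation
    traj = make_trajectory(frames, chains=["R", "L"])
    for atom, q in zip(traj.structure.atoms, charges):
        atom.charge = q
        atom.vdw_radius = 1.7
        atom.lj_epsilon = 0.0
    return traj


def selections(traj):
    n = traj.n_atoms
    comp = AtomSelection(indices=np.arange(n))
    rec = AtomSelection(indices=np.array([0]))
    lig = AtomSelection(indices=np.arange(1, n))
    return comp, rec, lig


class TestDecomposition:
    def test_empty_ligand_rejected(self):
        traj = two_fragment_trajectory()
        comp, rec, _ = selections(traj)
        empty = AtomSelection(indices=np.array([], dtype=int))
        with pytest.raises(ValueError, match="non-empty"):
            decompose_single_trajectory(traj, comp, comp, empty)

    def test_overlapping_subsets_rejected(self):
        traj = two_fragment_trajectory()
        comp, rec, lig = selections(traj)
        with pytest.raises(ValueError, match="overlap"):
            decompose_single_trajectory(traj, comp, comp, lig)

    def test_bonded_difference_identically_zero(self):
        traj = two_fragment_trajectory()
        comp, rec, lig = selections(traj)
        decomp = decompose_single_trajectory(traj, comp, rec, lig)
        bfe = binding_free_energy(decomp)
        mean, std = bfe.terms["dE_bonded"]
        assert mean == 0.0 and std == 0.0

    def test_table_mode_means_are_hand_averages(self, tmp_path):
        rows = {
            "frame": range(5),
            "E_bonded": [1.0, 1.0, 1.0, 1.0, 1.0],
            "E_elec": [-10.0, -12.0, -8.0, -11.0, -9.0],
            "E_vdw": [-1.0, -2.0, -3.0, -4.0, -5.0],
            "G_polar": [20.0, 21.0, 19.0, 22.0, 18.0],
            "G_np": [0.5, 0.5, 0.5, 0.5, 0.5],
        }
        df = pd.DataFrame(rows)
        p = tmp_path / "t.txt"
        write_term_table(df, p)
        back = read_term_table(p)
        traj = two_fragment_trajectory(n_frames=5)
        comp, rec, lig = selections(traj)
        decomp = decompose_single_trajectory(
            traj, comp, rec, lig, term_source="table",
            tables={"complex": back, "receptor": back, "ligand": back},
        )
        assert decomp["complex"].mean()["E_elec"] == pytest.approx(-10.0)
        assert decomp["complex"].std()["E_vdw"] == pytest.approx(
            np.std([-1, -2, -3, -4, -5], ddof=1)
        )

    def test_interaction_energy_identity(self, rng):
        """dE_elec + dE_vdw equals the receptor–ligand inter-fragment energy:
        every intra-fragment pair term cancels in the difference."""
        n_r, n_l = 3, 4
        coords = np.vstack(
            [rng.normal(scale=2.0, size=(n_r, 3)),
             np.array([12.0, 0, 0]) + rng.normal(scale=2.0, size=(n_l, 3))]
        )
        frames = coords[None]
        traj = make_trajectory(frames, chains=["R"] * n_r + ["L"] * n_l)
        charges = rng.uniform(-0.5, 0.5, n_r + n_l)
        for atom, q in zip(traj.structure.atoms, charges):
            atom.charge, atom.vdw_radius, atom.lj_epsilon = q, 1.8, 0.1
        comp = AtomSelection(indices=np.arange(n_r + n_l))
        rec = AtomSelection(indices=np.arange(n_r))
        lig = AtomSelection(indices=np.arange(n_r, n_r + n_l))
        decomp = decompose_single_trajectory(traj, comp, rec, lig)
        bfe = binding_free_energy(decomp)
        inter_e = inter_v = 0.0
        for i in range(n_r):
            for j in range(n_r, n_r + n_l):
                r = np.linalg.norm(coords[i] - coords[j])
                inter_e += COULOMB_CONSTANT * charges[i] * charges[j] / r
                rmin, eps = 3.6, 0.1
                inter_v += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert bfe.terms["dE_elec"][0] + bfe.terms["dE_vdw"][0] == pytest.approx(
            inter_e + inter_v, abs=1e-9
        )

    def test_two_charge_binding_electrostatics(self):
        traj = two_fragment_trajectory(separation=5.0)
        comp, rec, lig = selections(traj)
        decomp = decompose_single_trajectory(traj, comp, rec, lig)
        bfe = binding_free_energy(decomp)
        assert bfe.terms["dE_elec"][0] == pytest.approx(-COULOMB_CONSTANT / 5.0, abs=1e-9)
        assert bfe.terms["dE_elec"][0] == pytest.approx(-66.41, abs=0.01)

    def test_noninteracting_limit_binds_nothing(self):
        # neutral atoms, LJ off, b=0: every term's difference vanishes
        traj = two_fragment_trajectory(separation=500.0, charges=(0.0, 0.0))
        comp, rec, lig = selections(traj)
        decomp = decompose_single_trajectory(traj, comp, rec, lig, b=0.0)
        bfe = binding_free_energy(decomp)
        assert bfe.dG_bind == pytest.approx(0.0, abs=1e-6)


class TestBindingFreeEnergy:
    def test_synthetic_table_matches_spreadsheet_oracle(self):
        tables, analytic = generate_energy_tables(
            100, seed=6,
            delta_means={"E_elec": -40.0, "G_polar": 35.0, "G_np": -1.0},
            delta_stds={"E_elec": 3.0, "G_polar": 2.0},
        )
        traj = two_fragment_trajectory(n_frames=100)
        comp, rec, lig = selections(traj)
        decomp = decompose_single_trajectory(
            traj, comp, rec, lig, term_source="table", tables=tables
        )
        bfe = binding_free_energy(decomp)
        # independent aggregation of the same tables
        dg = (
            tables["complex"][TERM_COLUMNS].sum(axis=1)
            - tables["receptor"][TERM_COLUMNS].sum(axis=1)
            - tables["ligand"][TERM_COLUMNS].sum(axis=1)
        )
        assert bfe.dG_bind == pytest.approx(dg.mean(), abs=1e-12)
        assert bfe.dG_bind_std == pytest.approx(dg.std(ddof=1), abs=1e-12)

    def test_std_from_delta_series_not_quadrature(self):
        """Correlated subset fluctuations must cancel in the Δ-series std."""
        n = 50
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 10.0, n)  # huge common-mode noise
        base = {c: np.zeros(n) for c in TERM_COLUMNS}
        mk = lambda off: pd.DataFrame(
            {"frame": range(n), **{c: base[c] + noise + off for c in TERM_COLUMNS}}
        )
        tables = {"complex": mk(0.0), "receptor": mk(0.0), "ligand": mk(0.0)}
        # Δ per frame = 0 - noise... complex - rec - lig = -noise - 0 offsets
        traj = two_fragment_trajectory(n_frames=n)
        comp, rec, lig = selections(traj)
        decomp = decompose_single_trajectory(
            traj, comp, rec, lig, term_source="table", tables=tables
        )
        bfe = binding_free_energy(decomp)
        delta = -(noise)  # complex - (rec + lig), per column, equals -noise
        expected_std = np.std(5 * delta, ddof=1)  # 5 terms summed into dG
        assert bfe.dG_bind_std == pytest.approx(expected_std, rel=1e-10)
        # quadrature over subset stds would be ~sqrt(3)*5*std(noise) instead
        quadrature = np.sqrt(3) * 5 * np.std(noise, ddof=1)
        assert abs(bfe.dG_bind_std - quadrature) > 1.0

    def test_window_mismatch_rejected(self):
        traj = two_fragment_trajectory(n_frames=4)
        comp, rec, lig = selections(traj)
        d1 = decompose_single_trajectory(traj, comp, rec, lig, window=(0, 4))
        d2 = decompose_single_trajectory(traj, comp, rec, lig, window=(0, 3))
        mixed = {"complex": d1["complex"], "receptor": d2["receptor"],
                 "ligand": d1["ligand"]}
        with pytest.raises(ValueError, match="window"):
            binding_free_energy(mixed)

    def test_constant_delta_reproduced_exactly(self):
        tables, analytic = generate_energy_tables(
            20, seed=1, delta_means={"E_elec": -5.0}
        )
        traj = two_fragment_trajectory(n_frames=20)
        comp, rec, lig = selections(traj)
        decomp = decompose_single_trajectory(
            traj, comp, rec, lig, term_source="table", tables=tables
        )
        bfe = binding_free_energy(decomp)
        assert bfe.dG_bind == pytest.approx(-5.0, abs=1e-9)
        assert bfe.dG_bind_std == pytest.approx(0.0, abs=1e-9)


class TestQuasiharmonicEntropy:
    def test_static_trajectory_zero_entropy(self):
        frame = np.arange(9, dtype=float).reshape(3, 3)
        traj = make_trajectory(np.repeat(frame[None], 10, axis=0))
        res = quasiharmonic_entropy(traj, n_exclude=0)
        assert res.S_conf == 0.0

    def test_single_mode_alpha_one_closed_form(self):
        """A single fluctuating coordinate with hw = k_B*T contributes
        1/(e-1) - ln(1 - 1/e) = 1.04066 k_B of entropy."""
        # find sigma2 (amu*Å²) with alpha = 1, then plant it exactly:
        # population std s over frames [+s, -s, +s, ...]
        from scipy.optimize import brentq

        sigma2 = brentq(lambda s2: alpha_for_sigma2(s2) - 1.0, 1e-8, 1e2)
        mass = 12.011
        s = np.sqrt(sigma2 / mass)
        frames = np.zeros((10, 1, 3))
        frames[:, 0, 0] = s * np.array([1, -1] * 5)
        traj = make_trajectory(frames)
        res = quasiharmonic_entropy(traj, n_exclude=0)
        exact = 1.0 / (np.e - 1.0) - np.log(1.0 - np.exp(-1.0))
        assert res.S_conf / _R_KCAL == pytest.approx(exact, abs=1e-4)
        assert mode_entropy(1.0) == pytest.approx(exact, abs=1e-12)

    def test_monotone_in_fluctuation_amplitude(self, rng):
        base = 10.0 * np.eye(3)
        disp = rng.normal(size=(400, 3, 3))
        s1 = quasiharmonic_entropy(
            make_trajectory(base[None] + 0.3 * disp), n_exclude=0
        ).S_conf
        s2 = quasiharmonic_entropy(
            make_trajectory(base[None] + 0.6 * disp), n_exclude=0
        ).S_conf
        assert s2 > s1 > 0

    def test_invariant_under_rigid_rotation(self, rng):
        base = 10.0 * rng.normal(size=(4, 3))
        frames = base[None] + 0.4 * rng.normal(size=(200, 4, 3))
        s_ref = quasiharmonic_entropy(make_trajectory(frames)).S_conf
        q = random_rotation(rng)
        s_rot = quasiharmonic_entropy(make_trajectory(frames @ q.T)).S_conf
        assert s_rot == pytest.approx(s_ref, rel=1e-9)

    def test_additive_over_independent_blocks(self, rng):
        da = rng.normal(size=(300, 2, 3))
        db = rng.normal(size=(300, 2, 3))
        # orthogonalize in frame space so the sample cross-covariance between
        # the two blocks is exactly zero (true independence at finite n)
        fa = da.reshape(300, 6) - da.reshape(300, 6).mean(axis=0)
        fb = db.reshape(300, 6) - db.reshape(300, 6).mean(axis=0)
        qa, _ = np.linalg.qr(fa)
        fb = fb - qa @ (qa.T @ fb)
        da, db = fa.reshape(300, 2, 3), fb.reshape(300, 2, 3)
        base_a = np.zeros((2, 3))
        base_b = np.full((2, 3), 50.0)
        sa = quasiharmonic_entropy(
            make_trajectory(base_a[None] + 0.3 * da), n_exclude=0
        ).S_conf
        sb = quasiharmonic_entropy(
            make_trajectory(base_b[None] + 0.5 * db), n_exclude=0
        ).S_conf
        joint_frames = np.concatenate(
            [base_a[None] + 0.3 * da, base_b[None] + 0.5 * db], axis=1
        )
        s_joint = quasiharmonic_entropy(
            make_trajectory(joint_frames), n_exclude=0
        ).S_conf
        assert s_joint == pytest.approx(sa + sb, rel=1e-9)

    def test_schlitter_bounds_from_above(self, rng):
        frames = 10.0 * np.eye(3)[None] + 0.4 * rng.normal(size=(300, 3, 3))
        traj = make_trajectory(frames)
        ak = quasiharmonic_entropy(traj, n_exclude=0).S_conf
        sch = quasiharmonic_entropy(traj, n_exclude=0, method="schlitter").S_conf
        assert sch >= ak
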