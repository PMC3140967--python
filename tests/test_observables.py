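import numpy as np
import pytest
from scipy import constants

from inmkit import (
    Trajectory, backbone_dihedrals, build_covariance, dihedral_density,
    make_backbone_chain, region_entropy, sample_gaussian_ensemble, sasa,
    sasa_profile, schlitter_entropy,
)
from inmkit.observables import CovarianceModel, dihedral_angles
from inmkit.structures import Structure
from tests.conftest import random_rotation


def _ca_structure(n, spacing=3.8):
    # zigzag, not collinear, so rigid alignment is well posed
    i = np.arange(n)
    coords = np.column_stack((spacing * i, 1.5 * (i % 2), 0.7 * (i % 3)))
    return Structure(
        names=np.array(["CA"] * n), elements=np.array(["C"] * n),
        resids=np.arange(1, n + 1), icodes=np.array([""] * n),
        resnames=np.array(["GLY"] * n), chains=np.array(["A"] * n),
        coords=coords, masses=np.full(n, 12.011),
    )


def _schlitter_oracle(sigma_A2, masses_amu, temperature):
    """Independent route: slogdet of (1 + alpha * M * sigma), molar J/mol/K."""
    m = np.repeat(np.asarray(masses_amu) * constants.atomic_mass, 3)
    alpha = constants.k * temperature * np.e ** 2 / constants.hbar ** 2
    mat = np.eye(len(m)) + alpha * (m[:, None] * (sigma_A2 * 1e-20))
    sign, logdet = np.linalg.slogdet(mat)
    assert sign > 0
    return 0.5 * constants.R * logdet


class TestBuildCovariance:
    def test_identical_frames_zero_sigma(self):
        s = _ca_structure(5)
        traj = Trajectory(topology=s,
                          frames=np.repeat(s.coords[None], 4, axis=0),
                          times=np.arange(4.0))
        cov = build_covariance(traj, atom_names=("CA",))
        np.testing.assert_allclose(cov.sigma, 0.0, atol=1e-12)

    def test_two_frame_one_atom_unit_variance(self):
        s = _ca_structure(1)
        frames = np.array([[[1.0, 0.0, 0.0]], [[-1.0, 0.0, 0.0]]])
        traj = Trajectory(topology=s, frames=frames, times=np.arange(2.0))
        cov = build_covariance(traj, atom_names=("CA",), align=False)
        # 1/n convention: mean 0, var = (1 + 1)/2 = 1 Å²
        assert cov.sigma[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_recovers_generator_and_matches_two_pass_oracle(self, rng):
        s = _ca_structure(3)
        a = rng.normal(0, 0.4, size=(9, 9))
        gen = a @ a.T + 0.5 * np.eye(9)
        traj = sample_gaussian_ensemble(s, gen, 500, seed=11)
        cov = build_covariance(traj, atom_names=("CA",), align=False)
        # elementwise: 15% relative on variances, 15% of the largest
        # variance as absolute bound elsewhere
        diag = np.diag(gen)
        np.testing.assert_allclose(np.diag(cov.sigma), diag, rtol=0.15)
        np.testing.assert_allclose(cov.sigma, gen,
                                   atol=0.15 * diag.max())
        # exact agreement with a naive two-pass summation oracle
        flat = traj.frames.reshape(500, -1)
        mean = flat.mean(axis=0)
        oracle = np.zeros((9, 9))
        for row in flat:
            d = row - mean
            oracle += np.outer(d, d)
        oracle /= 500
        np.testing.assert_allclose(cov.sigma, oracle, atol=1e-10)

    def test_needs_two_frames(self):
        s = _ca_structure(4)
        traj = Trajectory(topology=s, frames=s.coords[None],
                          times=np.array([0.0]))
        with pytest.raises(ValueError, match="2 frames"):
            build_covariance(traj, atom_names=("CA",))


class TestSchlitterEntropy:
    def test_zero_covariance_zero_entropy(self):
        s = _ca_structure(2)
        cov = CovarianceModel(mean_coords=s.coords, sigma=np.zeros((6, 6)),
                              masses=s.masses, temperature=300.0, n_frames=10)
        assert schlitter_entropy(cov) == 0.0

    @pytest.mark.parametrize("wavenumber_cm", [1.0, 10.0, 100.0, 1000.0])
    def test_scalar_closed_form(self, wavenumber_cm):
        # one harmonic dof: variance kBT/(m Ω²) gives
        # S = (kB/2) ln(1 + (e kBT / ħΩ)²) per dof, molar here
        t = 300.0
        m_amu = 12.011
        m = m_amu * constants.atomic_mass
        omega = 2 * np.pi * constants.c * wavenumber_cm * 100.0
        var_m2 = constants.k * t / (m * omega ** 2)
        sigma = np.zeros((3, 3))
        sigma[0, 0] = var_m2 / 1e-20       # Å²
        s1 = _ca_structure(1)
        cov = CovarianceModel(mean_coords=s1.coords, sigma=sigma,
                              masses=np.array([m_amu]), temperature=t,
                              n_frames=100)
        expect = 0.5 * constants.R * np.log1p(
            (np.e * constants.k * t / (constants.hbar * omega)) ** 2)
        assert schlitter_entropy(cov) == pytest.approx(expect, rel=1e-10)

    def test_gaussian_ensemble_matches_generator_truth(self, rng):
        s = _ca_structure(3)
        a = rng.normal(0, 0.3, size=(9, 9))
        gen = a @ a.T + 0.2 * np.eye(9)
        traj = sample_gaussian_ensemble(s, gen, 5000, seed=21)
        cov = build_covariance(traj, atom_names=("CA",), align=False)
        est = schlitter_entropy(cov)
        truth = _schlitter_oracle(gen, s.masses, 300.0)
        assert est == pytest.approx(truth, rel=0.05)

    def test_units_kj(self):
        s = _ca_structure(2)
        sigma = 0.5 * np.eye(6)
        cov = CovarianceModel(mean_coords=s.coords, sigma=sigma,
                              masses=s.masses, temperature=300.0,
                              n_frames=10)
        j = schlitter_entropy(cov, units="J/mol/K")
        kj = schlitter_entropy(cov, units="kJ/mol/K")
        assert kj == pytest.approx(j / 1000.0)
        with pytest.raises(ValueError, match="units"):
            schlitter_entropy(cov, units="cal")

    def test_non_psd_rejected(self):
        s = _ca_structure(1)
        sigma = np.diag([1.0, -0.5, 1.0])
        cov = CovarianceModel(mean_coords=s.coords, sigma=sigma,
                              masses=s.masses, temperature=300.0,
                              n_frames=10)
        with pytest.raises(ValueError, match="positive semidefinite"):
            schlitter_entropy(cov)

    def test_upper_bound_and_scaling_monotonicity(self, rng):
        s = _ca_structure(3)
        a = rng.normal(0, 0.3, size=(9, 9))
        gen = a @ a.T + 0.2 * np.eye(9)
        traj = sample_gaussian_ensemble(s, gen, 4000, seed=5)
        est = schlitter_entropy(
            build_covariance(traj, atom_names=("CA",), align=False))
        truth = _schlitter_oracle(gen, s.masses, 300.0)
        assert est >= 0.99 * truth
        # ln det is monotone under uniform covariance scaling
        def entropy_of(scale):
            cov = CovarianceModel(mean_coords=s.coords, sigma=scale * gen,
                                  masses=s.masses, temperature=300.0,
                                  n_frames=10)
            return schlitter_entropy(cov)
        assert entropy_of(2.0) > entropy_of(1.0) > entropy_of(0.5)


class TestRegionEntropy:
    def test_rigid_trajectory_all_zero(self):
        s = make_backbone_chain([-57.0] * 12, [-47.0] * 12)
        traj = Trajectory(topology=s,
                          frames=np.repeat(s.coords[None], 6, axis=0),
                          times=np.arange(6.0))
        rep = region_entropy(traj, {"a": [(1, 6)], "b": [(7, 12)]},
                             n_blocks=2)
        for row in rep.rows:
            assert row["per_atom_entropy"] == pytest.approx(0.0, abs=1e-12)
            assert row["block_std"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_regions_identical_values(self, rng):
        s = make_backbone_chain([-57.0] * 10, [-47.0] * 10)
        gen = 0.05 * np.eye(3 * s.n_atoms)
        traj = sample_gaussian_ensemble(s, gen, 60, seed=3)
        rep = region_entropy(traj, {"first": [(1, 10)], "again": [(1, 10)]},
                             n_blocks=2)
        assert rep.rows[0]["per_atom_entropy"] == pytest.approx(
            rep.rows[1]["per_atom_entropy"])

    def test_flexible_region_has_higher_per_atom_entropy(self, rng):
        s = make_backbone_chain([-57.0] * 20, [-47.0] * 20)
        var = np.full(3 * s.n_atoms, 0.05)
        loop_atoms = (s.resids >= 11)
        var[np.repeat(loop_atoms, 3)] = 0.20      # 4x positional variance
        traj = sample_gaussian_ensemble(s, np.diag(var), 300, seed=8)
        rep = region_entropy(traj, {"cleft": [(1, 10)], "loop": [(11, 20)]},
                             n_blocks=3)
        by_name = {r["region"]: r for r in rep.rows}
        assert (by_name["loop"]["per_atom_entropy"] >
                by_name["cleft"]["per_atom_entropy"])

    def test_superposition_invariance(self, rng):
        s = make_backbone_chain([-57.0] * 8, [-47.0] * 8)
        gen = 0.04 * np.eye(3 * s.n_atoms)
        traj = sample_gaussian_ensemble(s, gen, 40, seed=13)
        rot = random_rotation(rng)
        rotated = Trajectory(topology=s,
                             frames=traj.frames @ rot.T + np.array(
                                 [3.0, -2.0, 1.0]),
                             times=traj.times)
        r1 = region_entropy(traj, {"all": [(1, 8)]}, n_blocks=2)
        r2 = region_entropy(rotated, {"all": [(1, 8)]}, n_blocks=2)
        assert abs(r1.rows[0]["per_atom_entropy"] -
                   r2.rows[0]["per_atom_entropy"]) < 1e-6

    def test_empty_region_is_error(self):
        s = make_backbone_chain([-57.0] * 5, [-47.0] * 5)
        traj = Trajectory(topology=s,
                          frames=np.repeat(s.coords[None], 4, axis=0),
                          times=np.arange(4.0))
        with pytest.raises(Exception, match="no atoms|selects"):
            region_entropy(traj, {"ghost": [(100, 120)]}, n_blocks=2)


class TestSasa:
    def test_isolated_sphere(self):
        s = _ca_structure(1)
        area = sasa(s, probe=1.4, n_points=960)[0]
        expect = 4 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(expect, rel=0.01)

    def test_distant_atoms_additive(self):
        s = _ca_structure(2, spacing=100.0)
        areas = sasa(s, probe=1.4, n_points=960)
        expect = 4 * np.pi * (1.7 + 1.4) ** 2
        np.testing.assert_allclose(areas, expect, rtol=0.01)

    def test_caged_atom_buried(self):
        phi = (1 + np.sqrt(5)) / 2
        verts = np.array([
            [0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
            [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
            [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1],
        ], dtype=float)
        verts *= 2.5 / np.linalg.norm(verts[0])
        coords = np.vstack([[0.0, 0.0, 0.0], verts])
        n = len(coords)
        s = Structure(
            names=np.array(["CA"] * n), elements=np.array(["C"] * n),
            resids=np.arange(1, n + 1), icodes=np.array([""] * n),
            resnames=np.array(["GLY"] * n), chains=np.array(["A"] * n),
            coords=coords, masses=np.full(n, 12.011),
        )
        coarse = sasa(s, n_points=960)
        fine = sasa(s, n_points=9600)      # 10x denser quadrature oracle
        isolated = 4 * np.pi * (1.7 + 1.4) ** 2
        assert coarse[0] < 0.01 * isolated
        assert abs(coarse[0] - fine[0]) < 0.5

    def test_missing_radius_names_element(self):
        s = _ca_structure(1)
        s.elements = np.array(["FE"])
        with pytest.raises(ValueError, match="FE"):
            sasa(s)

    def test_point_count_floor(self):
        with pytest.raises(ValueError, match="100"):
            sasa(_ca_structure(1), n_points=50)


class TestSasaProfile:
    def test_single_frame_std_zero(self):
        s = make_backbone_chain([-57.0] * 6, [-47.0] * 6)
        traj = Trajectory(topology=s, frames=s.coords[None],
                          times=np.array([0.0]))
        prof = sasa_profile(traj, (1, 6), n_points=240)
        np.testing.assert_array_equal(prof.std, 0.0)

    def test_released_domain_more_exposed(self):
        helix = make_backbone_chain([-57.0] * 16, [-47.0] * 16)
        bound = helix
        released_coords = helix.coords.copy()
        moving = np.repeat(helix.resids > 8, 1)
        released_coords[helix.resids > 8] += np.array([20.0, 0.0, 0.0])
        released = helix.copy_with_coords(released_coords)
        p_bound = sasa_profile(
            Trajectory(topology=bound, frames=bound.coords[None],
                       times=np.array([0.0])), (7, 10), n_points=240)
        p_rel = sasa_profile(
            Trajectory(topology=released, frames=released.coords[None],
                       times=np.array([0.0])), (7, 10), n_points=240)
        # interface residues straddling the break gain exposure
        assert np.all(p_rel.mean >= p_bound.mean)
        assert p_rel.mean.sum() > p_bound.mean.sum() + 10.0
        _ = moving

    def test_duplicated_frames_invariant(self, rng):
        s = make_backbone_chain([-57.0] * 6, [-47.0] * 6)
        frames = s.coords[None] + rng.normal(0, 0.1, size=(3, s.n_atoms, 3))
        base = Trajectory(topology=s, frames=frames, times=np.arange(3.0))
        doubled = Trajectory(topology=s,
                             frames=np.repeat(frames, 2, axis=0),
                             times=np.arange(6.0))
        p1 = sasa_profile(base, (1, 6), n_points=240)
        p2 = sasa_profile(doubled, (1, 6), n_points=240)
        np.testing.assert_allclose(p1.mean, p2.mean, atol=1e-10)
        np.testing.assert_allclose(p1.std, p2.std, atol=1e-10)

    def test_conservation_residue_vs_atom_sums(self):
        s = make_backbone_chain([-57.0] * 8, [-47.0] * 8)
        traj = Trajectory(topology=s, frames=s.coords[None],
                          times=np.array([0.0]))
        prof = sasa_profile(traj, (1, 8), n_points=240)
        atom_total = sasa(s, n_points=240).sum()
        assert prof.mean.sum() == pytest.approx(atom_total, abs=1e-8)


def _torsion_oracle(p0, p1, p2, p3):
    """Normal-vector atan2 formulation (independent of the package's)."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    ang = np.degrees(np.arctan2(
        np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)), n1 @ n2))
    return ang + 360.0 if ang <= -180.0 else ang


class TestBackboneDihedrals:
    def test_alpha_helix_angles(self):
        s = make_backbone_chain([-57.0] * 8, [-47.0] * 8)
        traj = Trajectory(topology=s, frames=s.coords[None],
                          times=np.array([0.0]))
        series = backbone_dihedrals(traj, list(range(2, 8)))
        np.testing.assert_allclose(series.phi[0], -57.0, atol=2.0)
        np.testing.assert_allclose(series.psi[0], -47.0, atol=2.0)

    def test_trans_zigzag_is_180(self):
        s = make_backbone_chain([180.0] * 6, [180.0] * 6)
        traj = Trajectory(topology=s, frames=s.coords[None],
                          times=np.array([0.0]))
        series = backbone_dihedrals(traj, [2, 3, 4, 5])
        np.testing.assert_allclose(np.abs(series.phi[0]), 180.0, atol=1e-6)
        np.testing.assert_allclose(np.abs(series.psi[0]), 180.0, atol=1e-6)

    def test_terminal_residues_partial(self):
        s = make_backbone_chain([-57.0] * 5, [-47.0] * 5)
        traj = Trajectory(topology=s, frames=s.coords[None],
                          times=np.array([0.0]))
        series = backbone_dihedrals(traj, [1, 5])
        assert np.isnan(series.phi[0, 0])        # first residue: no phi
        assert not np.isnan(series.psi[0, 0])
        assert np.isnan(series.psi[0, 1])        # last residue: no psi
        assert not np.isnan(series.phi[0, 1])

    def test_missing_residue_recorded(self):
        s = make_backbone_chain([-57.0] * 5, [-47.0] * 5)
        traj = Trajectory(topology=s, frames=s.coords[None],
                          times=np.array([0.0]))
        series = backbone_dihedrals(traj, [3, 99])
        assert 99 in series.omitted

    def test_random_conformer_matches_atan2_oracle(self, rng):
        coords = rng.normal(0, 3, size=(15, 3))
        s = make_backbone_chain([-57.0] * 5, [-47.0] * 5)
        s = s.copy_with_coords(coords)
        traj = Trajectory(topology=s, frames=coords[None],
                          times=np.array([0.0]))
        series = backbone_dihedrals(traj, [2, 3, 4])
        for k, r in enumerate([2, 3, 4]):
            i = 3 * (r - 1)
            phi_oracle = _torsion_oracle(coords[i - 1], coords[i],
                                         coords[i + 1], coords[i + 2])
            psi_oracle = _torsion_oracle(coords[i], coords[i + 1],
                                         coords[i + 2], coords[i + 3])
            assert series.phi[0, k] == pytest.approx(phi_oracle, abs=1e-8)
            assert series.psi[0, k] == pytest.approx(psi_oracle, abs=1e-8)


class TestDihedralDensity:
    def _series(self, phi_vals, psi_vals):
        from inmkit.observables import DihedralSeries
        f = len(phi_vals)
        return DihedralSeries(resids=[1],
                              phi=np.asarray(phi_vals, float).reshape(f, 1),
                              psi=np.asarray(psi_vals, float).reshape(f, 1))

    def test_single_frame_single_bin(self):
        d = dihedral_density(self._series([-57.0], [-47.0]), bins=36)
        h = d[1]
        assert h.sum() == pytest.approx(1.0)
        assert np.count_nonzero(h) == 1

    def test_wraparound_adjacent_bins(self):
        d = dihedral_density(self._series([179.9, -179.9], [0.0, 0.0]),
                             bins=36)
        h = d[1]
        assert h.sum() == pytest.approx(1.0)   # nothing dropped
        occupied = np.nonzero(h)[0]
        assert set(occupied) == {0, 35}        # periodic neighbors

    def test_bimodal_clusters_two_maxima(self, rng):
        c1 = (-60.0, -45.0)
        c2 = (60.0, 45.0)
        phi = np.concatenate([rng.normal(c1[0], 5, 2000),
                              rng.normal(c2[0], 5, 2000)])
        psi = np.concatenate([rng.normal(c1[1], 5, 2000),
                              rng.normal(c2[1], 5, 2000)])
        bins = 36
        d = dihedral_density(self._series(phi, psi), bins=bins)
        h = d[1]
        peaks = []
        for i in range(bins):
            for j in range(bins):
                if h[i, j] < 0.01:
                    continue
                nb = [h[(i + di) % bins, (j + dj) % bins]
                      for di in (-1, 0, 1) for dj in (-1, 0, 1)
                      if (di, dj) != (0, 0)]
                if h[i, j] > max(nb):
                    peaks.append((i, j))
        assert len(peaks) == 2
        centers = sorted(
            ((edge_center(d["edges"], i), edge_center(d["edges"], j))
             for i, j in peaks))
        for got, expect in zip(centers, sorted([c1, c2])):
            assert abs(got[0] - expect[0]) <= 10.0
            assert abs(got[1] - expect[1]) <= 10.0

    def test_frame_order_invariance(self, rng):
        phi = rng.uniform(-180, 180, 50)
        psi = rng.uniform(-180, 180, 50)
        d1 = dihedral_density(self._series(phi, psi), bins=18)
        perm = rng.permutation(50)
        d2 = dihedral_density(self._series(phi[perm], psi[perm]), bins=18)
        np.testing.assert_array_equal(d1[1], d2[1])


def edge_center(edges, idx):
    return 0.5 * (edges[idx] + edges[idx + 1])
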