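"""Potential models, valid-point selection, grid metrics, and cube I/O."""

import numpy as np
import pytest
from scipy.integrate import quad as scipy_quad

from qdrcharges import (
    AtomSite,
    Cell,
    FixtureSpec,
    PotentialGrid,
    StockholderPartition,
    esp_metrics,
    make_fixture,
    make_oracle_grids,
    model_potential,
    read_cube,
    valid_grid_mask,
    write_cube,
)
from qdrcharges.constants import ANGSTROM_TO_BOHR, HARTREE_TO_KCAL_PER_MOL
from qdrcharges.errors import ValidationError


def _single_charge(q=1.0):
    atoms = [AtomSite(index=0, element=1, position=np.zeros(3), charge=q)]
    return StockholderPartition(atoms=atoms, net_charge=q)


class TestModelPotential:
    def test_coulomb_law(self):
        part = _single_charge(1.0)
        v = model_potential(part, np.array([[1.0, 0.0, 0.0]]))
        assert v[0] == pytest.approx(1.0, abs=1e-14)
        v_kcal = model_potential(part, np.array([[1.0, 0.0, 0.0]]), units="kcal/mol/e")
        assert v_kcal[0] == pytest.approx(HARTREE_TO_KCAL_PER_MOL, rel=1e-12)

    def test_dipole_antisymmetry(self):
        atoms = [AtomSite(index=0, element=1, position=np.zeros(3), charge=0.0,
                          dipole=[0.0, 0.0, 0.7])]
        part = StockholderPartition(atoms=atoms)
        pts = np.array([[0.0, 0.0, 3.0], [0.0, 0.0, -3.0]])
        v = model_potential(part, pts, terms=("atomic_dipoles",))
        assert v[0] == pytest.approx(-v[1], abs=1e-14)
        assert v[0] == pytest.approx(0.7 / 9.0, abs=1e-14)

    def test_cloud_potential_matches_radial_integration_oracle(self):
        a_cloud, b_cloud = 2.2, 2.0
        atoms = [AtomSite(index=0, element=6, position=np.zeros(3), charge=0.0,
                          cloud_a=a_cloud, cloud_b=b_cloud)]
        part = StockholderPartition(atoms=atoms)
        n_cloud = 8 * np.pi * a_cloud / b_cloud**3

        def oracle(d):
            # neutral pair: +N_cloud point minus the diffuse cloud's potential
            inner = scipy_quad(lambda s: 4 * np.pi * s**2 * a_cloud * np.exp(-b_cloud * s), 0, d)[0]
            outer = scipy_quad(lambda s: 4 * np.pi * s * a_cloud * np.exp(-b_cloud * s), d, 80)[0]
            return n_cloud / d - (inner / d + outer)

        for d in (0.5, 1.5, 4.0):
            v = model_potential(part, np.array([[d, 0, 0]]), terms=("cloud_penetration",))
            assert v[0] == pytest.approx(oracle(d), rel=1e-10)

    def test_cloud_term_decays_exponentially(self):
        atoms = [AtomSite(index=0, element=6, position=np.zeros(3),
                          cloud_a=2.2, cloud_b=2.0)]
        part = StockholderPartition(atoms=atoms)
        v = model_potential(part, np.array([[20.0, 0, 0]]), terms=("cloud_penetration",))
        assert abs(v[0]) < 1e-10

    def test_point_on_nucleus_rejected(self):
        with pytest.raises(ValidationError, match="nucleus"):
            model_potential(_single_charge(), np.zeros((1, 3)))

    def test_periodic_ewald_reproduces_madelung_constant(self):
        part = make_fixture(FixtureSpec(kind="rocksalt", size=8))
        na = part.atoms[0]
        delta = np.array([1e-3, 0.0, 0.0])
        v = model_potential(part, (na.position + delta)[None, :])[0]
        site_potential = v - na.charge / np.linalg.norm(delta)
        r_nn = 2.82 * ANGSTROM_TO_BOHR
        madelung = -site_potential * r_nn / na.charge
        assert madelung == pytest.approx(1.7475646, abs=1e-5)


class TestValidMask:
    def _grid_and_partition(self):
        part = make_fixture(FixtureSpec(kind="water_like"))
        _, density = make_oracle_grids(part, spacing_angstrom=0.6)
        return part, density

    def test_three_selection_rules(self):
        part, density = self._grid_and_partition()
        mask = valid_grid_mask(density, part)
        pts = density.points()
        pos = part.positions
        d = np.min(
            np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2), axis=1
        )
        rho = density.values.reshape(-1)
        inner = 2.0 * ANGSTROM_TO_BOHR
        outer = 5.0 * ANGSTROM_TO_BOHR
        expected = (rho < 1e-4) & (d > inner) & (d <= outer)
        np.testing.assert_array_equal(mask.flat, expected)
        # all three rules are active on this grid
        assert np.any((rho < 1e-4) & (d > inner) & (d > outer))   # outer excludes
        assert np.any((d <= inner))                                # inner excludes
        assert np.any((rho >= 1e-4) & (d > inner) & (d <= outer))  # rho excludes

    def test_mismatched_grid_errors(self):
        part, density = self._grid_and_partition()
        shifted = part.copy()
        for a in shifted.atoms:
            a.position = a.position + 1e3
        with pytest.raises(ValidationError, match="valid grid points"):
            valid_grid_mask(density, shifted)


class TestEspMetrics:
    def test_perfect_model(self):
        v = np.linspace(-1, 1, 50)
        m = esp_metrics(v, v, np.ones(50, dtype=bool))
        assert m.rmse == 0.0 and m.rrmse == 0.0 and m.r_squared == 1.0

    def test_null_model_rrmse_exactly_one(self):
        rng = np.random.default_rng(0)
        qm = rng.standard_normal(100)
        m = esp_metrics(np.zeros(100), qm, np.ones(100, dtype=bool))
        assert m.rrmse == 1.0
        assert m.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_rrmse_030_gives_r_squared_091(self):
        qm = np.full(10, 1.0)
        model = np.full(10, 0.7)  # rmse 0.3, rmse_null 1.0
        m = esp_metrics(model, qm, np.ones(10, dtype=bool))
        assert m.rrmse == pytest.approx(0.3, abs=1e-14)
        assert m.r_squared == pytest.approx(0.91, abs=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError, match="RRMSE"):
            esp_metrics(np.ones(5), np.zeros(5), np.ones(5, dtype=bool))

    def test_convex_scaling_toward_truth_keeps_rrmse_below_one(self):
        rng = np.random.default_rng(2)
        qm = rng.standard_normal(200)
        for lam in (0.1, 0.5, 0.9):
            m = esp_metrics(lam * qm, qm, np.ones(200, dtype=bool))
            assert m.rrmse <= 1.0


class TestOracleClosure:
    def test_charges_only_grid_is_reproduced_exactly(self):
        part = make_fixture(FixtureSpec(kind="random", seed=3, size=5))
        esp, density = make_oracle_grids(part, spacing_angstrom=0.8, terms=("charges",))
        mask = valid_grid_mask(density, part)
        model = model_potential(part, esp.points(), terms=("charges",))
        m = esp_metrics(model, esp.values.reshape(-1), mask)
        assert m.rmse / HARTREE_TO_KCAL_PER_MOL < 1e-10

    def test_dipole_term_needed_when_ground_truth_has_dipoles(self):
        part = make_fixture(FixtureSpec(kind="random", seed=4, size=5, dipole_scale=0.3))
        esp, density = make_oracle_grids(
            part, spacing_angstrom=0.8, terms=("charges", "atomic_dipoles")
        )
        mask = valid_grid_mask(density, part)
        pts = esp.points()
        qm = esp.values.reshape(-1)
        m_q = esp_metrics(model_potential(part, pts, terms=("charges",)), qm, mask)
        m_qd = esp_metrics(
            model_potential(part, pts, terms=("charges", "atomic_dipoles")), qm, mask
        )
        assert m_q.rmse > 0.0
        assert m_qd.rmse / HARTREE_TO_KCAL_PER_MOL < 1e-10

    def test_noise_is_seeded_and_reproducible(self):
        part = make_fixture(FixtureSpec(kind="water_like"))
        e1, _ = make_oracle_grids(part, spacing_angstrom=1.0, noise_sd=0.01, seed=5)
        e2, _ = make_oracle_grids(part, spacing_angstrom=1.0, noise_sd=0.01, seed=5)
        np.testing.assert_array_equal(e1.values, e2.values)


class TestRingTubeOffset:
    def _symmetric_probe_circles(self, part):
        n = part.n_atoms
        radius = np.linalg.norm(part.atoms[0].position)
        angles = 2 * np.pi * (np.arange(2 * n) + 0.5) / (2 * n)
        def circle(s):
            return np.stack(
                [s * np.cos(angles), s * np.sin(angles), np.zeros_like(angles)], axis=1
            )
        return circle(0.3 * radius), circle(3.0 * radius)

    def test_dipoles_create_inside_outside_offset_charges_cannot(self):
        part = make_fixture(FixtureSpec(kind="ring_tube", seed=0, size=10,
                                        dipole_scale=0.15))
        inside, outside = self._symmetric_probe_circles(part)
        truth_in = model_potential(part, inside, terms=("charges", "atomic_dipoles"))
        truth_out = model_potential(part, outside, terms=("charges", "atomic_dipoles"))
        assert abs(np.mean(truth_in) - np.mean(truth_out)) > 1e-3

        # any neutral alternating point-charge assignment gives exactly zero
        # mean over the symmetric probe circles
        for q_even in (0.4, 0.9, 0.1):
            pc = part.copy()
            pc.charges = np.array([q_even if i % 2 == 0 else -q_even
                                   for i in range(part.n_atoms)])
            v_in = model_potential(pc, inside, terms=("charges",))
            v_out = model_potential(pc, outside, terms=("charges",))
            assert abs(np.mean(v_in) - np.mean(v_out)) < 1e-12


class TestCubeIO:
    def test_round_trip(self, tmp_path):
        part = make_fixture(FixtureSpec(kind="water_like"))
        esp, density = make_oracle_grids(part, spacing_angstrom=1.2)
        path = tmp_path / "esp.cube"
        write_cube(esp, part, path)
        grid, elements, positions = read_cube(path, kind="esp")
        np.testing.assert_allclose(grid.values, esp.values, rtol=1e-4, atol=1e-12)
        np.testing.assert_allclose(grid.origin, esp.origin, atol=1e-6)
        np.testing.assert_array_equal(elements, part.elements)
        np.testing.assert_allclose(positions, part.positions, atol=1e-6)
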