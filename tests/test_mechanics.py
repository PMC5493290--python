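"""Vertex-model energy, forces and the soft-core repulsion."""

import numpy as np
import pytest

import avm
from avm import mechanics as mech
from avm.mechanics import MechanicalParams, cell_geometry

from conftest import hex_lattice_tissue, single_hexagon_tissue

HEX_P0 = 3.7224194364083982  # regular hexagon


def fd_force(tissue, params, k, terms=("area", "perimeter", "junction"), h=1e-6):
    fd = np.empty(2)
    for c in range(2):
        tissue.pos[k, c] += h
        tissue.remesh()
        Ep = mech.vm_energy(tissue, params, terms=terms).total
        tissue.pos[k, c] -= 2 * h
        tissue.remesh()
        Em = mech.vm_energy(tissue, params, terms=terms).total
        tissue.pos[k, c] += h
        tissue.remesh()
        fd[c] = -(Ep - Em) / (2 * h)
    return fd


class TestShapeFactors:
    def test_growth_study_parameter_mapping(self):
        assert mech.effective_p0(1.0, -5.5, np.pi) == pytest.approx(3.10, abs=5e-3)

    def test_scale_invariance(self):
        assert mech.effective_p0(2.0, -11.0, np.pi) == pytest.approx(
            mech.effective_p0(1.0, -5.5, np.pi), rel=1e-12
        )

    def test_zero_tension(self):
        assert mech.effective_p0(1.0, 0.0, np.pi) == 0.0

    def test_gamma_zero_raises(self):
        with pytest.raises(ValueError):
            mech.effective_p0(0.0, -5.5)

    @pytest.mark.parametrize(
        "n,expected", [(6, 3.722), (5, 3.812), (4, 4.0), (3, 4.559)]
    )
    def test_regular_polygons(self, n, expected):
        assert mech.regular_polygon_p0(n) == pytest.approx(expected, abs=5e-4)

    def test_polygon_needs_three_sides(self):
        with pytest.raises(ValueError):
            mech.regular_polygon_p0(2)

    def test_p0_lambda_round_trip(self):
        lam = mech.p0_to_lambda(3.7, Gamma=0.5, A0=np.pi)
        assert mech.effective_p0(0.5, lam, np.pi) == pytest.approx(3.7, rel=1e-12)


class TestEnergy:
    def test_single_hexagon_scaled_energy(self):
        """A regular hexagonal cell with A = A0 and P = P0 has zero scaled
        energy; displacing A0 by delta gives delta^2/2."""
        t = single_hexagon_tissue()
        geo = cell_geometry(t)
        A, P = geo["areas"][0], geo["perimeters"][0]
        Gamma = 1.0
        lam = -Gamma * P  # P0 = P exactly
        params = MechanicalParams(K=1.0, Gamma=Gamma, Lambda=lam)
        e = mech.vm_energy(t, params, scaled=True)
        assert e.total == pytest.approx(0.0, abs=1e-12)
        delta = 0.37
        t.A0[t.interior_idx] = A + delta
        e2 = mech.vm_energy(t, params, scaled=True)
        assert e2.total == pytest.approx(delta**2 / 2, rel=1e-10)

    def test_scaled_and_raw_forms_differ_by_completed_square(self, disk40):
        """E(raw) - E(scaled) = N Gamma P0^2 / 2 for uniform tension."""
        Gamma, lam = 0.7, -2.2
        params = MechanicalParams(K=1.0, Gamma=Gamma, Lambda=lam)
        raw = mech.vm_energy(disk40, params).total
        scaled = mech.vm_energy(disk40, params, scaled=True).total
        N = disk40.n_cells
        # Gamma/2 P^2 + Lambda P = Gamma/2 (P - P0)^2 - Lambda^2/(2 Gamma)
        assert scaled - raw == pytest.approx(N * lam**2 / (2 * Gamma), rel=1e-9)

    def test_breakdown_totals(self, disk40):
        params = MechanicalParams(K=1.0, Gamma=0.5, Lambda=-1.0)
        e = mech.vm_energy(disk40, params)
        assert e.total == pytest.approx(
            e.area_term + e.perimeter_term + e.junction_term, rel=1e-12
        )

    def test_type_swap_symmetry(self, disk40):
        """Relabelling the two cell types leaves the energy invariant when
        the tension matrix is symmetric."""
        t = disk40.copy()
        t.n_types = 2
        rng = np.random.default_rng(0)
        t.types[t.interior_idx] = rng.integers(0, 2, t.n_cells)
        t.types[~t.interior] = 2
        t.remesh()
        lam = np.array([[-6.8, -6.4, -6.2], [-6.4, -6.2, -6.2], [-6.2, -6.2, -6.2]])
        params = MechanicalParams(K=1.0, Gamma=1.0, Lambda=lam)
        e1 = mech.vm_energy(t, params).total
        # swap labels and permute the matrix accordingly
        t2 = t.copy()
        sw = t2.types.copy()
        sw[t2.types == 0] = 1
        sw[t2.types == 1] = 0
        t2.types = sw
        t2.remesh()
        perm = np.ix_([1, 0, 2], [1, 0, 2])
        params2 = MechanicalParams(K=1.0, Gamma=1.0, Lambda=lam[perm])
        assert mech.vm_energy(t2, params2).total == pytest.approx(e1, rel=1e-12)


class TestForces:
    @pytest.mark.parametrize("terms", [("area",), ("perimeter",), ("junction",), ("area", "perimeter", "junction")])
    def test_forces_match_fd_gradient_per_term(self, disk40_copy, terms):
        t = disk40_copy
        params = MechanicalParams(K=1.0, Gamma=0.6, Lambda=-2.0)
        F = mech.vm_forces(t, params, terms=terms)
        rng = np.random.default_rng(1)
        sample = list(rng.choice(t.interior_idx, 4, replace=False)) + [
            int(t.loops[0][3])
        ]
        for k in sample:
            fd = fd_force(t, params, k, terms=terms)
            scale = max(np.abs(fd).max(), 1e-6)
            assert np.allclose(F[k], fd, rtol=1e-5, atol=1e-5 * scale)

    def test_heterogeneous_tension_forces_match_fd(self, disk40_copy):
        t = disk40_copy
        t.n_types = 2
        rng = np.random.default_rng(2)
        t.types[t.interior_idx] = rng.integers(0, 2, t.n_cells)
        t.types[~t.interior] = 2
        t.remesh()
        lam = np.array([[-6.8, -6.4, -6.8], [-6.4, -6.2, -6.2], [-6.8, -6.2, -6.2]])
        params = MechanicalParams(K=1.0, Gamma=1.0, Lambda=lam)
        F = mech.vm_forces(t, params)
        for k in [int(t.interior_idx[5]), int(t.loops[0][0])]:
            fd = fd_force(t, params, k)
            assert np.allclose(F[k], fd, rtol=1e-5, atol=1e-5 * max(np.abs(fd).max(), 1e-6))

    def test_total_force_vanishes(self, disk40):
        """Translation invariance of the energy: forces sum to zero on an
        isolated patch (interior + free boundary, no constraints)."""
        params = MechanicalParams(K=1.0, Gamma=1.0, Lambda=-3.0)
        F = mech.vm_forces(disk40, params)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-10)

    def test_gradient_descent_monotone(self, disk40_copy):
        t = disk40_copy
        params = MechanicalParams.uniform_p0(3.10)
        energies = []
        lr = 0.02
        for _ in range(200):
            F = mech.vm_forces(t, params) + mech.soft_core_forces(t, params)
            energies.append(
                mech.vm_energy(t, params).total + mech.soft_core_energy(t, params)
            )
            t.pos += lr * F
            t.mark_moved()
            t.equiangulate()
        e = np.asarray(energies)
        assert np.all(np.diff(e) <= 1e-10)

    def test_hexagonal_ground_state_is_force_free(self):
        """Triangular lattice at the hexagon shape factor (A0 and P0 matching
        the regular hexagon) is a zero-force state in the bulk."""
        spacing = np.sqrt(np.pi / (np.sqrt(3) / 2))  # hexagon area = pi
        t = hex_lattice_tissue(10, 10, spacing=spacing)
        params = MechanicalParams.uniform_p0(HEX_P0)
        F = mech.vm_forces(t, params)
        # deep bulk: at least 3 lattice spacings from the patch edge
        ipos = t.pos[t.interior_idx]
        lo = ipos.min(axis=0) + 3 * spacing
        hi = ipos.max(axis=0) - 3 * spacing
        deep = t.interior_idx[np.all((ipos > lo) & (ipos < hi), axis=1)]
        assert len(deep) > 5
        assert np.max(np.abs(F[deep])) < 1e-8


class TestSoftCore:
    def _pair_tissue(self, r):
        pts = np.array([[0.0, 0.0], [r, 0.0]])
        ring = 5 * np.stack(
            [np.cos(2 * np.pi * np.arange(10) / 10), np.sin(2 * np.pi * np.arange(10) / 10)],
            axis=1,
        ) + np.array([r / 2, 0])
        return avm.Tissue.build(pts, [ring])

    def test_zero_at_cutoff(self):
        t = self._pair_tissue(1.0)
        F = mech.soft_core_forces(t, MechanicalParams(k_core=1.0, a=1.0))
        assert np.allclose(F, 0.0)

    def test_half_range_magnitude_and_newton(self):
        t = self._pair_tissue(0.5)
        F = mech.soft_core_forces(t, MechanicalParams(k_core=1.0, a=1.0))
        assert np.linalg.norm(F[0]) == pytest.approx(0.5, rel=1e-12)
        assert np.allclose(F[0], -F[1])

    def test_three_overlapping_net_zero(self):
        pts = np.array([[0, 0], [0.4, 0], [0.2, 0.3]], dtype=float)
        ring = 5 * np.stack(
            [np.cos(2 * np.pi * np.arange(10) / 10), np.sin(2 * np.pi * np.arange(10) / 10)],
            axis=1,
        )
        t = avm.Tissue.build(pts, [ring])
        F = mech.soft_core_forces(t, MechanicalParams(k_core=1.0, a=1.0))
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-12)

    def test_energy_force_consistency(self, disk40_copy):
        t = disk40_copy
        params = MechanicalParams(k_core=1.0, a=1.2)
        F = mech.soft_core_forces(t, params)
        h = 1e-6
        k = int(t.interior_idx[7])
        fd = np.empty(2)
        for c in range(2):
            t.pos[k, c] += h
            Ep = mech.soft_core_energy(t, params)
            t.pos[k, c] -= 2 * h
            Em = mech.soft_core_energy(t, params)
            t.pos[k, c] += h
            fd[c] = -(Ep - Em) / (2 * h)
        assert np.allclose(F[k], fd, rtol=1e-5, atol=1e-8)
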