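"""FTCS competition-diffusion solver: oracles, fixed points, invariants."""

import numpy as np
import pytest
from scipy.linalg import expm

from patchcoex import (
    Ecosystem,
    IntervalDomain,
    IslandRecipe,
    SimulationConfig,
    StateField,
    dominance_map,
    generate_island,
    kernel_dispersal_step,
    rasterize,
    run_to_equilibrium,
    stable_timestep,
    step_ftcs,
)
from patchcoex.dynamics import DOMINANCE_EMPTY, DOMINANCE_EXTERIOR
from patchcoex.errors import (
    DegenerateSystemError,
    KernelTooWideError,
    NumericalInstabilityError,
    WrongDimensionalityError,
)

single = lambda r, D: Ecosystem(r=[r], D=[D], A=[[1.0]])
transport = lambda D: Ecosystem(r=[0.0], D=[D], A=np.zeros((1, 1)))


class TestStableTimestep:
    def test_diffusion_bound_1d(self):
        eco = Ecosystem(r=[1.0], D=[5e-4], A=[[1.0]])
        # 0.9 h^2 / (2 D) = 0.09 < 0.1/r
        assert stable_timestep(eco, h=0.01, dims=1) == pytest.approx(0.09)

    def test_reaction_cap_when_no_diffusion(self):
        assert stable_timestep(single(1.0, 0.0), h=0.01, dims=1) == pytest.approx(0.1)

    def test_2d_halves_diffusion_bound(self):
        eco = transport(1e-3)
        assert stable_timestep(eco, 0.01, 2) == pytest.approx(
            stable_timestep(eco, 0.01, 1) / 2
        )

    def test_degenerate_system(self):
        with pytest.raises(DegenerateSystemError):
            stable_timestep(Ecosystem(r=[0.0], D=[0.0], A=[[1.0]]), 0.01, 1)


class TestStepFTCS:
    def test_uniform_interior_cell_is_logistic_map(self):
        domain = IntervalDomain(99)
        eco = single(0.7, 1e-3)
        u0 = 0.2
        state = StateField.uniform(domain, 1, u0)
        dt = 0.01
        new = step_ftcs(state, eco, dt)
        mid = 49  # far from both boundaries: zero curvature
        assert new.u[0, mid] == pytest.approx(u0 + dt * u0 * (0.7 - u0), rel=1e-12)

    def test_all_zero_state_is_fixed_point(self):
        domain = IntervalDomain(20)
        state = StateField(np.zeros((1, 20)), domain)
        new = step_ftcs(state, single(1.0, 1e-3), 0.01)
        assert not new.u.any()

    def test_pure_diffusion_matches_matrix_exponential(self):
        """FTCS transport on 50 cells vs the dense expm of the same discrete
        Laplacian, at a step far below the stability bound."""
        domain = IntervalDomain(50)
        D, dt, steps = 1e-3, 1e-5, 100
        u0 = np.exp(-(((domain.x - 0.5) / 0.1) ** 2))[None, :]
        state = StateField(u0.copy(), domain)
        eco = transport(D)
        for _ in range(steps):
            state = step_ftcs(state, eco, dt)
        ref = expm(domain.laplacian().toarray() * D * steps * dt) @ u0[0]
        rel = np.abs(state.u[0] - ref).max() / np.abs(ref).max()
        assert rel < 1e-6

    def test_unstable_dt_rejected(self):
        domain = IntervalDomain(50)
        state = StateField.uniform(domain, 1, 0.1)
        with pytest.raises(ValueError, match="stable"):
            step_ftcs(state, transport(1e-2), dt=1.0)

    def test_compiled_loop_matches_reference_steps(self):
        """run_to_equilibrium's compiled kernel reproduces repeated step_ftcs."""
        domain = IntervalDomain(40)
        eco = Ecosystem.two_species(a21=1.3, D1=2e-3, D2=5e-4)
        dt = stable_timestep(eco, domain.h, 1)
        state = StateField.uniform(domain, 2, 0.1)
        for _ in range(50):
            state = step_ftcs(state, eco, dt)
        res = run_to_equilibrium(
            StateField.uniform(domain, 2, 0.1), eco,
            SimulationConfig(dt=dt, max_steps=50, tol=1e-300),
        )
        np.testing.assert_allclose(res.state.u, state.u, rtol=1e-12, atol=1e-300)


class TestRunToEquilibrium:
    def test_logistic_fixed_point(self):
        domain = IntervalDomain(60)
        res = run_to_equilibrium(
            StateField.uniform(domain, 1, 0.01), single(0.5, 0.0), SimulationConfig()
        )
        assert res.converged
        np.testing.assert_allclose(res.state.u, 0.5, atol=1e-3)

    def test_subcritical_patch_goes_extinct(self):
        # L_c = pi sqrt(D/r) = pi sqrt(0.2) = 1.40 > 1: extinction
        domain = IntervalDomain(99)
        res = run_to_equilibrium(
            StateField.uniform(domain, 1, 0.01), single(1.0, 0.2),
            SimulationConfig(tol=1e-10),
        )
        assert res.state.u.max() < 1e-4

    def test_two_species_boundary_dominance_profile(self):
        """Superior competitor-and-disperser holds the interior; the inferior
        species dominates adjacent to both absorbing boundaries."""
        domain = IntervalDomain(199)
        eco = Ecosystem.two_species(a21=1.2, D1=3e-3, D2=5e-4)
        res = run_to_equilibrium(
            StateField.uniform(domain, 2, 0.1), eco, SimulationConfig()
        )
        u = res.state.u
        assert res.converged
        assert (res.totals > 0.05 * res.totals.max()).all()  # both persist
        assert u[1, 0] > u[0, 0] and u[1, -1] > u[0, -1]
        assert u[0, 99] > u[1, 99]
        assert np.abs(u - u[:, ::-1]).max() < 1e-6  # midpoint symmetry

    def test_nonconvergence_flagged_not_raised(self):
        domain = IntervalDomain(30)
        res = run_to_equilibrium(
            StateField.uniform(domain, 1, 0.01), single(1.0, 1e-4),
            SimulationConfig(max_steps=10),
        )
        assert not res.converged
        assert res.steps == 10

    def test_dirichlet_mass_decay(self):
        """With no growth or interactions, total abundance strictly decreases."""
        domain = IntervalDomain(50)
        state = StateField.uniform(domain, 1, 1.0)
        eco = transport(2e-3)
        dt = stable_timestep(eco, domain.h, 1)
        totals = [state.totals()[0]]
        for _ in range(40):
            state = step_ftcs(state, eco, dt)
            totals.append(state.totals()[0])
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_gause_exclusion_without_space(self):
        """D = 0, inversely symmetric interactions: the dominant excludes."""
        domain = IntervalDomain(30)
        eco = Ecosystem(r=[1, 1], D=[0, 0], A=[[1, 1 / 1.3], [1.3, 1]])
        res = run_to_equilibrium(
            StateField.uniform(domain, 2, 0.1), eco,
            SimulationConfig(max_steps=500_000),
        )
        assert res.state.u[1].max() < 1e-4
        assert res.state.u[0].max() == pytest.approx(1.0, abs=1e-3)

    def test_neutral_competition_inferior_disperser_wins(self):
        """a12 = a21 = 1: dispersal differences alone do not allow coexistence;
        the better disperser loses more mass over the boundary and is excluded."""
        domain = IntervalDomain(99)
        eco = Ecosystem(r=[1, 1], D=[2e-3, 5e-4], A=np.ones((2, 2)))
        res = run_to_equilibrium(
            StateField.uniform(domain, 2, 0.1), eco,
            SimulationConfig(max_steps=2_000_000),
        )
        assert res.state.u[0].max() < 1e-4
        assert res.state.u[1].max() > 0.5

    @pytest.mark.parametrize("D,r", [(2e-3, 1.0), (5e-3, 1.0), (1e-3, 0.5)])
    def test_critical_patch_size_law(self, D, r):
        """Bisection over interval length locates L_c = pi sqrt(D/r) within 5%."""

        def persists(L):
            domain = IntervalDomain(64, length=L)
            eco = single(r, D)
            dt = stable_timestep(eco, domain.h, 1)
            res = run_to_equilibrium(
                StateField.uniform(domain, 1, 0.01), eco,
                SimulationConfig(tol=1e-13, max_steps=int(400 / r / dt) + 1),
            )
            return res.state.u.max() > 0.01

        L_c = np.pi * np.sqrt(D / r)
        lo, hi = 0.5 * L_c, 2.0 * L_c
        assert not persists(lo) and persists(hi)
        while hi - lo > 0.02 * lo:
            mid = 0.5 * (lo + hi)
            if persists(mid):
                hi = mid
            else:
                lo = mid
        assert 0.5 * (lo + hi) == pytest.approx(L_c, rel=0.05)


class TestKernelDispersal:
    def test_zero_sigma_is_reaction_only(self):
        domain = IntervalDomain(50)
        state = StateField.uniform(domain, 1, 0.2)
        eco = single(1.0, 0.0)
        new = kernel_dispersal_step(state, eco, 0.01, [0.0])
        expected = 0.2 + 0.01 * 0.2 * (1.0 - 0.2)
        np.testing.assert_allclose(new.u, expected)

    def test_absorbing_exterior_loses_mass(self):
        domain = IntervalDomain(50)
        state = StateField.uniform(domain, 1, 0.5)
        new = kernel_dispersal_step(state, transport(0.0), 0.01, [0.1])
        assert new.totals()[0] < state.totals()[0]

    def test_too_wide_kernel_rejected(self):
        domain = IntervalDomain(50)
        state = StateField.uniform(domain, 1, 0.1)
        with pytest.raises(KernelTooWideError):
            kernel_dispersal_step(state, transport(0.0), 0.01, [0.9])

    def test_matched_variance_reproduces_diffusion(self):
        """Gaussian redispersal with sigma^2 = 2 D dt per step tracks the FTCS
        diffusion profile within 5% after 500 steps."""
        domain = IntervalDomain(99)
        eco = transport(2e-3)
        dt = stable_timestep(eco, domain.h, 1)
        sigma = np.sqrt(2 * 2e-3 * dt)
        ftcs = StateField.uniform(domain, 1, 0.1)
        kern = StateField.uniform(domain, 1, 0.1)
        for _ in range(500):
            ftcs = step_ftcs(ftcs, eco, dt)
            kern = kernel_dispersal_step(kern, eco, dt, [sigma])
        rel = np.abs(kern.u - ftcs.u).max() / ftcs.u.max()
        assert rel < 0.05


@pytest.fixture(scope="module")
def disc_domain():
    theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)
    from patchcoex import PatchOutline

    return rasterize(
        PatchOutline(np.column_stack([np.cos(theta), np.sin(theta)])), 24
    )


class TestDominanceMap:
    def test_single_species_everywhere(self, disc_domain):
        res = run_to_equilibrium(
            StateField.uniform(disc_domain, 1, 0.1), single(1.0, 1e-3),
            SimulationConfig(),
        )
        grid, ties = dominance_map(res)
        assert set(np.unique(grid[disc_domain.mask])) == {0}
        assert (grid[~disc_domain.mask] == DOMINANCE_EXTERIOR).all()

    def test_disjoint_supports_recovered(self, disc_domain):
        n = disc_domain.n_interior
        u = np.zeros((2, n))
        left = disc_domain.cell_centers()[:, 0] < 0
        u[0, left] = 0.5
        u[1, ~left] = 0.4
        state = StateField(u, disc_domain)
        from patchcoex.dynamics import EquilibriumResult

        res = EquilibriumResult(state, True, 0, state.totals(), np.empty(0))
        grid, ties = dominance_map(res)
        vals = grid[disc_domain.mask]
        assert (vals[left] == 0).all() and (vals[~left] == 1).all()
        assert ties == 0

    def test_all_zero_marked_empty(self, disc_domain):
        state = StateField(np.zeros((2, disc_domain.n_interior)), disc_domain)
        from patchcoex.dynamics import EquilibriumResult

        res = EquilibriumResult(state, True, 0, state.totals(), np.empty(0))
        grid, _ = dominance_map(res)
        assert (grid[disc_domain.mask] == DOMINANCE_EMPTY).all()

    def test_1d_rejected(self):
        domain = IntervalDomain(30)
        res = run_to_equilibrium(
            StateField.uniform(domain, 1, 0.1), single(1.0, 0.0), SimulationConfig()
        )
        with pytest.raises(WrongDimensionalityError):
            dominance_map(res)


class TestInstability:
    def test_overshooting_reaction_raises(self):
        # far above carrying capacity the explicit logistic update overshoots
        # to strongly negative abundance, which must not be silently repaired
        domain = IntervalDomain(30)
        state = StateField.uniform(domain, 1, 50.0)
        with pytest.raises(NumericalInstabilityError):
            run_to_equilibrium(state, single(1.0, 0.0), SimulationConfig())

    def test_excessive_dt_rejected_up_front(self):
        domain = IntervalDomain(30)
        state = StateField.uniform(domain, 1, 0.1)
        eco = single(1.0, 5e-3)
        dt = stable_timestep(eco, domain.h, 1)
        with pytest.raises(ValueError, match="stable"):
            run_to_equilibrium(state, eco, SimulationConfig(dt=dt * 30))
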