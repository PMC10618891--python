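"""Competition-diffusion dynamics on bounded domains.

The model: S competing species with abundances u_i(x, t) obey

    du_i/dt = D_i * Lap(u_i) + u_i * (r_i - sum_j a_ij u_j)

on a bounded habitat patch with absorbing (Dirichlet) boundaries —
u_i = 0 on the patch edge, representing hostile surrounding habitat.
r_i is the intrinsic growth rate, D_i the diffusion coefficient, and
a_ij the per-capita effect of species j on species i (a_ii = 1).

Integration uses the explicit forward-time centred-space (FTCS) scheme on
either a 1-D interval or a rasterized 2-D patch, with the time step chosen
below the diffusion (CFL) bound and a reaction-rate cap. A run is at
equilibrium when the total absolute change of all species over all cells
in one step falls below a tolerance (1e-6 by default).

The boundary mechanism in brief: diffusion across the absorbing edge is a
mortality flux proportional to D_i, so near boundaries a low dispersal
ability becomes an advantage — the reverse of the classic
competition-colonization trade-off, and the source of the stable
concentric dominance patterns this package studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp

from ._kernels import evolve
from .errors import (
    DegenerateSystemError,
    KernelTooWideError,
    NumericalInstabilityError,
    WrongDimensionalityError,
)
from .geometry import RasterDomain

__all__ = [
    "Ecosystem",
    "IntervalDomain",
    "StateField",
    "SimulationConfig",
    "EquilibriumResult",
    "stable_timestep",
    "step_ftcs",
    "run_to_equilibrium",
    "kernel_dispersal_step",
    "dominance_map",
]


@dataclass(frozen=True)
class Ecosystem:
    """Parameters of an S-species competitive community.

    ``A[i, j]`` is the per-capita effect of species j on species i;
    the diagonal (intraspecific density dependence) is fixed at 1.
    """

    r: np.ndarray
    D: np.ndarray
    A: np.ndarray

    def __post_init__(self):
        r = np.atleast_1d(np.asarray(self.r, dtype=float))
        D = np.atleast_1d(np.asarray(self.D, dtype=float))
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        S = r.size
        if D.size != S or A.shape != (S, S):
            raise ValueError(f"inconsistent shapes: r{r.shape} D{D.shape} A{A.shape}")
        for name, arr in (("r", r), ("D", D), ("A", A)):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and non-negative")
        # the competition model fixes intraspecific density dependence at 1;
        # an all-zero A is also accepted for pure-transport diagnostics
        if not (np.allclose(np.diag(A), 1.0) or not A.any()):
            raise ValueError("diagonal of A (intraspecific competition) must be 1")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "A", np.ascontiguousarray(A))

    @property
    def S(self) -> int:
        return self.r.size

    @classmethod
    def two_species(cls, a21: float, D1: float, D2: float, r: float = 1.0) -> "Ecosystem":
        """Two species with inversely symmetric interactions a12 = 1/a21.

        a21 > 1 makes species 1 the competitive dominant.
        """
        if a21 <= 0:
            raise ValueError("a21 must be positive")
        A = np.array([[1.0, 1.0 / a21], [a21, 1.0]])
        assert abs(A[0, 1] * A[1, 0] - 1.0) < 1e-12
        return cls(r=np.array([r, r]), D=np.array([D1, D2]), A=A)


@dataclass(frozen=True)
class IntervalDomain:
    """1-D habitat patch [0, length] with n interior cells.

    Dirichlet zeros sit at both endpoints; interior cell j is at
    x = (j + 1) * h with h = length / (n + 1).
    """

    n: int
    length: float = 1.0

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("need at least 3 interior cells")
        if self.length <= 0:
            raise ValueError("length must be positive")

    dims = 1

    @property
    def h(self) -> float:
        return self.length / (self.n + 1)

    @property
    def n_interior(self) -> int:
        return self.n

    @property
    def is_empty(self) -> bool:
        return False

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.n) + 1) * self.h

    def laplacian(self) -> sp.csr_matrix:
        main = np.full(self.n, -2.0)
        off = np.ones(self.n - 1)
        lap = sp.diags([off, main, off], [-1, 0, 1], format="csr")
        lap.sort_indices()
        return lap * (1.0 / self.h**2)


@dataclass
class StateField:
    """Per-species abundance over a domain's interior cells, plus the clock.

    ``u`` is packed as (S, n_interior); exterior cells are identically zero
    by construction (Dirichlet). Use :meth:`grids` to scatter a 2-D state
    back onto the full raster for inspection.
    """

    u: np.ndarray
    domain: object
    t: float = 0.0

    def __post_init__(self):
        u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if u.shape[1] != self.domain.n_interior:
            raise ValueError(
                f"state has {u.shape[1]} cells, domain has {self.domain.n_interior}"
            )
        if np.any(u < 0):
            raise ValueError("abundances must be non-negative")
        self.u = np.ascontiguousarray(u)

    @property
    def S(self) -> int:
        return self.u.shape[0]

    @classmethod
    def uniform(cls, domain, S: int, u0: float) -> "StateField":
        """All species present everywhere at equal low abundance u0."""
        if u0 <= 0:
            raise ValueError("u0 must be positive")
        return cls(np.full((S, domain.n_interior), float(u0)), domain)

    def totals(self) -> np.ndarray:
        """Spatially integrated abundance per species (sum * cell measure)."""
        return self.u.sum(axis=1) * self.domain.h**self.domain.dims

    def grids(self) -> np.ndarray:
        """Scatter to full (S, ny, nx) arrays with zero exterior (2-D only)."""
        if self.domain.dims != 2:
            raise WrongDimensionalityError("grids() needs a 2-D raster domain")
        out = np.zeros((self.S,) + self.domain.mask.shape)
        out[:, self.domain.mask] = self.u
        return out

    def copy(self) -> "StateField":
        return StateField(self.u.copy(), self.domain, self.t)


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings for equilibrium runs.

    tol is the literal total-absolute-change-per-step criterion (summed over
    every cell and species); set per_cell_tol=True to scale it by the number
    of unknowns instead.
    """

    u0: float = 0.1
    dt: float | None = None
    tol: float = 1e-6
    max_steps: int = 2_000_000
    clamp_eps: float = 1e-12
    per_cell_tol: bool = False
    history_every: int = 200
    use_numba: bool = True

    def __post_init__(self):
        if self.tol <= 0 or self.u0 <= 0:
            raise ValueError("tol and u0 must be positive")
        if not (0 <= self.clamp_eps <= 1e-8):
            raise ValueError("clamp_eps must be in [0, 1e-8]")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class EquilibriumResult:
    """Outcome of an equilibrium integration."""

    state: StateField
    converged: bool
    steps: int
    totals: np.ndarray
    change_history: np.ndarray
    clamp_count: int = 0

    @property
    def domain(self):
        return self.state.domain


def stable_timestep(eco: Ecosystem, h: float, dims: int) -> float:
    """Explicit-scheme time step: 0.9x the diffusion CFL bound, further
    capped at 0.1/max(r) so the logistic reaction is well resolved."""
    if h <= 0:
        raise ValueError("h must be positive")
    if dims not in (1, 2):
        raise ValueError("dims must be 1 or 2")
    maxD = float(np.max(eco.D))
    maxr = float(np.max(eco.r))
    if maxD == 0 and maxr == 0:
        raise DegenerateSystemError("all diffusion and growth rates are zero")
    caps = []
    if maxD > 0:
        caps.append(0.9 * h**2 / (2 * dims * maxD))
    if maxr > 0:
        caps.append(0.1 / maxr)
    return min(caps)


def _check_dt(eco, domain, dt):
    limit = stable_timestep(eco, domain.h, domain.dims)
    if dt > limit * (1 + 1e-12):
        raise ValueError(f"dt={dt:g} exceeds stable step {limit:g}")


def step_ftcs(state: StateField, eco: Ecosystem, dt: float,
              clamp_eps: float = 1e-12) -> StateField:
    """One explicit FTCS step; returns a new StateField.

    Reference implementation (plain numpy); long integrations go through
    :func:`run_to_equilibrium`, which uses the same update in a compiled
    loop. Undershoots in (-clamp_eps, 0) are clamped to zero; anything
    at or below -clamp_eps, or non-finite, raises NumericalInstabilityError.
    """
    _check_dt(eco, state.domain, dt)
    u = state.u
    lap = state.domain.laplacian().dot(u.T).T
    new = u + dt * (eco.D[:, None] * lap + u * (eco.r[:, None] - eco.A @ u))
    bad = ~np.isfinite(new) | (new <= -clamp_eps)
    if bad.any():
        i, c = np.argwhere(bad)[0]
        raise NumericalInstabilityError(
            f"unstable update at cell {c}, species {i}", cell=int(c), species=int(i)
        )
    new[new < 0] = 0.0
    return StateField(new, state.domain, state.t + dt)


def run_to_equilibrium(state0: StateField, eco: Ecosystem,
                       config: SimulationConfig = SimulationConfig()) -> EquilibriumResult:
    """Integrate until the total absolute change per step drops below tol.

    Non-convergence within max_steps is not an error — the result is
    returned with ``converged=False``. Numerical instability raises.
    """
    domain = state0.domain
    if domain.n_interior == 0:
        empty = StateField(np.zeros((state0.S, 0)), domain, state0.t)
        return EquilibriumResult(empty, True, 0, np.zeros(state0.S), np.empty(0))
    dt = config.dt if config.dt is not None else stable_timestep(eco, domain.h, domain.dims)
    _check_dt(eco, domain, dt)
    tol = config.tol
    if config.per_cell_tol:
        tol = tol * state0.S * domain.n_interior
    u = state0.u.copy()
    out = evolve(
        domain.laplacian(), u, eco.r, eco.D, eco.A, dt, tol,
        config.max_steps, config.clamp_eps,
        hist_every=config.history_every, use_numba=config.use_numba,
    )
    if out["status"] == 2:
        step, cell, species = out["bad"]
        raise NumericalInstabilityError(
            f"unstable at step {step}, cell {cell}, species {species}",
            step=step, cell=cell, species=species,
        )
    state = StateField(u, domain, state0.t + out["steps"] * dt)
    return EquilibriumResult(
        state=state,
        converged=out["status"] == 1,
        steps=out["steps"],
        totals=state.totals(),
        change_history=out["history"],
        clamp_count=out["clamp_count"],
    )


def kernel_dispersal_step(state: StateField, eco: Ecosystem, dt: float,
                          kernel_sigmas) -> StateField:
    """Growth-then-redistribution step for the kernel-dispersal variant.

    The local (reaction) update is applied with diffusion off, then each
    species' field is convolved with an isotropic Gaussian of its sigma
    (length units). Mass carried onto exterior cells is discarded — the
    exterior absorbs, exactly as under diffusive dispersal. With
    sigma^2 = 2 * D * dt per step this reproduces diffusion in the
    matched-variance limit.
    """
    domain = state.domain
    sig = np.broadcast_to(np.asarray(kernel_sigmas, dtype=float), (state.S,)).copy()
    if np.any(sig < 0):
        raise ValueError("kernel sigmas must be >= 0")
    if domain.dims == 2:
        extent = min(domain.mask.shape) * domain.h
    else:
        extent = domain.length
    if np.any(sig > extent / 2):
        raise KernelTooWideError(
            f"kernel sigma {sig.max():g} exceeds half the domain extent {extent / 2:g}"
        )
    # reaction-only update
    u = state.u
    new = u + dt * (u * (eco.r[:, None] - eco.A @ u))
    new[new < 0] = 0.0
    if domain.dims == 2:
        full = np.zeros((state.S,) + domain.mask.shape)
        full[:, domain.mask] = new
        for i in range(state.S):
            if sig[i] > 0:
                full[i] = ndi.gaussian_filter(full[i], sig[i] / domain.h,
                                              mode="constant", cval=0.0)
        packed = full[:, domain.mask]  # exterior mass discarded
    else:
        packed = np.empty_like(new)
        for i in range(state.S):
            if sig[i] > 0:
                packed[i] = ndi.gaussian_filter1d(new[i], sig[i] / domain.h,
                                                  mode="constant", cval=0.0)
            else:
                packed[i] = new[i]
    return StateField(packed, domain, state.t + dt)


#: Abundance below which a cell is considered unoccupied in dominance maps.
DOMINANCE_FLOOR = 1e-6

#: Codes used in dominance maps for non-species cells.
DOMINANCE_EMPTY = -1
DOMINANCE_EXTERIOR = -2


def dominance_map(result: EquilibriumResult):
    """Per-cell index of the most abundant species at equilibrium (2-D).

    Returns an int grid the shape of the raster mask: species index where
    occupied, DOMINANCE_EMPTY where every species is below 1e-6, and
    DOMINANCE_EXTERIOR outside the patch. Exact ties go to the lowest
    species index; the tie count is returned alongside.
    """
    domain = result.domain
    if getattr(domain, "dims", None) != 2:
        raise WrongDimensionalityError("dominance_map requires a 2-D run")
    u = result.state.u
    winner = np.argmax(u, axis=0)  # lowest index wins ties (numpy argmax)
    best = u[winner, np.arange(u.shape[1])]
    ties = int(np.sum((u == best).sum(axis=0) > 1))
    winner = np.where(best < DOMINANCE_FLOOR, DOMINANCE_EMPTY, winner)
    grid = np.full(domain.mask.shape, DOMINANCE_EXTERIOR, dtype=int)
    grid[domain.mask] = winner
    return grid, ties
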