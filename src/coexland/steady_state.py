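"""Stationary solutions of the master equation and coexpression landscapes.

The stationary distribution pi is the normalized null vector of the
generator K. It is found by a sparse LU solve of K with one equation
replaced by the normalization constraint sum(pi) = 1 (with a
shift-invert eigensolve as fallback); the contract is the recorded
residual ||K pi||, not the algorithm. Summing pi over the 16 promoter
state combinations yields the M x M gene-pair coexpression landscape
pi(n_x, n_y); its negative log, phi = -ln(max(pi, floor)), is the
quasipotential landscape whose valleys are the stable cell states.

A Gillespie stochastic-simulation routine over the same reaction set
provides an independent (Monte-Carlo) estimate of the stationary
occupancy for cross-validation of the exact solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network_model import (
    GeneNetworkModel,
    RateMatrix,
    StateSpace,
    REACTION_DELTAS,
    build_rate_matrix,
)

__all__ = [
    "DEFAULT_FLOOR",
    "StationaryDistribution",
    "CoexpressionLandscape",
    "SolverError",
    "solve_stationary",
    "marginalize_promoters",
    "quasipotential",
    "compute_landscape",
    "boundary_mass",
    "ssa_simulate",
]

#: Pseudo-probability used when log-transforming, for model and
#: empirical landscapes alike so their feature vectors are commensurable.
DEFAULT_FLOOR = 1e-6

# Numerical tolerances of the stationary solve.
RESIDUAL_RTOL = 1e-8      # ||K pi||_inf relative to the generator scale
NEGATIVE_CLIP = 1e-12     # entries above -this are round-off; clip to 0


class SolverError(RuntimeError):
    """Stationary solve failed to meet the residual/positivity contract."""


@dataclass(frozen=True)
class StationaryDistribution:
    """Full-state stationary probability vector with its solve residual."""

    pi: np.ndarray
    residual: float
    state_space: StateSpace

    def __post_init__(self) -> None:
        if self.pi.shape != (self.state_space.n_states,):
            raise ValueError("pi length does not match the state space")


@dataclass(frozen=True)
class CoexpressionLandscape:
    """M x M gene-pair landscape, as probability or quasipotential.

    ``grid[n_x, n_y]`` holds either the stationary probability of the
    mRNA count pair or its quasipotential -ln(probability).
    """

    grid: np.ndarray
    representation: str = "probability"
    provenance: str = "model"
    floor: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
            raise ValueError("landscape grid must be square")
        if self.representation not in ("probability", "quasipotential"):
            raise ValueError(f"bad representation {self.representation!r}")
        if self.provenance not in ("model", "empirical"):
            raise ValueError(f"bad provenance {self.provenance!r}")
        if self.representation == "probability":
            if np.any(grid < 0):
                raise ValueError("probability landscape has negative entries")
            if abs(grid.sum() - 1.0) > 1e-6:
                raise ValueError("probability landscape does not sum to 1")

    @property
    def M(self) -> int:
        return self.grid.shape[0]

    def features(self) -> np.ndarray:
        """Flattened length-M^2 feature vector (row-major over n_x)."""
        return self.grid.ravel()


def _solve_normalized(K: sp.csc_matrix) -> np.ndarray:
    """Solve K pi = 0 by pinning one component and solving the rest.

    With pi[N-1] fixed to 1 the remaining components satisfy
    K[:-1, :-1] x = -K[:-1, -1]; the full vector is then normalized.
    Keeps the factorization sparse (no dense constraint row).
    """
    N = K.shape[0]
    A = K[:-1, :-1].tocsc()
    b = -K[:-1, [N - 1]].toarray().ravel()
    # MMD on A + A^T roughly halves fill vs COLAMD for this quasi-banded pattern
    x = spla.splu(A, permc_spec="MMD_AT_PLUS_A").solve(b)
    return np.concatenate([x, [1.0]])


def _solve_eigs(K: sp.csc_matrix) -> np.ndarray:
    """Fallback: shift-invert eigensolve targeting the zero eigenvalue."""
    scale = np.abs(K.diagonal()).max()
    sigma = 1e-12 * scale
    _, vecs = spla.eigs(K, k=1, sigma=sigma, which="LM")
    v = np.real(vecs[:, 0])
    if v.sum() < 0:
        v = -v
    return v / v.sum()


def solve_stationary(K: RateMatrix | sp.spmatrix,
                     state_space: StateSpace | None = None) -> StationaryDistribution:
    """Stationary distribution of a CME generator.

    Entries within round-off of zero (magnitude below 1e-12 relative to
    the largest entry) are clipped and the vector renormalized; larger
    negative entries, or a residual above 1e-8 of the generator scale,
    raise :class:`SolverError` after the fallback solver has been tried.
    """
    if isinstance(K, RateMatrix):
        state_space = K.state_space
        K = K.K
    if state_space is None:
        M = int(round(np.sqrt(K.shape[0] / 16)))
        state_space = StateSpace(M)
    scale = np.abs(K.diagonal()).max()
    if scale == 0:
        raise SolverError("zero generator")

    last_exc: Exception | None = None
    for solver in (_solve_normalized, _solve_eigs):
        try:
            pi = solver(K)
        except Exception as exc:  # singular factorization etc.
            last_exc = exc
            continue
        total = pi.sum()
        if not np.isfinite(total) or total <= 0:
            last_exc = SolverError("non-finite or non-positive solution")
            continue
        pi = pi / total
        neg = pi.min()
        if neg < -NEGATIVE_CLIP * max(1.0, pi.max()):
            last_exc = SolverError(f"negative probability {neg:.3e} beyond round-off")
            continue
        pi = np.clip(pi, 0.0, None)
        pi = pi / pi.sum()
        residual = float(np.abs(K @ pi).max())
        if residual > RESIDUAL_RTOL * scale:
            last_exc = SolverError(
                f"residual {residual:.3e} exceeds {RESIDUAL_RTOL:.0e} x scale {scale:.3e}"
            )
            continue
        return StationaryDistribution(pi=pi, residual=residual, state_space=state_space)
    raise SolverError(f"stationary solve failed: {last_exc}")


def marginalize_promoters(stationary: StationaryDistribution) -> CoexpressionLandscape:
    """Project the full-state distribution onto the mRNA count pair.

    Sums pi over all 16 promoter state combinations; probability mass
    is conserved exactly.
    """
    M = stationary.state_space.M
    # index order i = s_y + 4 s_x + 16 n_y + 16 M n_x
    grid = stationary.pi.reshape(M, M, 4, 4).sum(axis=(2, 3))
    grid = grid / grid.sum()
    return CoexpressionLandscape(grid=grid, representation="probability",
                                 provenance="model")


def quasipotential(landscape: CoexpressionLandscape,
                   floor: float = DEFAULT_FLOOR) -> CoexpressionLandscape:
    """Quasipotential transform phi = -ln(max(pi, floor)).

    The floor (default 1e-6) stands in for unobserved / numerically-zero
    probabilities, below the least estimable frequency at typical
    single-cell sample sizes.
    """
    if landscape.representation != "probability":
        raise ValueError("quasipotential requires a probability landscape")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    phi = -np.log(np.maximum(landscape.grid, floor))
    return replace(landscape, grid=phi, representation="quasipotential",
                   floor=floor)


def compute_landscape(model: GeneNetworkModel,
                      representation: str = "probability",
                      floor: float = DEFAULT_FLOOR) -> CoexpressionLandscape:
    """Model -> generator -> stationary solve -> marginal landscape."""
    rm = build_rate_matrix(model)
    land = marginalize_promoters(solve_stationary(rm))
    if representation == "quasipotential":
        land = quasipotential(land, floor=floor)
    return land


def boundary_mass(landscape: CoexpressionLandscape) -> float:
    """Probability that either count sits at the reflecting cap M-1.

    A diagnostic for the truncation quality: should be negligible when
    M is well above g_hi/k.
    """
    if landscape.representation != "probability":
        raise ValueError("boundary_mass requires a probability landscape")
    g = landscape.grid
    return float(g[-1, :].sum() + g[:, -1].sum() - g[-1, -1])


def ssa_simulate(model: GeneNetworkModel, t_end: float, seed: int,
                 initial_state: tuple[int, int, int, int] = (0, 0, 0, 0),
                 burn_in_fraction: float = 0.1) -> np.ndarray:
    """Gillespie simulation returning time-weighted state occupancy.

    Runs a single exact-SSA trajectory to ``t_end`` hours, discards the
    first ``burn_in_fraction`` of simulated time to remove
    initial-condition bias, and accumulates the dwell time per state.
    The result is a normalized length-N occupancy vector comparable to
    the stationary distribution; it is a deterministic function of the
    seed.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    space = model.state_space
    occupancy = np.zeros(space.n_states)
    state = np.array(initial_state, dtype=np.int64)
    space.state_to_index(*state)  # validate
    if t_end == 0:
        occupancy[int(space.state_to_index(*state))] = 1.0
        return occupancy
    rng = np.random.default_rng(seed)
    t = 0.0
    t_burn = burn_in_fraction * t_end
    # hot loop: inlined propensities with precomputed per-state synthesis rates
    p = model.params
    M = model.M
    gx = model.synthesis_rates("x")
    gy = model.synthesis_rates("y")
    deltas = REACTION_DELTAS
    n_x, n_y, s_x, s_y = (int(v) for v in state)
    a = np.empty(12)
    while t < t_end:
        a[0] = gx[s_x] if n_x < M - 1 else 0.0
        a[1] = gy[s_y] if n_y < M - 1 else 0.0
        a[2] = p.k * n_x
        a[3] = p.k * n_y
        a[4] = p.h_a * n_x * n_x / 2 if not s_x & 1 else 0.0
        a[5] = p.f_a if s_x & 1 else 0.0
        a[6] = p.h_r * n_y * n_y / 2 if s_x < 2 else 0.0
        a[7] = p.f_r if s_x >= 2 else 0.0
        a[8] = p.h_a * n_y * n_y / 2 if not s_y & 1 else 0.0
        a[9] = p.f_a if s_y & 1 else 0.0
        a[10] = p.h_r * n_x * n_x / 2 if s_y < 2 else 0.0
        a[11] = p.f_r if s_y >= 2 else 0.0
        a_tot = a.sum()
        t_new = t + rng.exponential(1.0 / a_tot) if a_tot > 0 else t_end
        idx = s_y + 4 * s_x + 16 * (n_y + M * n_x)
        lo, hi = max(t, t_burn), min(t_new, t_end)
        if hi > lo:
            occupancy[idx] += hi - lo
        t = t_new
        if t >= t_end or a_tot == 0:
            break
        r = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, a_tot), side="right"))
        r = min(r, 11)
        n_x += deltas[r, 0]
        n_y += deltas[r, 1]
        s_x += deltas[r, 2]
        s_y += deltas[r, 3]
    state = np.array([n_x, n_y, s_x, s_y])
    total = occupancy.sum()
    if total == 0:  # burn-in swallowed everything; fall back to last state
        occupancy[int(space.state_to_index(*state))] = 1.0
        total = 1.0
    return occupancy / total
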