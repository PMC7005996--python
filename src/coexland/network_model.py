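"""Discrete stochastic two-gene regulatory network models.

A model couples two genes, X and Y, whose protein products (proxied by
their mRNA counts) can bind each other's promoter and their own. Each
promoter is in one of four binding states — nothing bound, self-TF
bound, other-TF bound, or both bound — and each state maps to a
transcription level, low (``g_lo``, leaky but effectively off) or high
(``g_hi``). The 16 symmetric assignments of levels to the four states
form the "Two-Gene Flex" family; the mutual-inhibition/self-activation
(MISA) motif is the member {00: lo, self: hi, other: lo, both: lo}.

The chemical master equation over the joint state
(n_x, n_y, s_x, s_y) — mRNA copy numbers capped at M-1 by a reflecting
boundary, times 4 x 4 promoter states — is encoded as a sparse
generator matrix K whose off-diagonal entry K[l, m] is the rate of the
m -> l transition and whose columns sum to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "PROMOTER_STATES",
    "MOTIF_CLASSES",
    "MISA_MOTIF_ID",
    "NON_INTERACTING_MOTIF_IDS",
    "INTERACTING_MOTIF_IDS",
    "REACTIONS",
    "RegulatoryLogic",
    "KineticParameters",
    "GeneNetworkModel",
    "StateSpace",
    "RateMatrix",
    "enumerate_state_space",
    "propensity",
    "propensity_vector",
    "build_rate_matrix",
    "make_misa_model",
    "make_flex_model",
    "motif_class",
    "gene_swap_permutation",
]

# Promoter binding states, in the frozen order used for linear indexing.
# Encoding: bit 0 = self TF bound, bit 1 = other TF bound.
PROMOTER_STATES = ("00", "self", "other", "both")

MOTIF_CLASSES = (
    "mutual-activation",
    "mutual-repression",
    "no-interaction",
    "incoherent",
)

#: 4-bit motif id: bits (00, self, other, both), hi = 1.
MISA_MOTIF_ID = 0b0100  # {lo, hi, lo, lo}

#: Constant-level variants encode no gene-gene interaction at all and are
#: excluded from Flex sweeps.
NON_INTERACTING_MOTIF_IDS = (0b0000, 0b1111)

INTERACTING_MOTIF_IDS = tuple(
    m for m in range(16) if m not in NON_INTERACTING_MOTIF_IDS
)

#: Reaction identifiers: 2 synthesis, 2 degradation, 8 promoter transitions.
REACTIONS = (
    "synth_x",
    "synth_y",
    "deg_x",
    "deg_y",
    "bind_self_x",
    "unbind_self_x",
    "bind_cross_x",
    "unbind_cross_x",
    "bind_self_y",
    "unbind_self_y",
    "bind_cross_y",
    "unbind_cross_y",
)

# Table-1 kinetic ranges for promoter-state-change rates, per regime.
FAST_F_RANGE = (10.0, 1e5)
FAST_H_RANGE = (10.0, 500.0)
SLOW_RANGE = (1e-6, 10.0)


def _levels_from_motif_id(motif_id: int) -> tuple[str, str, str, str]:
    if not 0 <= motif_id <= 15:
        raise ValueError(f"motif_id must be in 0..15, got {motif_id}")
    bits = [(motif_id >> shift) & 1 for shift in (3, 2, 1, 0)]
    return tuple("hi" if b else "lo" for b in bits)  # type: ignore[return-value]


def _motif_id_from_levels(levels: Sequence[str]) -> int:
    if len(levels) != 4 or any(lv not in ("lo", "hi") for lv in levels):
        raise ValueError(f"levels must be four of 'lo'/'hi', got {levels!r}")
    mid = 0
    for lv in levels:
        mid = (mid << 1) | (1 if lv == "hi" else 0)
    return mid


def motif_class(motif_id: int) -> str:
    """Classify a logic variant by the sign of the cross-gene effect.

    The other gene's TF acts in two contexts: with the self site empty
    (compare the ``other`` vs ``00`` levels) and with it occupied
    (``both`` vs ``self``). Consistent non-positive effects give mutual
    repression, consistent non-negative give mutual activation, two
    zeros give no interaction, and opposite signs are incoherent
    (dual-effect) regulation.
    """
    hi = _levels_from_motif_id(motif_id)
    val = {"lo": 0, "hi": 1}
    d1 = val[hi[2]] - val[hi[0]]  # other vs 00
    d2 = val[hi[3]] - val[hi[1]]  # both vs self
    if d1 == 0 and d2 == 0:
        return "no-interaction"
    if d1 >= 0 and d2 >= 0:
        return "mutual-activation"
    if d1 <= 0 and d2 <= 0:
        return "mutual-repression"
    return "incoherent"


@dataclass(frozen=True)
class RegulatoryLogic:
    """Promoter-state -> transcription-level table for a symmetric motif.

    ``levels`` maps gene X's four promoter states, ordered
    (00, self, other, both), to 'lo' or 'hi'. Gene Y's table is the
    mirror image (identical over its own state ordering), so one tuple
    fully specifies the motif.
    """

    levels: tuple[str, str, str, str]
    motif_id: int = field(init=False)
    motif_class: str = field(init=False)

    def __post_init__(self) -> None:
        mid = _motif_id_from_levels(self.levels)
        object.__setattr__(self, "motif_id", mid)
        object.__setattr__(self, "motif_class", motif_class(mid))

    @classmethod
    def from_motif_id(cls, motif_id: int) -> "RegulatoryLogic":
        return cls(_levels_from_motif_id(motif_id))

    @property
    def interacting(self) -> bool:
        return self.motif_id not in NON_INTERACTING_MOTIF_IDS


@dataclass(frozen=True)
class KineticParameters:
    """Kinetic rate constants of the two-gene model.

    Units: synthesis rates in mRNA/hr, degradation ``k`` in 1/hr,
    binding ``h_*`` in 1/(hr mRNA^2) (TF dimers bind, so the propensity
    is h n^2 / 2), unbinding ``f_*`` in 1/hr. ``g_hi`` may differ
    between the genes (asymmetric model, 8 parameters). ``regime``
    tags the promoter kinetics as 'fast' (adiabatic) or 'slow'
    (nonadiabatic) per the catalogued ranges; None skips the range
    check.
    """

    g_hi_x: float = 1.0
    g_hi_y: float = 1.0
    g_lo: float = 0.001
    k: float = 0.2
    h_a: float = 100.0
    f_a: float = 1000.0
    h_r: float = 100.0
    f_r: float = 1000.0
    regime: str | None = None

    def __post_init__(self) -> None:
        for name in ("g_hi_x", "g_hi_y", "g_lo", "k", "h_a", "f_a", "h_r", "f_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (self.g_lo < self.g_hi_x and self.g_lo < self.g_hi_y):
            raise ValueError("g_lo must be below g_hi for both genes")
        if self.regime is not None:
            if self.regime not in ("fast", "slow"):
                raise ValueError("regime must be 'fast', 'slow' or None")
            f_rng = FAST_F_RANGE if self.regime == "fast" else SLOW_RANGE
            h_rng = FAST_H_RANGE if self.regime == "fast" else SLOW_RANGE
            for name, rng in (
                ("f_a", f_rng), ("f_r", f_rng), ("h_a", h_rng), ("h_r", h_rng),
            ):
                v = getattr(self, name)
                if not rng[0] <= v <= rng[1]:
                    raise ValueError(
                        f"{name}={v} outside the {self.regime} regime "
                        f"range {rng}"
                    )

    @property
    def symmetric(self) -> bool:
        return self.g_hi_x == self.g_hi_y


@dataclass(frozen=True)
class StateSpace:
    """Bijection between linear indices and (n_x, n_y, s_x, s_y) tuples.

    Linearization: ``i = s_y + 4 s_x + 16 (n_y + M n_x)``, so
    N = 16 M^2 states.
    """

    M: int

    def __post_init__(self) -> None:
        if not isinstance(self.M, (int, np.integer)) or self.M < 1:
            raise ValueError(f"M must be a positive integer, got {self.M!r}")

    @property
    def n_states(self) -> int:
        return 16 * self.M * self.M

    def state_to_index(self, n_x, n_y, s_x, s_y):
        n_x = np.asarray(n_x)
        if np.any((n_x < 0) | (n_x >= self.M)):
            raise ValueError("n_x out of range")
        n_y = np.asarray(n_y)
        if np.any((n_y < 0) | (n_y >= self.M)):
            raise ValueError("n_y out of range")
        s_x, s_y = np.asarray(s_x), np.asarray(s_y)
        if np.any((s_x < 0) | (s_x > 3)) or np.any((s_y < 0) | (s_y > 3)):
            raise ValueError("promoter state out of range")
        return s_y + 4 * s_x + 16 * (n_y + self.M * n_x)

    def index_to_state(self, i):
        i = np.asarray(i)
        if np.any((i < 0) | (i >= self.n_states)):
            raise ValueError("index out of range")
        s_y = i % 4
        s_x = (i // 4) % 4
        n_y = (i // 16) % self.M
        n_x = i // (16 * self.M)
        return n_x, n_y, s_x, s_y

    def all_states(self):
        """Arrays (n_x, n_y, s_x, s_y), each of length N, in index order."""
        return self.index_to_state(np.arange(self.n_states))


def enumerate_state_space(M: int) -> StateSpace:
    """Enumerate the N = M x M x 4 x 4 joint mRNA/promoter state space."""
    return StateSpace(M)


@dataclass(frozen=True)
class GeneNetworkModel:
    """A fully specified two-gene stochastic model: logic + kinetics + cap M.

    M should satisfy g_hi/k << M - 1 so that the reflecting boundary
    carries negligible probability (default M = 21 with g_hi/k <= 7).
    """

    logic: RegulatoryLogic
    params: KineticParameters
    M: int = 21

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")

    @property
    def state_space(self) -> StateSpace:
        return enumerate_state_space(self.M)

    def synthesis_rates(self, gene: str) -> np.ndarray:
        """Transcription rate per promoter state (length-4 array)."""
        g_hi = self.params.g_hi_x if gene == "x" else self.params.g_hi_y
        return np.array(
            [g_hi if lv == "hi" else self.params.g_lo for lv in self.logic.levels]
        )


def make_misa_model(params: KineticParameters, M: int = 21) -> GeneNetworkModel:
    """Mutual-inhibition/self-activation model: self-TF binding turns the
    gene on, other-TF binding turns it off."""
    return GeneNetworkModel(RegulatoryLogic.from_motif_id(MISA_MOTIF_ID), params, M)


def make_flex_model(
    motif_id: int, params: KineticParameters, M: int = 21
) -> GeneNetworkModel:
    """One of the 16 Two-Gene Flex logic variants, sharing the MISA
    four-rate binding parameterization (h_a, f_a, h_r, f_r)."""
    return GeneNetworkModel(RegulatoryLogic.from_motif_id(motif_id), params, M)


def propensity_vector(state, model: GeneNetworkModel) -> np.ndarray:
    """Propensities of all 12 reactions from one state, ordered as REACTIONS."""
    n_x, n_y, s_x, s_y = state
    p = model.params
    M = model.M
    gx = model.synthesis_rates("x")
    gy = model.synthesis_rates("y")
    out = np.zeros(len(REACTIONS))
    # reflecting boundary: synthesis beyond M-1 has zero propensity
    out[0] = gx[s_x] if n_x < M - 1 else 0.0
    out[1] = gy[s_y] if n_y < M - 1 else 0.0
    out[2] = p.k * n_x
    out[3] = p.k * n_y
    # promoter X: self TF is x, cross TF is y; dimers bind -> h n^2 / 2
    out[4] = p.h_a * n_x**2 / 2 if not s_x & 1 else 0.0
    out[5] = p.f_a if s_x & 1 else 0.0
    out[6] = p.h_r * n_y**2 / 2 if s_x < 2 else 0.0
    out[7] = p.f_r if s_x >= 2 else 0.0
    # promoter Y: self TF is y, cross TF is x
    out[8] = p.h_a * n_y**2 / 2 if not s_y & 1 else 0.0
    out[9] = p.f_a if s_y & 1 else 0.0
    out[10] = p.h_r * n_x**2 / 2 if s_y < 2 else 0.0
    out[11] = p.f_r if s_y >= 2 else 0.0
    return out


#: State-change vectors (dn_x, dn_y, ds_x, ds_y) matching REACTIONS.
REACTION_DELTAS = np.array(
    [
        (1, 0, 0, 0), (0, 1, 0, 0), (-1, 0, 0, 0), (0, -1, 0, 0),
        (0, 0, 1, 0), (0, 0, -1, 0), (0, 0, 2, 0), (0, 0, -2, 0),
        (0, 0, 0, 1), (0, 0, 0, -1), (0, 0, 0, 2), (0, 0, 0, -2),
    ]
)


def propensity(state, reaction: str, model: GeneNetworkModel) -> float:
    """Rate (per hour) of one reaction from one (n_x, n_y, s_x, s_y) state."""
    space = model.state_space
    space.state_to_index(*state)  # validates the state
    try:
        r = REACTIONS.index(reaction)
    except ValueError:
        raise ValueError(f"unknown reaction id {reaction!r}") from None
    return float(propensity_vector(state, model)[r])


@dataclass(frozen=True)
class RateMatrix:
    """Sparse CME generator: K[l, m] = rate of m -> l, columns sum to 0."""

    K: sp.csc_matrix
    state_space: StateSpace
    model: GeneNetworkModel

    @property
    def n_states(self) -> int:
        return self.state_space.n_states


def build_rate_matrix(model: GeneNetworkModel) -> RateMatrix:
    """Assemble the sparse generator of the master equation.

    Vectorized over the whole state space: for each reaction class a
    source mask, destination offset and rate array are computed at
    once. Zero-rate transitions are dropped, so structurally disabled
    reactions leave no explicit entries.
    """
    space = model.state_space
    M = space.M
    N = space.n_states
    p = model.params
    n_x, n_y, s_x, s_y = space.all_states()
    gx = model.synthesis_rates("x")
    gy = model.synthesis_rates("y")

    rows, cols, vals = [], [], []

    def add(mask, offset, rate):
        idx = np.nonzero(mask & (rate > 0))[0]
        cols.append(idx)
        rows.append(idx + offset)
        vals.append(rate[idx] if rate.shape else np.full(idx.size, rate))

    add(n_x < M - 1, 16 * M, gx[s_x])
    add(n_y < M - 1, 16, gy[s_y])
    add(n_x > 0, -16 * M, p.k * n_x)
    add(n_y > 0, -16, p.k * n_y)
    add((s_x & 1) == 0, 4, p.h_a * n_x**2 / 2)
    add((s_x & 1) == 1, -4, np.full(N, p.f_a))
    add(s_x < 2, 8, p.h_r * n_y**2 / 2)
    add(s_x >= 2, -8, np.full(N, p.f_r))
    add((s_y & 1) == 0, 1, p.h_a * n_y**2 / 2)
    add((s_y & 1) == 1, -1, np.full(N, p.f_a))
    add(s_y < 2, 2, p.h_r * n_x**2 / 2)
    add(s_y >= 2, -2, np.full(N, p.f_r))

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    K = sp.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsc()
    K = K - sp.diags(np.asarray(K.sum(axis=0)).ravel(), format="csc")
    return RateMatrix(K=K, state_space=space, model=model)


def gene_swap_permutation(space: StateSpace) -> np.ndarray:
    """Index permutation induced by relabeling X <-> Y."""
    n_x, n_y, s_x, s_y = space.all_states()
    return np.asarray(space.state_to_index(n_y, n_x, s_y, s_x))
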