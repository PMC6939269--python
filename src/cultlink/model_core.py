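"""Core domain types, pay-offs, and interaction-partner choice.

The model: a well-mixed population of ``N`` individuals, each carrying one of
``k`` discrete variants at each of ``h`` cultural traits (the cultural
analogue of alleles at loci), plus a private, symmetric link graph over its
traits. Variant ``1`` of a functional trait gives the highest pay-off and
variant ``k`` the lowest; the per-trait pay-off gap is ``s_i``. Individuals
choose whom to copy from under one of three rules: unbiased (uniform over the
other N-1), pay-off-biased (proportional to total pay-off), or
conformist-biased (weight ``1 - s_kappa * (1 - q_r)`` in the frequency
``q_r`` of the candidate's variant — a linear discount of rare-variant
carriers that reduces to unbiased choice at ``s_kappa = 0``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels as _k

logger = logging.getLogger(__name__)

TRANSMISSION_MODES = {
    "unbiased": _k.UNBIASED,
    "payoff": _k.PAYOFF,
    "conformist": _k.CONFORMIST,
}


@dataclass
class SimulationParams:
    """All constants of one simulation run.

    Parameters
    ----------
    N : population size (individuals; never changes during a run).
    h : number of cultural traits per individual.
    k : number of variants per trait.
    s : length-h vector of maximum pay-off differences, each in [0, 1];
        a neutral trait has ``s_i = 0``.
    a : probability per timestep that any currently unlinked trait pair of an
        individual forms a link.
    b : probability that a link offered inside a transmitted package is
        *not* acquired (links are copied at rate ``1 - b``).
    c : probability that each variant in a package is copied successfully.
    mu : per-trait innovation probability per timestep; an innovating trait
        switches to one of the other ``k - 1`` variants uniformly.
    s_kappa : conformity strength (only used in conformist mode).
    transmission_mode : "unbiased", "payoff", or "conformist".
    burn_in_steps, post_steps : run-phase lengths in timesteps.
    n_fixed : when not None, the fixed-package control mode — each focal
        copies exactly ``n_fixed`` random distinct traits and all link
        dynamics are disabled.
    shared_link_breakage : sensitivity switch; when True, links shared by
        both individuals inside a transmitted package are re-tested and kept
        only w.p. ``1 - b`` instead of being kept with certainty (the default
        outcome-table rule).
    seed : RNG seed; replicate_id: integer label for bookkeeping.
    """

    N: int = 1000
    h: int = 5
    k: int = 4
    s: tuple = None
    a: float = 0.0
    b: float = 0.0
    c: float = 0.99
    mu: float = 0.01
    s_kappa: float = 0.0
    transmission_mode: str = "unbiased"
    burn_in_steps: int = 5000
    post_steps: int = 2000
    n_fixed: int | None = None
    shared_link_breakage: bool = False
    seed: int | None = None
    replicate_id: int = 0

    def __post_init__(self):
        if self.s is None:
            self.s = (0.0,) * self.h
        self.s = tuple(float(x) for x in np.atleast_1d(self.s))
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.h < 1:
            raise ValueError("h must be at least 1")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if len(self.s) != self.h:
            raise ValueError("s must have one entry per trait")
        for name in ("a", "b", "c", "mu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if any(not 0.0 <= x <= 1.0 for x in self.s):
            raise ValueError("every s_i must lie in [0, 1]")
        if not 0.0 <= self.s_kappa <= 1.0:
            raise ValueError("s_kappa must lie in [0, 1] (0 = unbiased)")
        if self.transmission_mode not in TRANSMISSION_MODES:
            raise ValueError(f"unknown transmission_mode {self.transmission_mode!r}")
        if self.transmission_mode == "conformist" and self.h != 1:
            raise ValueError("conformist mode is defined for a single trait (h = 1)")
        if self.n_fixed is not None and not 0 <= self.n_fixed <= self.h:
            raise ValueError("n_fixed must be in {0, ..., h}")
        if self.burn_in_steps < 0 or self.post_steps < 0:
            raise ValueError("phase lengths must be nonnegative")

    @property
    def s_array(self) -> np.ndarray:
        return np.asarray(self.s, dtype=np.float64)

    @property
    def mode_code(self) -> int:
        return TRANSMISSION_MODES[self.transmission_mode]

    def with_(self, **kwargs) -> "SimulationParams":
        """A copy with some fields replaced (revalidated)."""
        return replace(self, **kwargs)


@dataclass
class PopulationState:
    """Variant assignments and per-individual trait-link graphs.

    ``variants``: (N, h) integers in {1, ..., k}. ``links``: (N, h, h)
    boolean, symmetric with a false diagonal. ``t``: current timestep.
    """

    variants: np.ndarray
    links: np.ndarray
    t: int = 0

    def __post_init__(self):
        self.variants = np.asarray(self.variants, dtype=np.int64)
        self.links = np.asarray(self.links, dtype=np.bool_)
        if self.variants.ndim != 2:
            raise ValueError("variants must be an (N, h) matrix")
        n, h = self.variants.shape
        if self.links.shape != (n, h, h):
            raise ValueError("links must have shape (N, h, h)")
        self.validate()

    @property
    def N(self) -> int:
        return self.variants.shape[0]

    @property
    def h(self) -> int:
        return self.variants.shape[1]

    def validate(self, k: int | None = None) -> None:
        if self.variants.min() < 1:
            raise ValueError("variants must be 1-based positive integers")
        if k is not None and self.variants.max() > k:
            raise ValueError("variant labels exceed k")
        if not np.array_equal(self.links, self.links.transpose(0, 2, 1)):
            raise ValueError("each link graph must be symmetric")
        if self.links[:, range(self.h), range(self.h)].any():
            raise ValueError("self-links are not allowed")

    def copy(self) -> "PopulationState":
        return PopulationState(self.variants.copy(), self.links.copy(), self.t)


@dataclass
class PartnerChoice:
    """The chosen interaction partner of each focal individual (never self)."""

    partner_index: np.ndarray

    def __post_init__(self):
        self.partner_index = np.asarray(self.partner_index, dtype=np.int64)
        if (self.partner_index == np.arange(self.partner_index.shape[0])).any():
            raise ValueError("an individual cannot choose itself")


def variant_payoff(i: int, j: int, params: SimulationParams) -> float:
    """Pay-off of variant ``j`` (1-based) at trait ``i`` (1-based).

    ``1 - ((j - 1) / (k - 1)) * s_i``: variant 1 always pays 1, variant k
    pays ``1 - s_i``, and a neutral trait (``s_i = 0``) pays 1 throughout.
    """
    if not 1 <= i <= params.h:
        raise ValueError(f"trait index {i} outside 1..{params.h}")
    if not 1 <= j <= params.k:
        raise ValueError(f"variant index {j} outside 1..{params.k}")
    return 1.0 - (j - 1) / (params.k - 1) * params.s[i - 1]


def individual_payoff(r: int, state: PopulationState, params: SimulationParams) -> float:
    """Total pay-off of individual ``r``: the product over traits of its variant pay-offs."""
    if not 0 <= r < state.N:
        raise ValueError(f"individual index {r} outside 0..{state.N - 1}")
    row = state.variants[r : r + 1]
    return float(_k.payoffs(row, params.s_array, params.k)[0])


def population_payoffs(state: PopulationState, params: SimulationParams) -> np.ndarray:
    """Pay-offs of all individuals at once."""
    return _k.payoffs(state.variants, params.s_array, params.k)


def partner_probabilities(state: PopulationState, params: SimulationParams) -> np.ndarray:
    """Row-stochastic (N, N) matrix of partner-choice probabilities.

    Row ``r`` is the probability distribution over the interaction partner of
    focal individual ``r``: zero on the diagonal (self is excluded) and
    proportional to the mode's weights over the other N - 1 candidates,
    evaluated on the current state snapshot.
    """
    if params.transmission_mode == "conformist" and state.h != 1:
        raise ValueError("conformist mode requires h = 1")
    w = _k.partner_weights(
        state.variants, params.s_array, params.k, params.mode_code, params.s_kappa
    )
    n = state.N
    mat = np.tile(w, (n, 1))
    np.fill_diagonal(mat, 0.0)
    rowsum = mat.sum(axis=1)
    degenerate = rowsum <= 0.0
    if degenerate.any():
        logger.warning(
            "all candidate weights zero for %d focal individuals; "
            "falling back to unbiased choice", int(degenerate.sum()),
        )
        mat[degenerate] = 1.0
        np.fill_diagonal(mat, 0.0)
        rowsum = mat.sum(axis=1)
    return mat / rowsum[:, None]


def choose_partners(
    state: PopulationState, params: SimulationParams, rng: np.random.Generator
) -> PartnerChoice:
    """Draw every focal individual's partner independently from its probability row."""
    w = _k.partner_weights(
        state.variants, params.s_array, params.k, params.mode_code, params.s_kappa
    )
    return PartnerChoice(_k.sample_partners(w, rng))
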