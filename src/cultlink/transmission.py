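"""One timestep of cultural change.

Transmission is package-based: the focal individual picks one trait to copy,
and the interaction partner demonstrates that trait together with every trait
directly or indirectly linked to it *in the partner's own link graph* — the
connected component of the chosen trait. Each variant in the package is
copied with probability ``c``; each in-package link the partner has and the
focal lacks is acquired with probability ``1 - b``; in-package links only the
focal has are broken, as are all focal links crossing the package boundary;
links with both ends outside the package are untouched. After transmission,
unlinked trait pairs form links at rate ``a`` and each trait innovates with
probability ``mu``.

All public operations here are functional: they return new objects and leave
their inputs untouched. The update within a timestep is synchronous — every
read is from the start-of-step snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .model_core import PopulationState, SimulationParams, choose_partners


@dataclass(frozen=True)
class Package:
    """The bundle of traits transmitted together in one interaction.

    ``member_traits`` is exactly the connected component of ``focal_trait``
    in the demonstrating partner's link graph (0-based trait indices).
    """

    focal_trait: int
    member_traits: frozenset

    def __post_init__(self):
        if self.focal_trait not in self.member_traits:
            raise ValueError("the chosen trait is always part of its package")

    def member_mask(self, h: int) -> np.ndarray:
        m = np.zeros(h, dtype=np.bool_)
        m[list(self.member_traits)] = True
        return m


def package_of(trait: int, partner_links: np.ndarray) -> Package:
    """Connected component of ``trait`` (0-based) in one link graph (h, h)."""
    partner_links = np.asarray(partner_links, dtype=np.bool_)
    h = partner_links.shape[0]
    if partner_links.shape != (h, h) or not np.array_equal(partner_links, partner_links.T):
        raise ValueError("partner_links must be a symmetric (h, h) matrix")
    if not 0 <= trait < h:
        raise ValueError(f"trait index {trait} outside 0..{h - 1}")
    member = np.zeros(h, dtype=np.bool_)
    _k.component_members(partner_links, trait, member)
    return Package(trait, frozenset(np.flatnonzero(member).tolist()))


def transmit_variants(
    focal: int,
    partner: int,
    package: Package,
    state: PopulationState,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """The focal individual's variants after one copying attempt.

    Each in-package trait independently adopts the partner's (snapshot)
    variant with probability ``c``; out-of-package traits are unchanged.
    Copying is blind to pay-offs.
    """
    member = package.member_mask(state.h)
    new = state.variants[focal].copy()
    _k.transmit_variants_one(new, state.variants[partner], member, params.c, rng.random(state.h))
    return new


def transmit_links(
    focal_links: np.ndarray,
    partner_links: np.ndarray,
    package: Package,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """The focal individual's link graph after one transmission event."""
    focal_links = np.asarray(focal_links, dtype=np.bool_)
    partner_links = np.asarray(partner_links, dtype=np.bool_)
    h = focal_links.shape[0]
    member = package.member_mask(h)
    new = focal_links.copy()
    npairs = h * (h - 1) // 2
    _k.transmit_links_one(new, partner_links, member, params.b,
                          rng.random(npairs), params.shared_link_breakage)
    return new


def form_links(
    state: PopulationState, params: SimulationParams, rng: np.random.Generator
) -> PopulationState:
    """Add a link, w.p. ``a``, to each currently unlinked trait pair of each individual."""
    out = state.copy()
    _k.form_links_all(out.links, params.a, rng)
    return out


def innovate(
    state: PopulationState, params: SimulationParams, rng: np.random.Generator
) -> PopulationState:
    """Each trait of each individual switches, w.p. ``mu``, to one of the
    other ``k - 1`` variants chosen uniformly (transition rate mu/(k-1) per
    ordered variant pair). Links are unaffected."""
    out = state.copy()
    _k.innovate_all(out.variants, params.k, params.mu, rng)
    return out


def step(
    state: PopulationState, params: SimulationParams, rng: np.random.Generator
) -> PopulationState:
    """One full synchronous timestep; returns the next state.

    Stage order: partner choice on the snapshot; per-focal package
    transmission (variants then links, all reads from the snapshot); link
    formation; innovation; increment ``t``. With ``params.n_fixed`` set, the
    fixed-package control replaces the package stages and link dynamics are
    skipped entirely.
    """
    out = state.copy()
    if params.n_fixed is not None:
        _k.fixed_package_step(
            out.variants, params.s_array, params.k, params.mode_code,
            params.s_kappa, params.n_fixed, params.c, params.mu, rng,
        )
    else:
        _k.step(
            out.variants, out.links, params.s_array, params.k, params.mode_code,
            params.s_kappa, params.a, params.b, params.c, params.mu, rng,
            params.shared_link_breakage,
        )
    out.t = state.t + 1
    return out


def fixed_package_step(
    state: PopulationState, params: SimulationParams, rng: np.random.Generator
) -> PopulationState:
    """Control dynamic: each focal copies ``n_fixed`` random distinct traits
    from its partner (each w.p. ``c``), then innovation; links are ignored.

    ``n_fixed = 0`` means no transmission at all; ``n_fixed = h`` offers every
    trait (with ``c = 1`` the focal becomes an exact copy of its partner).
    """
    if params.n_fixed is None:
        raise ValueError("fixed_package_step requires params.n_fixed to be set")
    out = state.copy()
    _k.fixed_package_step(
        out.variants, params.s_array, params.k, params.mode_code,
        params.s_kappa, params.n_fixed, params.c, params.mu, rng,
    )
    out.t = state.t + 1
    return out


__all__ = [
    "Package",
    "package_of",
    "transmit_variants",
    "transmit_links",
    "form_links",
    "innovate",
    "step",
    "fixed_package_step",
    "choose_partners",
]
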