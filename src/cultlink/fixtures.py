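"""Deterministic small-population fixtures and brute-force oracles.

Everything here exists so that each dynamic rule and statistic can be checked
exactly, without large stochastic simulations: a hand-built two-individual
configuration exercising every row of the link-outcome table, a pair-by-pair
enumeration of the pairwise difference, and an exact Markov-chain enumeration
of the full timestep for two individuals (where partner choice is forced and
every random outcome can be enumerated with its probability).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model_core import PopulationState, SimulationParams


@dataclass
class FixturePopulation:
    """A fully specified small population (no randomness)."""

    variants: np.ndarray  # (N, h), 1-based
    link_pairs: list  # per individual: list of (i, j) 0-based trait pairs
    label: str = ""

    def to_json(self) -> str:
        """Plain-JSON form (variant matrix, link pairs, label) for inspection."""
        import json

        return json.dumps({
            "label": self.label,
            "variants": np.asarray(self.variants).tolist(),
            "link_pairs": [[list(pr) for pr in pairs] for pairs in self.link_pairs],
        }, indent=2)

    def state(self) -> PopulationState:
        variants = np.asarray(self.variants, dtype=np.int64)
        n, h = variants.shape
        links = np.zeros((n, h, h), dtype=np.bool_)
        for r, pairs in enumerate(self.link_pairs):
            for i, j in pairs:
                links[r, i, j] = True
                links[r, j, i] = True
        return PopulationState(variants, links, t=0)


def fig1_fixture() -> FixturePopulation:
    """Two individuals arranged so one transmission event hits every link rule.

    Individual 0 is the focal, individual 1 the partner. With chosen trait 0
    the partner's package is {0, 1, 2} (links (0,1) and (1,2)). The focal has
    an in-package link the partner lacks ((0,2): broken), shares (1,2) (kept
    for any b), lacks (0,1) (acquired w.p. 1-b), carries the boundary-crossing
    (2,3) (always lost) and the fully-outside (3,4) (always untouched).
    """
    variants = [
        [2, 2, 2, 2, 2],  # focal
        [1, 3, 4, 1, 3],  # partner
    ]
    link_pairs = [
        [(0, 2), (1, 2), (2, 3), (3, 4)],  # focal
        [(0, 1), (1, 2)],  # partner
    ]
    return FixturePopulation(np.array(variants), link_pairs, label="link-outcome table")


def brute_force_pairwise(state: PopulationState, trait: int) -> float:
    """π at ``trait`` (1-based) by enumerating all unordered individual pairs."""
    if state.N > 1000:
        raise ValueError("brute-force enumeration is for small populations")
    v = state.variants[:, trait - 1]
    n = state.N
    diff = 0
    for r in range(n):
        for q in range(r + 1, n):
            if v[r] != v[q]:
                diff += 1
    return diff / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# exact two-individual Markov chain
# ---------------------------------------------------------------------------

def _component(links: frozenset, trait: int, h: int) -> frozenset:
    member = {trait}
    changed = True
    while changed:
        changed = False
        for (i, j) in links:
            if i in member and j not in member:
                member.add(j)
                changed = True
            elif j in member and i not in member:
                member.add(i)
                changed = True
    return frozenset(member)


class TwoIndividualOracle:
    """Exact one-step transition law of the model for N = 2.

    With two individuals, partner choice is forced (each copies from the
    other regardless of transmission bias), so a timestep is fully enumerable:
    trait choice (uniform over h), per-trait copy successes (c), in-package
    link acquisitions (1-b), link formation (a) and innovation (mu, uniform
    over the other k-1 variants). Restricted to h <= 2 and k <= 3 to keep the
    state space exactly enumerable.

    A state is ``(variants, links)`` with ``variants`` a pair of h-tuples
    (1-based) and ``links`` a pair of frozensets of 0-based trait pairs.
    """

    def __init__(self, params: SimulationParams):
        if params.N != 2:
            raise ValueError("the exact oracle is defined for N = 2")
        if params.h > 2 or params.k > 3:
            raise ValueError("state space too large for exact enumeration")
        if params.n_fixed is not None:
            raise ValueError("the oracle covers the full link dynamic only")
        self.params = params
        self.h = params.h
        self.k = params.k
        self._pairs = [
            (i, j) for i in range(self.h) for j in range(i + 1, self.h)
        ]

    # -- state space --------------------------------------------------------
    def state_space(self) -> list:
        h, k = self.h, self.k
        variant_rows = list(itertools.product(range(1, k + 1), repeat=h))
        linksets = [
            frozenset(sub)
            for n_take in range(len(self._pairs) + 1)
            for sub in itertools.combinations(self._pairs, n_take)
        ]
        return [
            ((v0, v1), (l0, l1))
            for v0 in variant_rows
            for v1 in variant_rows
            for l0 in linksets
            for l1 in linksets
        ]

    @staticmethod
    def from_population(state: PopulationState):
        v = tuple(tuple(int(x) for x in row) for row in state.variants)
        links = []
        h = state.h
        for r in range(2):
            pairs = frozenset(
                (i, j) for i in range(h) for j in range(i + 1, h) if state.links[r, i, j]
            )
            links.append(pairs)
        return (v, (links[0], links[1]))

    # -- one focal individual's transmission outcome ------------------------
    def _focal_outcomes(self, focal_v, partner_v, focal_l, partner_l):
        """Distribution over (new_variants, new_links) for one focal."""
        p = self.params
        out = {}
        for trait in range(self.h):
            p_trait = 1.0 / self.h
            member = _component(partner_l, trait, self.h)
            # variant copy outcomes: each member trait adopts w.p. c
            copy_sets = []
            member_list = sorted(member)
            for copied in itertools.product([False, True], repeat=len(member_list)):
                prob = 1.0
                for success in copied:
                    prob *= p.c if success else (1.0 - p.c)
                newv = list(focal_v)
                for t_i, success in zip(member_list, copied):
                    if success:
                        newv[t_i] = partner_v[t_i]
                copy_sets.append((tuple(newv), prob))
            # link outcomes: pairs that persist/arrive w.p. 1-b vs certain
            acquirable = [
                pr for pr in self._pairs
                if pr[0] in member and pr[1] in member
                and pr in partner_l
                and (pr not in focal_l or p.shared_link_breakage)
            ]
            base_links = set()
            for pr in self._pairs:
                inside = pr[0] in member and pr[1] in member
                crossing = (pr[0] in member) != (pr[1] in member)
                if inside:
                    if pr in partner_l and pr in focal_l and not p.shared_link_breakage:
                        base_links.add(pr)  # shared: kept with certainty
                elif not crossing and pr in focal_l:
                    base_links.add(pr)  # fully outside: untouched
                # crossing focal links are always lost; inside-only-focal broken
            link_sets = []
            for gained in itertools.product([False, True], repeat=len(acquirable)):
                prob = 1.0
                newl = set(base_links)
                for pr, g in zip(acquirable, gained):
                    if g:
                        prob *= 1.0 - p.b
                        newl.add(pr)
                    else:
                        prob *= p.b
                link_sets.append((frozenset(newl), prob))
            for newv, pv in copy_sets:
                for newl, pl in link_sets:
                    key = (newv, newl)
                    out[key] = out.get(key, 0.0) + p_trait * pv * pl
        return out

    def _form_links_outcomes(self, links: frozenset):
        p = self.params
        free = [pr for pr in self._pairs if pr not in links]
        out = {}
        for added in itertools.product([False, True], repeat=len(free)):
            prob = 1.0
            newl = set(links)
            for pr, addit in zip(free, added):
                if addit:
                    prob *= p.a
                    newl.add(pr)
                else:
                    prob *= 1.0 - p.a
            key = frozenset(newl)
            out[key] = out.get(key, 0.0) + prob
        return out

    def _innovate_outcomes(self, variants: tuple):
        p = self.params
        per_trait = []
        for v in variants:
            opts = [(v, 1.0 - p.mu)]
            for alt in range(1, self.k + 1):
                if alt != v:
                    opts.append((alt, p.mu / (self.k - 1)))
            per_trait.append(opts)
        out = {}
        for combo in itertools.product(*per_trait):
            newv = tuple(v for v, _ in combo)
            prob = 1.0
            for _, pr in combo:
                prob *= pr
            out[newv] = out.get(newv, 0.0) + prob
        return out

    # -- full step ----------------------------------------------------------
    def step_distribution(self, state) -> dict:
        """Exact distribution over states after one synchronous timestep."""
        (v0, v1), (l0, l1) = state
        o0 = self._focal_outcomes(v0, v1, l0, l1)
        o1 = self._focal_outcomes(v1, v0, l1, l0)
        out = {}
        for (nv0, nl0), p0 in o0.items():
            f0 = self._form_links_outcomes(nl0)
            i0 = self._innovate_outcomes(nv0)
            for (nv1, nl1), p1 in o1.items():
                f1 = self._form_links_outcomes(nl1)
                i1 = self._innovate_outcomes(nv1)
                for fl0, pf0 in f0.items():
                    for fl1, pf1 in f1.items():
                        for iv0, pi0 in i0.items():
                            for iv1, pi1 in i1.items():
                                key = ((iv0, iv1), (fl0, fl1))
                                prob = p0 * p1 * pf0 * pf1 * pi0 * pi1
                                if prob > 0.0:
                                    out[key] = out.get(key, 0.0) + prob
        return out

    def transition_matrix(self):
        """(states, T) with T[i, j] = P(state_j | state_i)."""
        states = self.state_space()
        index = {s: i for i, s in enumerate(states)}
        T = np.zeros((len(states), len(states)))
        for i, s in enumerate(states):
            for s2, pr in self.step_distribution(s).items():
                T[i, index[s2]] += pr
        return states, T

    def distribution_after(self, state, n_steps: int) -> dict:
        """State distribution after ``n_steps`` exact steps from ``state``."""
        dist = {state: 1.0}
        for _ in range(n_steps):
            nxt = {}
            for s, pr in dist.items():
                for s2, pr2 in self.step_distribution(s).items():
                    nxt[s2] = nxt.get(s2, 0.0) + pr * pr2
            dist = nxt
        return dist


def two_individual_markov_oracle(params: SimulationParams) -> TwoIndividualOracle:
    """Exact enumeration oracle for the N = 2 dynamics (h <= 2, small k)."""
    return TwoIndividualOracle(params)
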