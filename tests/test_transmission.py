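"""Package construction, variant/link transmission, link formation, innovation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cultlink as cl
from cultlink.fixtures import fig1_fixture
from conftest import state_from


def links_of(pairs, h=5):
    m = np.zeros((h, h), dtype=np.bool_)
    for i, j in pairs:
        m[i, j] = m[j, i] = True
    return m


class TestPackageOf:
    def test_isolated_trait_is_singleton(self):
        assert cl.package_of(3, links_of([])).member_traits == {3}

    def test_indirect_connection_included(self):
        pkg = cl.package_of(0, links_of([(0, 1), (1, 2)]))
        assert pkg.member_traits == {0, 1, 2}

    def test_matches_brute_force_reachability(self):
        links = links_of([(0, 1), (3, 4)])
        assert cl.package_of(3, links).member_traits == {3, 4}
        assert cl.package_of(2, links).member_traits == {2}

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_component_property(self, data):
        """Package equals the transitive closure over the partner's links."""
        h = data.draw(st.integers(2, 6))
        pairs = data.draw(st.lists(
            st.tuples(st.integers(0, h - 1), st.integers(0, h - 1)).filter(lambda p: p[0] != p[1]),
            max_size=8))
        trait = data.draw(st.integers(0, h - 1))
        links = links_of(pairs, h)
        member = cl.package_of(trait, links).member_traits
        # brute force: grow the reachable set to a fixed point
        reach = {trait}
        for _ in range(h):
            reach |= {j for i in reach for j in range(h) if links[i, j]}
        assert member == reach


class TestTransmitVariants:
    def test_certain_copying(self, rng):
        state = fig1_fixture().state()
        p = cl.SimulationParams(N=2, h=5, k=4, c=1.0)
        pkg = cl.package_of(0, state.links[1])
        new = cl.transmit_variants(0, 1, pkg, state, p, rng)
        assert new[:3].tolist() == state.variants[1, :3].tolist()
        assert new[3:].tolist() == state.variants[0, 3:].tolist()

    def test_no_copying(self, rng):
        state = fig1_fixture().state()
        p = cl.SimulationParams(N=2, h=5, k=4, c=0.0)
        pkg = cl.package_of(0, state.links[1])
        new = cl.transmit_variants(0, 1, pkg, state, p, rng)
        assert new.tolist() == state.variants[0].tolist()

    def test_copy_rate_matches_bernoulli(self, rng):
        """Single-trait package adoption fraction ~ c within binomial error."""
        c = 0.99
        p = cl.SimulationParams(N=2, h=1, k=2, c=c)
        state = state_from([[1], [2]])
        pkg = cl.package_of(0, state.links[1])
        m = 20000
        adopted = sum(
            cl.transmit_variants(0, 1, pkg, state, p, rng)[0] == 2 for _ in range(m)
        )
        se = np.sqrt(c * (1 - c) / m)
        assert abs(adopted / m - c) < 5 * se


class TestTransmitLinks:
    """Each row of the link-outcome table, on the two-individual fixture."""

    @pytest.fixture
    def fix(self):
        state = fig1_fixture().state()
        pkg = cl.package_of(0, state.links[1])
        return state, pkg

    def test_package_is_partner_component(self, fix):
        _, pkg = fix
        assert pkg.member_traits == {0, 1, 2}

    def test_b_zero_copies_partner_links_inside_package(self, fix, rng):
        state, pkg = fix
        p = cl.SimulationParams(N=2, h=5, k=4, b=0.0)
        new = cl.transmit_links(state.links[0], state.links[1], pkg, p, rng)
        # inside the package, focal now equals partner exactly (subset law)
        inside = [0, 1, 2]
        assert np.array_equal(new[np.ix_(inside, inside)],
                              state.links[1][np.ix_(inside, inside)])

    def test_boundary_crossing_link_always_lost(self, fix, rng):
        state, pkg = fix
        for b in (0.0, 0.5, 1.0):
            p = cl.SimulationParams(N=2, h=5, k=4, b=b)
            new = cl.transmit_links(state.links[0], state.links[1], pkg, p, rng)
            assert not new[2, 3] and not new[3, 2]

    def test_outside_link_untouched(self, fix, rng):
        state, pkg = fix
        p = cl.SimulationParams(N=2, h=5, k=4, b=1.0)
        new = cl.transmit_links(state.links[0], state.links[1], pkg, p, rng)
        assert new[3, 4] and new[4, 3]

    def test_shared_link_survives_any_b(self, fix, rng):
        state, pkg = fix
        for b in (0.0, 1.0):
            p = cl.SimulationParams(N=2, h=5, k=4, b=b)
            new = cl.transmit_links(state.links[0], state.links[1], pkg, p, rng)
            assert new[1, 2] and new[2, 1]

    def test_shared_link_retested_under_sensitivity_flag(self, fix, rng):
        """With shared_link_breakage, a shared in-package link survives only
        w.p. 1-b: at b=1 it is always lost, at b=0 always kept."""
        state, pkg = fix
        p = cl.SimulationParams(N=2, h=5, k=4, b=1.0, shared_link_breakage=True)
        new = cl.transmit_links(state.links[0], state.links[1], pkg, p, rng)
        assert not new[1, 2]
        p = cl.SimulationParams(N=2, h=5, k=4, b=0.0, shared_link_breakage=True)
        new = cl.transmit_links(state.links[0], state.links[1], pkg, p, rng)
        assert new[1, 2]

    def test_focal_only_in_package_link_broken(self, fix, rng):
        state, pkg = fix
        p = cl.SimulationParams(N=2, h=5, k=4, b=0.0)
        new = cl.transmit_links(state.links[0], state.links[1], pkg, p, rng)
        assert not new[0, 2]

    def test_b_one_acquires_nothing(self, fix, rng):
        state, pkg = fix
        p = cl.SimulationParams(N=2, h=5, k=4, b=1.0)
        new = cl.transmit_links(state.links[0], state.links[1], pkg, p, rng)
        # (0,1): only partner had it; with b=1 it is never acquired; (0,2)
        # broken; (1,2) shared kept -> exactly one in-package link remains
        assert not new[0, 1]
        assert not new[0, 2]
        assert new[1, 2]

    def test_acquisition_rate(self, fix, rng):
        """The partner-only in-package link (0,1) is gained w.p. 1-b."""
        state, pkg = fix
        b = 0.3
        p = cl.SimulationParams(N=2, h=5, k=4, b=b)
        m = 10000
        gained = sum(
            cl.transmit_links(state.links[0], state.links[1], pkg, p, rng)[0, 1]
            for _ in range(m)
        )
        se = np.sqrt(b * (1 - b) / m)
        assert abs(gained / m - (1 - b)) < 5 * se

    def test_result_symmetric_no_boundary_links(self, fix, rng):
        state, pkg = fix
        p = cl.SimulationParams(N=2, h=5, k=4, b=0.4)
        new = cl.transmit_links(state.links[0], state.links[1], pkg, p, rng)
        assert np.array_equal(new, new.T)
        member = pkg.member_mask(5)
        crossing = new[np.ix_(member, ~member)]
        assert not crossing.any()


class TestFormLinks:
    def test_zero_rate_no_change(self, small_params, rng):
        state = state_from(np.ones((4, 5), dtype=int))
        new = cl.form_links(state, small_params.with_(a=0.0), rng)
        assert not new.links.any()

    def test_rate_one_completes_all_graphs(self, small_params, rng):
        state = state_from(np.ones((4, 5), dtype=int))
        new = cl.form_links(state, small_params.with_(a=1.0), rng)
        offdiag = ~np.eye(5, dtype=bool)
        assert new.links[:, offdiag].all()

    def test_expected_new_links(self, rng):
        """a=0.05, 10 pairs: mean new links per individual ~ 0.5."""
        p = cl.SimulationParams(N=2000, h=5, k=4, a=0.05)
        state = state_from(np.ones((2000, 5), dtype=int))
        new = cl.form_links(state, p, rng)
        per_ind = new.links.sum(axis=(1, 2)) / 2
        se = np.sqrt(10 * 0.05 * 0.95 / 2000)
        assert abs(per_ind.mean() - 0.5) < 5 * se


class TestInnovate:
    def test_zero_rate_no_change(self, small_params, rng):
        state = state_from(np.full((6, 5), 2))
        new = cl.innovate(state, small_params.with_(mu=0.0), rng)
        assert np.array_equal(new.variants, state.variants)

    def test_forced_switch_two_variants(self, rng):
        """mu=1, k=2: every variant flips deterministically."""
        p = cl.SimulationParams(N=6, h=3, k=2, mu=1.0)
        state = state_from(np.full((6, 3), 1))
        new = cl.innovate(state, p, rng)
        assert (new.variants == 2).all()

    def test_transition_rate_between_specific_variants(self, rng):
        """Per-step probability of moving 2 -> 3 is mu/(k-1); never 2 -> 2."""
        mu, k = 0.3, 4
        p = cl.SimulationParams(N=30000, h=1, k=k, mu=mu)
        state = state_from(np.full((30000, 1), 2))
        new = cl.innovate(state, p, rng)
        frac3 = (new.variants == 3).mean()
        expected = mu / (k - 1)
        se = np.sqrt(expected * (1 - expected) / 30000)
        assert abs(frac3 - expected) < 5 * se
        stayed = (new.variants == 2).mean()
        assert abs(stayed - (1 - mu)) < 5 * np.sqrt(mu * (1 - mu) / 30000)


class TestStep:
    def test_no_link_source_stays_linkless(self, rng):
        p = cl.SimulationParams(N=10, h=5, k=4, a=0.0, b=0.5, c=0.9, mu=0.05)
        state = state_from(rng.integers(1, 5, (10, 5)))
        for _ in range(20):
            state = cl.step(state, p, rng)
        assert not state.links.any()
        assert state.t == 20

    def test_two_individual_fixation(self, rng):
        """N=2, h=1, c=1, mu=0: variants stay within the initial pair and the
        chain visits only swap/fixation states."""
        p = cl.SimulationParams(N=2, h=1, k=2, c=1.0, mu=0.0)
        state = state_from([[1], [2]])
        seen = set()
        for _ in range(10):
            state = cl.step(state, p, rng)
            seen.add(tuple(state.variants[:, 0]))
        assert seen <= {(1, 2), (2, 1), (1, 1), (2, 2)}

    def test_seeded_determinism(self, small_params):
        state = state_from(np.arange(1, 5)[np.random.default_rng(0).integers(0, 4, (20, 5))])
        out1 = cl.step(state, small_params, np.random.default_rng(99))
        out2 = cl.step(state, small_params, np.random.default_rng(99))
        assert np.array_equal(out1.variants, out2.variants)
        assert np.array_equal(out1.links, out2.links)

    def test_input_state_untouched(self, small_params, rng):
        state = state_from(np.full((20, 5), 2), [[(0, 1)]] * 20)
        before_v = state.variants.copy()
        before_l = state.links.copy()
        cl.step(state, small_params, rng)
        assert np.array_equal(state.variants, before_v)
        assert np.array_equal(state.links, before_l)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_invariants_after_step(self, seed):
        """Symmetry, no self-links, variant domain closure, package-boundary law."""
        rng = np.random.default_rng(seed)
        p = cl.SimulationParams(N=12, h=5, k=4, a=0.2, b=0.3, c=0.7, mu=0.1)
        variants = rng.integers(1, 5, (12, 5))
        links = rng.random((12, 5, 5)) < 0.4
        links &= links.transpose(0, 2, 1)
        links[:, range(5), range(5)] = False
        state = cl.PopulationState(variants, links)
        new = cl.step(state, p, rng)
        new.validate(k=4)
        assert new.variants.min() >= 1 and new.variants.max() <= 4


class TestFixedPackageStep:
    def test_zero_traits_only_innovation(self, rng):
        p = cl.SimulationParams(N=10, h=5, k=4, n_fixed=0, mu=0.0, c=1.0)
        state = state_from(np.full((10, 5), 3))
        new = cl.fixed_package_step(state, p, rng)
        assert np.array_equal(new.variants, state.variants)

    def test_all_traits_certain_copy_clones_partner(self, rng):
        p = cl.SimulationParams(N=2, h=5, k=4, n_fixed=5, c=1.0, mu=0.0)
        state = state_from([[1, 2, 3, 4, 1], [4, 3, 2, 1, 4]])
        new = cl.fixed_package_step(state, p, rng)
        # with N=2 each copies the other completely: a full swap
        assert new.variants[0].tolist() == [4, 3, 2, 1, 4]
        assert new.variants[1].tolist() == [1, 2, 3, 4, 1]

    def test_requires_n_fixed(self, small_params, rng):
        state = state_from(np.full((20, 5), 1))
        with pytest.raises(ValueError):
            cl.fixed_package_step(state, small_params, rng)

    def test_copies_exactly_n_distinct_traits(self, rng):
        """With c=1 and distinct variant rows, exactly n traits change per focal."""
        p = cl.SimulationParams(N=2, h=5, k=4, n_fixed=2, c=1.0, mu=0.0)
        state = state_from([[1, 1, 1, 1, 1], [2, 2, 2, 2, 2]])
        changed = []
        for _ in range(200):
            new = cl.fixed_package_step(state, p, rng)
            changed.append(int((new.variants[0] != 1).sum()))
        assert set(changed) == {2}
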