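"""Replicate runner: initialization, burn-in, sweep adjustment, recording, grids.

A standard run is a burn-in of 5000 timesteps under unbiased transmission
followed by 2000 further timesteps under the scenario's post-burn-in mode,
with per-trait variant counts and the population link frequency recorded at
the end of every timestep. The hitchhiking scenarios insert an adjustment at
the end of burn-in: a single innovator receives the best variant of trait 1
while everyone else is set to the worst, and trait 2 is relabelled so the
innovator carries the rarest, lowest-pay-off variant (the "associated
variant") — the most challenging, hence conservative, starting point for
hitchhiking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as _k
from .model_core import PopulationState, SimulationParams

SCENARIOS = (
    "neutral",
    "payoff",
    "hitchhike_neutral",
    "hitchhike_functional",
    "conformist",
    "fixed_package",
)


@dataclass
class ScenarioSpec:
    """Which study condition to run.

    ``s1``/``s2`` are the selection strengths imposed on traits 1 and 2 for
    the post-burn-in phase (0.9 / 0 in the neutral-hitchhiking scenario,
    0.9 / 0.1-0.2 in the functional one); ``post_mode`` is the transmission
    mode after burn-in. Burn-in itself is always unbiased.
    """

    scenario: str = "neutral"
    s1: float = 0.0
    s2: float = 0.0
    post_mode: str = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.post_mode is None:
            self.post_mode = {
                "neutral": "unbiased",
                "payoff": "payoff",
                "hitchhike_neutral": "payoff",
                "hitchhike_functional": "payoff",
                "conformist": "conformist",
                "fixed_package": "unbiased",
            }[self.scenario]
        if self.scenario == "neutral" and (self.s1 or self.s2):
            raise ValueError("the neutral scenario has no functional traits")
        if self.scenario == "neutral" and self.post_mode != "unbiased":
            raise ValueError("the neutral scenario is unbiased throughout")
        if self.scenario.startswith("hitchhike") and self.post_mode != "payoff":
            raise ValueError("hitchhike scenarios use pay-off-biased transmission after burn-in")

    @property
    def is_hitchhike(self) -> bool:
        return self.scenario.startswith("hitchhike")

    def effective_s(self, params: SimulationParams) -> tuple:
        """Selection vector for the post-burn-in phase."""
        s = list(params.s)
        if self.is_hitchhike or self.scenario == "payoff":
            s[0] = self.s1
            if params.h > 1:
                s[1] = self.s2
        return tuple(s)


@dataclass
class TrajectoryRecord:
    """Per-timestep variant counts and link summaries of one replicate.

    ``counts``: (T, h, k) integers, each trait row summing to N at every
    recorded timestep. ``link_frequency``: (T,) mean fraction of realized
    links. ``burn_in``: number of leading timesteps run under unbiased
    transmission. ``adjusted_counts``: the (h, k) counts immediately after
    the sweep adjustment (hitchhike scenarios only) — the frequency origin of
    the post-burn-in sweep clock.
    """

    counts: np.ndarray
    link_frequency: np.ndarray
    burn_in: int
    params: SimulationParams
    scenario: ScenarioSpec
    adjusted_counts: np.ndarray | None = None
    innovator: int | None = None
    final_state: PopulationState | None = None

    @property
    def n_steps(self) -> int:
        return self.counts.shape[0]

    def freq(self, trait: int, variant: int) -> np.ndarray:
        """Frequency trajectory of ``variant`` (1-based) at ``trait`` (1-based)."""
        return self.counts[:, trait - 1, variant - 1] / self.params.N

    def post_freq(self, trait: int, variant: int) -> np.ndarray:
        """Post-burn-in frequency trajectory on the sweep clock.

        Index 0 is the state at the adjustment point (counts right after the
        sweep adjustment when one was applied, else the last burn-in record);
        indices 1.. are the post-phase timesteps.
        """
        tail = self.counts[self.burn_in :, trait - 1, variant - 1]
        if self.adjusted_counts is not None:
            start = self.adjusted_counts[trait - 1, variant - 1]
        elif self.burn_in > 0:
            start = self.counts[self.burn_in - 1, trait - 1, variant - 1]
        else:
            raise ValueError("no adjustment point available (burn_in = 0)")
        return np.concatenate(([start], tail)) / self.params.N

    def final_counts(self, trait: int) -> np.ndarray:
        """Variant counts of ``trait`` (1-based) at the last recorded timestep."""
        return self.counts[-1, trait - 1]


def initialize(params: SimulationParams, rng: np.random.Generator) -> PopulationState:
    """Uniform random variants at every trait, no links, t = 0."""
    variants = rng.integers(1, params.k + 1, size=(params.N, params.h))
    links = np.zeros((params.N, params.h, params.h), dtype=np.bool_)
    return PopulationState(variants, links, t=0)


def apply_sweep_adjustment(
    state: PopulationState,
    params: SimulationParams,
    rng: np.random.Generator,
    scenario: ScenarioSpec | None = None,
) -> tuple[PopulationState, int]:
    """End-of-burn-in adjustment for the hitchhiking scenarios.

    Trait 1: a uniformly chosen innovator gets variant 1, everyone else
    variant k. Trait 2: the innovator's variant is overwritten with the
    rarest variant in the population (ties to the lowest label), then trait-2
    labels are permuted so that variant becomes ``k`` and the remaining
    labels rank the other variants by decreasing count. Link graphs are
    untouched. Returns the adjusted state and the innovator's index.
    """
    if scenario is not None and not scenario.is_hitchhike:
        raise ValueError("the sweep adjustment applies only to hitchhike scenarios")
    out = state.copy()
    innovator = int(rng.integers(0, params.N))
    out.variants[:, 0] = params.k
    out.variants[innovator, 0] = 1
    if params.h > 1:
        counts = np.bincount(out.variants[:, 1], minlength=params.k + 1)[1:]
        rarest = int(np.argmin(counts)) + 1  # argmin takes the lowest label on ties
        out.variants[innovator, 1] = rarest
        # relabel: rarest -> k; the others -> 1..k-1 by decreasing count
        # (ties by lower original label, which argsort preserves)
        others = [j for j in range(1, params.k + 1) if j != rarest]
        others.sort(key=lambda j: (-counts[j - 1], j))
        relabel = np.zeros(params.k + 1, dtype=np.int64)
        relabel[rarest] = params.k
        for newlab, j in enumerate(others, start=1):
            relabel[j] = newlab
        out.variants[:, 1] = relabel[out.variants[:, 1]]
    return out, innovator


def run_replicate(
    params: SimulationParams,
    scenario: ScenarioSpec | None = None,
    rng: np.random.Generator | None = None,
    keep_final_state: bool = True,
) -> TrajectoryRecord:
    """Run one complete replicate and return its trajectory.

    Phases: initialize; ``burn_in_steps`` unbiased timesteps; the sweep
    adjustment if the scenario calls for one; ``post_steps`` timesteps under
    the scenario's post-burn-in mode. The conformist scenario (h = 1) has no
    burn-in and runs ``burn_in_steps + post_steps`` timesteps under
    conformist bias throughout. The fixed-package control replaces package
    transmission in both phases.
    """
    if scenario is None:
        scenario = ScenarioSpec()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if scenario.scenario == "conformist" and params.h != 1:
        raise ValueError("the conformist scenario models a single trait (h = 1)")
    if scenario.scenario == "fixed_package" and params.n_fixed is None:
        raise ValueError("the fixed_package scenario requires params.n_fixed")

    n_fixed = -1 if params.n_fixed is None else params.n_fixed
    state = initialize(params, rng)
    h, k = params.h, params.k

    if scenario.scenario == "conformist":
        total = params.burn_in_steps + params.post_steps
        counts = np.zeros((total, h, k), dtype=np.int64)
        linkf = np.zeros(total)
        _k.run_phase(
            state.variants, state.links, params.s_array, k,
            _mode_code(scenario.post_mode), params.s_kappa,
            params.a, params.b, params.c, params.mu,
            total, n_fixed, counts, linkf, rng, params.shared_link_breakage,
        )
        state.t = total
        return TrajectoryRecord(
            counts, linkf, burn_in=0, params=params, scenario=scenario,
            final_state=state if keep_final_state else None,
        )

    total = params.burn_in_steps + params.post_steps
    counts = np.zeros((total, h, k), dtype=np.int64)
    linkf = np.zeros(total)
    s_neutral = np.asarray(params.s, dtype=np.float64)
    # burn-in: always unbiased
    _k.run_phase(
        state.variants, state.links, s_neutral, k,
        _k.UNBIASED, 0.0, params.a, params.b, params.c, params.mu,
        params.burn_in_steps, n_fixed,
        counts[: params.burn_in_steps], linkf[: params.burn_in_steps], rng,
        params.shared_link_breakage,
    )
    adjusted_counts = None
    innovator = None
    if scenario.is_hitchhike:
        state, innovator = apply_sweep_adjustment(state, params, rng, scenario)
        adjusted_counts = np.zeros((h, k), dtype=np.int64)
        _k.record_counts(state.variants, k, adjusted_counts)
    s_post = np.asarray(scenario.effective_s(params), dtype=np.float64)
    _k.run_phase(
        state.variants, state.links, s_post, k,
        _mode_code(scenario.post_mode), params.s_kappa,
        params.a, params.b, params.c, params.mu,
        params.post_steps, n_fixed,
        counts[params.burn_in_steps :], linkf[params.burn_in_steps :], rng,
        params.shared_link_breakage,
    )
    state.t = total
    return TrajectoryRecord(
        counts, linkf, burn_in=params.burn_in_steps, params=params,
        scenario=scenario, adjusted_counts=adjusted_counts, innovator=innovator,
        final_state=state if keep_final_state else None,
    )


def _mode_code(mode: str) -> int:
    from .model_core import TRANSMISSION_MODES

    return TRANSMISSION_MODES[mode]


def replicate_seed(seed_base: int, combo_index: int, replicate_index: int) -> np.random.Generator:
    """Deterministic per-run generator: every run is reconstructible from
    (seed_base, combination index, replicate index)."""
    ss = np.random.SeedSequence(seed_base, spawn_key=(combo_index, replicate_index))
    return np.random.default_rng(ss)


def run_grid(
    base_params: SimulationParams,
    grid: dict,
    replicates: int,
    seed_base: int,
    scenario: ScenarioSpec | None = None,
    keep_records: bool = False,
):
    """Run a full Cartesian parameter sweep.

    ``grid`` maps parameter names to value lists; every combination is run
    ``replicates`` times with independent, reconstructible seeds. Returns a
    per-combination summary DataFrame (mean/quantile final pairwise
    difference per trait, mean final link frequency, package-size variance,
    and sweep metrics for hitchhike scenarios), plus the list of records when
    ``keep_records`` is requested.
    """
    from . import stats

    keys = list(grid)
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate grid keys")
    for key, values in grid.items():
        for v in values:
            base_params.with_(**{key: v})  # validates before any run starts
    if replicates < 1:
        raise ValueError("replicates must be positive")

    rows = []
    records = []
    for combo_index, combo in enumerate(itertools.product(*grid.values())):
        p = base_params.with_(**dict(zip(keys, combo)))
        pis = np.zeros((replicates, p.h))
        linkfs = np.zeros(replicates)
        psvars = np.zeros(replicates)
        sweeps = []
        for rep in range(replicates):
            rng = replicate_seed(seed_base, combo_index, rep)
            rec = run_replicate(p.with_(replicate_id=rep), scenario, rng)
            for trait in range(1, p.h + 1):
                pis[rep, trait - 1] = stats.pairwise_difference(rec.final_counts(trait))
            linkfs[rep] = rec.link_frequency[-1]
            psvars[rep] = stats.package_size_variance(rec.final_state)
            if scenario is not None and scenario.is_hitchhike:
                sweeps.append(stats.sweep_summary_from_record(rec))
            if keep_records:
                records.append(rec)
        row = dict(zip(keys, combo))
        row["replicates"] = replicates
        for trait in range(1, p.h + 1):
            row[f"pi{trait}_mean"] = pis[:, trait - 1].mean()
            row[f"pi{trait}_q05"] = np.quantile(pis[:, trait - 1], 0.05)
            row[f"pi{trait}_q95"] = np.quantile(pis[:, trait - 1], 0.95)
        row["link_frequency_mean"] = linkfs.mean()
        row["package_size_variance_mean"] = psvars.mean()
        if sweeps:
            agg = stats.aggregate_sweeps(sweeps)
            row.update({f"sweep_{kk}": v for kk, v in agg.items()})
        rows.append(row)
    summary = pd.DataFrame(rows)
    if keep_records:
        return summary, records
    return summary
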