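"""Summary statistics: pairwise difference, Wright–Fisher references,
link/package summaries, distribution overlap, and sweep/hitchhiking metrics.

The central diversity measure is the pairwise difference π of a trait — the
probability that two individuals sampled without replacement carry different
variants (a small-sample-corrected Simpson/heterozygosity index). Under the
standard multi-allele Wright–Fisher model its expectation is approximately
``2Nμ(k-1) / (k-1 + 2Nμk)``; in this package-transmission model a trait is
only successfully copied every ``h/(nc)`` timesteps on average, so the
matching reference rescales the innovation rate by ``h/(nc)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .model_core import PopulationState


@dataclass
class PiSample:
    """Final pairwise-difference values across replicates for one trait/timepoint."""

    values: np.ndarray
    trait: int = 1
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size == 0:
            raise ValueError("a PiSample cannot be empty")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("pairwise differences lie in [0, 1]")


@dataclass
class OverlapResult:
    """Estimated area of overlap between two π distributions, with settings."""

    overlap: float
    method: str
    bins: int | None = None
    bandwidth: float | None = None
    n_x: int = 0
    n_y: int = 0


@dataclass
class SweepSummary:
    """Hitchhiking outcome of one replicate, on the post-burn-in sweep clock."""

    sweep_end: int
    assoc_freq_at_end: float
    majority_reached: bool
    majority_duration: int | None
    censored: bool

    def __post_init__(self):
        if self.majority_reached and (self.majority_duration is None or self.majority_duration < 0):
            raise ValueError("majority_duration must be a nonnegative count when majority is reached")
        if not self.majority_reached and self.majority_duration is not None:
            raise ValueError("majority_duration is defined only when majority is reached")


def pairwise_difference(counts) -> float:
    """π = 1 - Σ_j n_j (n_j - 1) / (N (N - 1)) for variant counts n_j.

    Exactly the probability that two individuals sampled without replacement
    differ at the trait: 0 for a monomorphic population, 1 when every
    individual is unique.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be a vector of nonnegative integers")
    n = int(counts.sum())
    if n < 2:
        raise ValueError("pairwise difference needs at least two individuals")
    same = (counts * (counts - 1)).sum()
    return 1.0 - same / (n * (n - 1))


def wf_expectation(N: int, mu: float, k: int) -> float:
    """Wright–Fisher expected pairwise difference 2Nμ(k-1)/(k-1 + 2Nμk)."""
    if N < 2 or k < 2:
        raise ValueError("need N >= 2 and k >= 2")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be a probability")
    if mu == 0.0:
        warnings.warn("mu = 0: drift-only limit, expected pairwise difference is 0")
        return 0.0
    theta = 2.0 * N * mu
    return theta * (k - 1) / (k - 1 + theta * k)


def scaled_wf_expectation(N: int, mu: float, k: int, h: int, n: int, c: float) -> float:
    """Wright–Fisher expectation with innovation rescaled by h/(nc).

    With packages of size ``n`` and copy probability ``c``, a given trait is
    successfully transmitted only every ``h/(nc)`` timesteps while innovation
    ticks every timestep, so the matching single-trait Wright–Fisher model
    uses ``μ_eff = μ h / (n c)``. With ``n = h`` and ``c = 1`` this is the
    plain expectation.
    """
    if not 1 <= n <= h:
        raise ValueError("n must lie in 1..h (n = 0 means no transmission at all)")
    if not 0.0 < c <= 1.0:
        raise ValueError("c must be in (0, 1]")
    return wf_expectation(N, mu * h / (n * c), k)


def link_frequency(state: PopulationState) -> float:
    """Mean fraction of realized links per individual (0 when h = 1)."""
    h = state.h
    if h == 1:
        return 0.0
    iu = np.triu_indices(h, 1)
    per_ind = state.links[:, iu[0], iu[1]].sum(axis=1) / (h * (h - 1) / 2)
    return float(per_ind.mean())


def package_size_variance(state: PopulationState) -> float:
    """Variance of connected-component sizes over all N·h (individual, trait) pairs.

    0 when every trait is a singleton everywhere or every graph is complete;
    largest at intermediate link frequency, where some variants ride in large
    packages and others do not.
    """
    from . import _kernels as _k

    n, h = state.N, state.h
    sizes = np.empty(n * h)
    member = np.zeros(h, dtype=np.bool_)
    for r in range(n):
        for trait in range(h):
            _k.component_members(state.links[r], trait, member)
            sizes[r * h + trait] = member.sum()
    return float(np.var(sizes))


def _kde_density(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE on [0, 1] with boundary reflection."""
    kde = gaussian_kde(values)
    # reflect at both boundaries so mass does not leak off the support
    dens = kde(grid) + kde(-grid) + kde(2.0 - grid)
    return dens


def area_of_overlap(x, y, method: str = "hist", bins: int = 100) -> OverlapResult:
    """Area of overlap ∫ min(f_x, f_y) between two π distributions on [0, 1].

    ``method="hist"`` (default): shared equal-width bins over [0, 1],
    overlap = Σ min(p̂_x, p̂_y). ``method="kde"``: Gaussian kernel densities
    (reflected at the support boundaries) integrated on a fine grid —
    smoother, and preferable when replicate counts are modest. Symmetric in
    its arguments; 1 for identical samples; 0 for disjoint supports.
    """
    xv = x.values if isinstance(x, PiSample) else np.asarray(x, dtype=np.float64)
    yv = y.values if isinstance(y, PiSample) else np.asarray(y, dtype=np.float64)
    if xv.size == 0 or yv.size == 0:
        raise ValueError("overlap requires two non-empty samples")
    if method == "hist":
        edges = np.linspace(0.0, 1.0, bins + 1)
        px, _ = np.histogram(np.clip(xv, 0, 1), bins=edges)
        py, _ = np.histogram(np.clip(yv, 0, 1), bins=edges)
        ov = np.minimum(px / xv.size, py / yv.size).sum()
        return OverlapResult(float(ov), "hist", bins=bins, n_x=xv.size, n_y=yv.size)
    if method == "kde":
        if np.ptp(xv) == 0.0 and np.ptp(yv) == 0.0:
            # two point masses: overlap is 1 iff they coincide
            ov = 1.0 if xv[0] == yv[0] else 0.0
            return OverlapResult(ov, "kde", n_x=xv.size, n_y=yv.size)
        if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
            # a degenerate sample has no density estimate; fall back to bins
            return area_of_overlap(xv, yv, method="hist", bins=bins)
        grid = np.linspace(0.0, 1.0, 1001)
        fx = _kde_density(xv, grid)
        fy = _kde_density(yv, grid)
        ov = np.trapezoid(np.minimum(fx, fy), grid)
        bw = float(gaussian_kde(xv).factor)
        return OverlapResult(min(float(ov), 1.0), "kde", bandwidth=bw,
                             n_x=xv.size, n_y=yv.size)
    raise ValueError(f"unknown overlap method {method!r}")


def detect_sweep_end(freqs) -> tuple[int, bool]:
    """Earliest timestep at which the sweeping variant's frequency does not increase.

    ``freqs`` is the post-burn-in frequency trajectory of trait 1's variant 1,
    with index 0 the adjustment point (frequency 1/N). Returns ``(t,
    censored)``: the smallest t >= 1 with freqs[t] <= freqs[t-1], or the last
    index with ``censored=True`` when the frequency rises strictly throughout.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if freqs.size < 2:
        raise ValueError("a sweep trajectory needs at least two points")
    nonincrease = np.flatnonzero(np.diff(freqs) <= 0.0)
    if nonincrease.size:
        return int(nonincrease[0] + 1), False
    return freqs.size - 1, True


def hitchhike_metrics(trait2_traj, sweep_end: int) -> SweepSummary:
    """Hitchhiking outcome given the associated variant's frequency trajectory.

    The associated variant hitchhikes when its frequency strictly exceeds 0.5
    at the end of the sweep; ``majority_duration`` counts the consecutive
    timesteps after ``sweep_end`` it stays strictly above 0.5, censored when
    the run ends while still above.
    """
    traj = np.asarray(trait2_traj, dtype=np.float64)
    if not 0 <= sweep_end < traj.size:
        raise ValueError("sweep_end outside the trajectory")
    freq_end = float(traj[sweep_end])
    majority = freq_end > 0.5
    if not majority:
        return SweepSummary(sweep_end, freq_end, False, None, False)
    tail = traj[sweep_end + 1 :]
    below = np.flatnonzero(tail <= 0.5)
    if below.size:
        return SweepSummary(sweep_end, freq_end, True, int(below[0]), False)
    return SweepSummary(sweep_end, freq_end, True, int(tail.size), True)


def sweep_summary_from_record(record) -> SweepSummary:
    """Sweep metrics of one hitchhike replicate (associated variant = k at trait 2)."""
    p = record.params
    sweep_traj = record.post_freq(1, 1)
    end, _censored_sweep = detect_sweep_end(sweep_traj)
    assoc = record.post_freq(2, p.k)
    return hitchhike_metrics(assoc, end)


def aggregate_sweeps(summaries) -> dict:
    """Across-replicate hitchhiking summary.

    ``mean_duration`` averages observed durations over replicates where the
    majority was reached, counting censored durations at their observed
    (lower-bound) value, with the censored fraction reported alongside. The
    duration is conventionally reported only when hitchhiking occurred in
    more than 5% of replicates.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no sweep summaries to aggregate")
    n = len(summaries)
    reached = [s for s in summaries if s.majority_reached]
    prop = len(reached) / n
    out = {
        "n": n,
        "proportion_majority": prop,
        "mean_assoc_freq_at_end": float(np.mean([s.assoc_freq_at_end for s in summaries])),
        "mean_sweep_end": float(np.mean([s.sweep_end for s in summaries])),
    }
    if reached and prop > 0.05:
        out["mean_majority_duration"] = float(np.mean([s.majority_duration for s in reached]))
        out["censored_fraction"] = float(np.mean([s.censored for s in reached]))
    else:
        out["mean_majority_duration"] = float("nan")
        out["censored_fraction"] = float("nan")
    return out


def wright_fisher_pi_sample(
    N: int, mu: float, k: int, steps: int, replicates: int, rng: np.random.Generator
) -> PiSample:
    """Final pairwise differences of a standard multi-allele Wright–Fisher model.

    The single-trait reference process: each generation the population is
    multinomially resampled from the current variant frequencies, then each
    individual innovates with probability μ to one of the other k-1 variants.
    Vectorized across replicates; used as the independent baseline in the
    equifinality comparisons.
    """
    counts = rng.multinomial(N, np.full((replicates, k), 1.0 / k))
    for _ in range(steps):
        counts = rng.multinomial(N, counts / N)
        leaving = rng.binomial(counts, mu)
        arriving = np.zeros_like(counts)
        for j in range(k):
            dest = np.full((replicates, k), 1.0 / (k - 1))
            dest[:, j] = 0.0
            arriving += rng.multinomial(leaving[:, j], dest)
        counts = counts - leaving + arriving
    pis = np.array([pairwise_difference(row) for row in counts])
    return PiSample(pis, trait=1, label="wright-fisher")


__all__ = [
    "PiSample",
    "OverlapResult",
    "SweepSummary",
    "pairwise_difference",
    "wf_expectation",
    "scaled_wf_expectation",
    "link_frequency",
    "package_size_variance",
    "area_of_overlap",
    "detect_sweep_end",
    "hitchhike_metrics",
    "sweep_summary_from_record",
    "aggregate_sweeps",
    "wright_fisher_pi_sample",
]
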