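"""Jitted inner loops of the transmission dynamics.

Every rule of the model lives here exactly once: the public operations in
:mod:`cultlink.model_core` and :mod:`cultlink.transmission` wrap the
per-individual kernels, and the replicate driver in :mod:`cultlink.engine`
runs the same kernels from inside a jitted multi-step loop.

Conventions: variants are stored 1-based in ``int64`` arrays of shape (N, h);
link graphs are boolean (N, h, h) arrays kept symmetric with a false diagonal.
All randomness flows through a single ``numpy.random.Generator``; uniforms are
drawn in batches per stage in a fixed order (stage, then individual index), so
a run is reproducible from its seed alone.
"""

import numpy as np
from numba import njit

# transmission-mode codes shared with model_core
UNBIASED = 0
PAYOFF = 1
CONFORMIST = 2


@njit(cache=True)
def payoffs(variants, s, k):
    """Individual pay-offs: product over traits of 1 - ((j-1)/(k-1)) * s_i."""
    n, h = variants.shape
    f = np.ones(n)
    for r in range(n):
        for i in range(h):
            f[r] *= 1.0 - (variants[r, i] - 1) / (k - 1) * s[i]
    return f


@njit(cache=True)
def partner_weights(variants, s, k, mode, s_kappa):
    """Unnormalized partner-choice weights over the whole population.

    Self-exclusion happens at sampling time (sample_partners); the weight of
    the focal individual itself is simply never drawn.
    """
    n, h = variants.shape
    if mode == UNBIASED:
        return np.ones(n)
    if mode == PAYOFF:
        return payoffs(variants, s, k)
    # conformist: single trait; weight 1 - s_kappa * (1 - q_r) with q_r the
    # population frequency of the variant carried by r — a linear discount of
    # rare-variant carriers, unbiased at s_kappa = 0
    counts = np.zeros(k + 1)
    for r in range(n):
        counts[variants[r, 0]] += 1.0
    w = np.empty(n)
    for r in range(n):
        q = counts[variants[r, 0]] / n
        w[r] = 1.0 - s_kappa * (1.0 - q)
    return w


@njit(cache=True)
def _sample_partners_uniform(n, rng):
    """Uniform partner choice over the N-1 others, one per focal."""
    u = rng.random(n)
    out = np.empty(n, np.int64)
    for r in range(n):
        j = int(u[r] * (n - 1))
        if j >= n - 1:
            j = n - 2
        out[r] = j if j < r else j + 1
    return out


@njit(cache=True)
def sample_partners(w, rng):
    """Draw one partner per focal individual, never self, P ∝ w over others.

    Exact inverse-CDF sampling on the weight vector with the focal's own mass
    excised, so the realized law matches the self-excluded renormalized
    probabilities. Falls back to uniform choice when all non-self weight
    vanishes (degenerate pay-off states).
    """
    n = w.shape[0]
    cum = np.cumsum(w)
    tot = cum[-1]
    u = rng.random(n)
    out = np.empty(n, np.int64)
    for r in range(n):
        excl = tot - w[r]
        if excl <= 0.0:
            # everyone else has zero weight: uniform over the other N-1
            j = int(u[r] * (n - 1))
            if j >= n - 1:
                j = n - 2
            out[r] = j if j < r else j + 1
            continue
        target = u[r] * excl
        low = cum[r] - w[r]  # cumulative mass strictly before focal r
        if target >= low:
            target += w[r]
        # leftmost index with cum[idx] > target
        lo, hi = 0, n
        while lo < hi:
            mid = (lo + hi) >> 1
            if cum[mid] <= target:
                lo = mid + 1
            else:
                hi = mid
        if lo >= n:
            lo = n - 1
        out[r] = lo
    return out


@njit(cache=True, inline="always")
def component_members(links_one, trait, member):
    """Mark the connected component of `trait` in one individual's link graph."""
    h = links_one.shape[0]
    for i in range(h):
        member[i] = False
    member[trait] = True
    changed = True
    while changed:
        changed = False
        for i in range(h):
            if member[i]:
                for j in range(h):
                    if links_one[i, j] and not member[j]:
                        member[j] = True
                        changed = True


@njit(cache=True, inline="always")
def transmit_variants_one(focal_variants, partner_variants, member, c, u):
    """Copy each in-package variant from the partner with probability c.

    u: (h,) uniforms, one per trait (draws for out-of-package traits unused).
    """
    h = member.shape[0]
    for i in range(h):
        if member[i] and u[i] < c:
            focal_variants[i] = partner_variants[i]


@njit(cache=True, inline="always")
def transmit_links_one(focal_links, partner_links, member, b, u, shared_break):
    """Apply the link-outcome table for one transmission event.

    In-package pair: kept if both have it (or, with shared_break, re-tested
    and kept w.p. 1-b), acquired w.p. 1-b if only the partner has it, broken
    if only the focal has it. Boundary-crossing focal links are always lost;
    links fully outside the package are untouched.
    u: (h*(h-1)//2,) uniforms indexed in upper-triangle order.
    """
    h = member.shape[0]
    p = 0
    for i in range(h):
        for j in range(i + 1, h):
            if member[i] and member[j]:
                if partner_links[i, j]:
                    if focal_links[i, j] and not shared_break:
                        new = True
                    else:
                        new = u[p] < 1.0 - b
                else:
                    new = False
                focal_links[i, j] = new
                focal_links[j, i] = new
            elif member[i] != member[j]:
                focal_links[i, j] = False
                focal_links[j, i] = False
            p += 1


@njit(cache=True)
def form_links_all(links, a, rng):
    """Each unlinked trait pair of each individual links w.p. a."""
    n, h, _ = links.shape
    if a <= 0.0:
        return
    npairs = h * (h - 1) // 2
    u = rng.random((n, npairs))
    for r in range(n):
        p = 0
        for i in range(h):
            for j in range(i + 1, h):
                if not links[r, i, j] and u[r, p] < a:
                    links[r, i, j] = True
                    links[r, j, i] = True
                p += 1


@njit(cache=True)
def innovate_all(variants, k, mu, rng):
    """Each trait of each individual switches to one of the other k-1 variants w.p. mu."""
    n, h = variants.shape
    if mu <= 0.0:
        return
    u = rng.random((n, h))
    for r in range(n):
        for i in range(h):
            if u[r, i] < mu:
                # u | u < mu rescaled is again Uniform(0,1), independent of
                # the event itself: reuse it to pick the replacement variant
                shift = 1 + int(u[r, i] / mu * (k - 1))
                if shift > k - 1:
                    shift = k - 1
                variants[r, i] = 1 + (variants[r, i] - 1 + shift) % k


@njit(cache=True)
def step(variants, links, s, k, mode, s_kappa, a, b, c, mu, rng, shared_break=False):
    """One synchronous timestep, in place.

    All reads come from a snapshot of the start-of-step state; stage order is
    partner choice, package transmission, link formation, innovation.
    """
    n, h = variants.shape
    npairs = h * (h - 1) // 2
    vsnap = variants.copy()
    lsnap = links.copy()
    if mode == UNBIASED:
        partners = _sample_partners_uniform(n, rng)
    else:
        w = partner_weights(vsnap, s, k, mode, s_kappa)
        partners = sample_partners(w, rng)
    traits = rng.random(n)
    ucopy = rng.random((n, h))
    ulink = rng.random((n, npairs))
    # linkless individuals take a closed-form shortcut below; because the
    # uniforms are pre-drawn positionally, the shortcut is draw-for-draw
    # identical to the general path (singleton package, no link updates)
    linkless = np.empty(n, np.bool_)
    for r in range(n):
        any_link = False
        for i in range(h):
            if any_link:
                break
            for j in range(i + 1, h):
                if lsnap[r, i, j]:
                    any_link = True
                    break
        linkless[r] = not any_link
    member = np.zeros(h, np.bool_)
    for r in range(n):
        p = partners[r]
        trait = int(traits[r] * h)
        if trait >= h:
            trait = h - 1
        if linkless[p] and linkless[r]:
            if ucopy[r, trait] < c:
                variants[r, trait] = vsnap[p, trait]
            continue
        component_members(lsnap[p], trait, member)
        transmit_variants_one(variants[r], vsnap[p], member, c, ucopy[r])
        transmit_links_one(links[r], lsnap[p], member, b, ulink[r], shared_break)
    form_links_all(links, a, rng)
    innovate_all(variants, k, mu, rng)


@njit(cache=True)
def fixed_package_step(variants, s, k, mode, s_kappa, n_fixed, c, mu, rng):
    """Control dynamic: copy n_fixed random distinct traits, ignoring links."""
    n, h = variants.shape
    vsnap = variants.copy()
    if mode == UNBIASED:
        partners = _sample_partners_uniform(n, rng)
    else:
        w = partner_weights(vsnap, s, k, mode, s_kappa)
        partners = sample_partners(w, rng)
    usel = rng.random((n, h))
    ucopy = rng.random((n, h))
    idx = np.empty(h, np.int64)
    for r in range(n):
        p = partners[r]
        for i in range(h):
            idx[i] = i
        # partial Fisher-Yates: first n_fixed entries are the sampled traits
        for i in range(n_fixed):
            j = i + int(usel[r, i] * (h - i))
            if j >= h:
                j = h - 1
            idx[i], idx[j] = idx[j], idx[i]
        for i in range(n_fixed):
            if ucopy[r, i] < c:
                variants[r, idx[i]] = vsnap[p, idx[i]]
    innovate_all(variants, k, mu, rng)


@njit(cache=True)
def count_links(links):
    """Total number of present links (unordered pairs) over all individuals."""
    n, h, _ = links.shape
    tot = 0
    for r in range(n):
        for i in range(h):
            for j in range(i + 1, h):
                if links[r, i, j]:
                    tot += 1
    return tot


@njit(cache=True)
def record_counts(variants, k, out):
    """Per-trait variant counts into out (h, k)."""
    n, h = variants.shape
    for i in range(h):
        for j in range(k):
            out[i, j] = 0
    for r in range(n):
        for i in range(h):
            out[i, variants[r, i] - 1] += 1


@njit(cache=True)
def run_phase(variants, links, s, k, mode, s_kappa, a, b, c, mu,
              n_steps, n_fixed, rec_counts, rec_linkfrac, rng,
              shared_break=False):
    """Advance n_steps timesteps, recording counts and link frequency each step.

    rec_counts: (n_steps, h, k) int64; rec_linkfrac: (n_steps,) float64.
    n_fixed < 0 means the full link dynamic; n_fixed >= 0 the fixed-package
    control (link stages skipped).
    """
    n, h = variants.shape
    pairs = h * (h - 1) / 2.0
    for t in range(n_steps):
        if n_fixed >= 0:
            fixed_package_step(variants, s, k, mode, s_kappa, n_fixed, c, mu, rng)
        else:
            step(variants, links, s, k, mode, s_kappa, a, b, c, mu, rng, shared_break)
        record_counts(variants, k, rec_counts[t])
        if pairs > 0:
            rec_linkfrac[t] = count_links(links) / (n * pairs)
        else:
            rec_linkfrac[t] = 0.0
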