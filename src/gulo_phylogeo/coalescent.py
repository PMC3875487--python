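"""Infinite-sites coalescent sampler for null distributions and bootstraps.

A minimal, seedable Kingman-coalescent simulator with piecewise-constant
population size.  It produces exactly the quantities the neutrality tests
and the mismatch bootstrap need — segregating sites S, mean pairwise
differences k̄, the number of distinct sequence classes, and the pairwise
mismatch histogram — without materialising sequences, which keeps the cost
per replicate low enough for the 10^5–10^6 tiny replicates the simulation
p-values and calibration studies consume.

Conventions: time is measured in units of 2N_0 generations (N_0 the present
size); ``theta`` is the population-scaled mutation rate over the whole
sequence (2·N_0·u); mutations fall on each branch as Poisson(theta/2 per
unit time).  ``size_history`` is a sequence of ``(time, relative_size)``
breakpoints looking backward, the present relative size being 1.

The scenario-level simulator (multi-population colonization histories with
finite-site HKY mutations) is msprime-based and lives in
:mod:`gulo_phylogeo.scenarios`; msprime also serves as the independent
cross-check of this sampler in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoalescentSample", "simulate_sample", "coalescent_times"]


@dataclass(frozen=True)
class CoalescentSample:
    S: int
    kbar: float
    n_haplotypes: int
    mismatch: np.ndarray | None = None  # counts per difference class, length max_diff+1


def coalescent_times(n: int, rng: np.random.Generator, size_history=()) -> np.ndarray:
    """Waiting times between coalescent events for k = n..2 lineages."""
    breaks = sorted(size_history)
    waits = np.empty(n - 1)
    t = 0.0
    for idx, k in enumerate(range(n, 1, -1)):
        rate = k * (k - 1) / 2.0
        hazard = rng.exponential()
        while True:
            lam = 1.0
            nxt = np.inf
            for bt, bs in breaks:
                if bt <= t:
                    lam = bs
                else:
                    nxt = bt
                    break
            dt = hazard * lam / rate
            if t + dt <= nxt:
                t += dt
                break
            hazard -= (nxt - t) * rate / lam
            t = nxt
        waits[idx] = t
    return waits  # absolute event times, ascending


def simulate_sample(
    n: int,
    theta: float,
    rng: np.random.Generator,
    size_history=(),
    mismatch: bool = False,
) -> CoalescentSample:
    """Simulate one sample of ``n`` sequences under the infinite-sites model."""
    if n < 2:
        raise ValueError("need at least two sequences")
    event_times = coalescent_times(n, rng, size_history)

    birth = [0.0] * n
    sizes = [1] * n
    classes = [1] * n  # sequence classes within each subtree
    crown = [1] * n    # leaves identical to the subtree root
    depths = [np.zeros(1, dtype=np.int64) for _ in range(n)] if mismatch else None
    hist: dict[int, int] = {} if mismatch else None

    S = 0
    ssum = 0.0
    half_theta = theta / 2.0
    for idx, k in enumerate(range(n, 1, -1)):
        t = event_times[idx]
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        i, j = (i, j) if i < j else (j, i)
        mi = rng.poisson(half_theta * (t - birth[i]))
        mj = rng.poisson(half_theta * (t - birth[j]))
        S += mi + mj
        ssum += mi * sizes[i] * (n - sizes[i]) + mj * sizes[j] * (n - sizes[j])
        ci = crown[i] if mi == 0 else 0
        cj = crown[j] if mj == 0 else 0
        new_classes = classes[i] + classes[j] - (1 if ci and cj else 0)
        if mismatch:
            di = depths[i] + mi
            dj = depths[j] + mj
            for v in (di[:, None] + dj[None, :]).ravel():
                hist[int(v)] = hist.get(int(v), 0) + 1
            depths[i] = np.concatenate([di, dj])
            del depths[j]
        birth[i] = t
        sizes[i] += sizes[j]
        classes[i] = new_classes
        crown[i] = ci + cj
        del birth[j], sizes[j], classes[j], crown[j]

    mm = None
    if mismatch:
        mm = np.zeros(max(hist) + 1 if hist else 1, dtype=np.int64)
        for v, c in hist.items():
            mm[v] = c
    return CoalescentSample(S=S, kbar=ssum / (n * (n - 1) / 2.0), n_haplotypes=classes[0], mismatch=mm)
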