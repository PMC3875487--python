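"""Per-population diversity and neutrality statistics.

Implements the standard single-locus descriptive statistics of mtDNA
phylogeography — nucleotide diversity π, Nei's unbiased haplotype diversity
h, rarefied haplotype richness and private-haplotype richness (hypergeometric
expectation in a standardized subsample of size g) — together with Tajima's D
and Fu's Fs, whose p-values come from neutral constant-size coalescent
simulations conditioned on the observed θ̂_π.

p-values are lower-tail probabilities Pr(stat_sim ≤ stat_obs): strongly
negative statistics (excess rare variants, as after expansion) give small p,
while large positive values give p near 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import HaplotypeAlignment, VariableSiteTable, variable_sites
from .coalescent import simulate_sample
from .distance import PairwiseDistanceMatrix
from .samples import RegionalSample

__all__ = [
    "DiversityResult",
    "NeutralityResult",
    "nucleotide_diversity",
    "haplotype_diversity",
    "rarefied_richness",
    "rarefied_private",
    "private_count",
    "mean_pairwise_differences",
    "tajimas_d_value",
    "fus_fs_value",
    "tajima_p_value",
    "neutrality_tests",
    "diversity_table",
]


@dataclass(frozen=True)
class DiversityResult:
    region: str
    era: str
    n: int
    pi: float
    sd_pi: float
    h: float
    sd_h: float
    H_R: int
    H_Rstd: float
    H_P: int
    H_Pstd: float
    g: int


@dataclass(frozen=True)
class NeutralityResult:
    D: float
    p_D: float
    Fs: float | None
    p_Fs: float | None
    S: int
    k_obs: int
    kbar: float


def _count_items(sample: RegionalSample) -> tuple[list[str], np.ndarray]:
    haps = sample.haplotypes()
    return haps, np.array([sample.counts[h] for h in haps], dtype=float)


def mean_pairwise_differences(sample: RegionalSample, dist: PairwiseDistanceMatrix) -> float:
    """k̄: average number of differences over all n(n-1)/2 individual pairs."""
    haps, c = _count_items(sample)
    n = c.sum()
    if n < 2:
        raise ValueError("need n >= 2")
    D = dist.submatrix(haps).d
    total = 0.5 * c @ D @ c  # same-haplotype pairs contribute zero
    return float(total / (n * (n - 1) / 2.0))


def nucleotide_diversity(
    sample: RegionalSample, dist: PairwiseDistanceMatrix, L: int
) -> tuple[float, float]:
    """π per site, with its standard deviation.

    The variance estimator is the total (stochastic + sampling) variance for
    a non-recombining locus, Var(π) = b1·π/L + b2·π², with the usual
    b1 = (n+1)/(3(n−1)) and b2 = 2(n²+n+3)/(9n(n−1)).
    """
    n = sample.n
    pi = mean_pairwise_differences(sample, dist) / L
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    var = b1 * pi / L + b2 * pi * pi
    return pi, math.sqrt(max(var, 0.0))


def haplotype_diversity(sample: RegionalSample) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity h = n/(n−1)·(1 − Σ p_i²), with SD.

    The variance is Nei's estimator
    V(h) = 2/(n(n−1))·{2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)²}.
    """
    _, c = _count_items(sample)
    n = c.sum()
    if n < 2:
        raise ValueError("need n >= 2")
    p = c / n
    sp2 = float(np.sum(p**2))
    sp3 = float(np.sum(p**3))
    h = n / (n - 1.0) * (1.0 - sp2)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (sp3 - sp2**2) + sp2 - sp2**2)
    return float(h), math.sqrt(max(var, 0.0))


def rarefied_richness(sample: RegionalSample, g: int) -> float:
    """Expected number of distinct haplotypes in a size-g subsample.

    Drawing without replacement, haplotype with count n_h is present with
    probability 1 − C(n−n_h, g)/C(n, g).
    """
    n = sample.n
    if not 1 <= g <= n:
        raise ValueError(f"g={g} out of range for n={n}")
    total = 0.0
    for c in sample.counts.values():
        if c > 0:
            total += 1.0 - math.comb(n - c, g) / math.comb(n, g)
    return total


def _absent_prob(count: int, n: int, g: int) -> float:
    if count > n - g:
        return 0.0
    return math.comb(n - count, g) / math.comb(n, g)


def rarefied_private(samples: list[RegionalSample], focal: str, g: int) -> float:
    """Expected number of haplotypes private to the focal sample at size g.

    For each haplotype: probability it appears in the focal g-subsample times
    the probability it is absent from every other sample's g-subsample
    (independent hypergeometric draws within each sample).
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    by_label = {s.label: s for s in samples}
    if focal not in by_label:
        raise KeyError(f"unknown focal sample {focal!r}")
    foc = by_label[focal]
    others = [s for s in samples if s.label != focal]
    if g > min(s.n for s in samples):
        raise ValueError("g exceeds the smallest sample size")
    total = 0.0
    for hap, c in foc.counts.items():
        if c == 0:
            continue
        p_in = 1.0 - _absent_prob(c, foc.n, g)
        p_out = 1.0
        for s in others:
            p_out *= _absent_prob(s.counts.get(hap, 0), s.n, g)
        total += p_in * p_out
    return total


def private_count(samples: list[RegionalSample], focal: str) -> int:
    """Haplotypes observed in the focal sample and in no other sample."""
    by_label = {s.label: s for s in samples}
    foc = by_label[focal]
    others = [s for s in samples if s.label != focal]
    return sum(
        1
        for hap, c in foc.counts.items()
        if c > 0 and all(s.counts.get(hap, 0) == 0 for s in others)
    )


# ---------------------------------------------------------------------------
# Neutrality statistics


def tajimas_d_value(n: int, S: int, kbar: float) -> float:
    """Tajima's D from n, segregating sites S, and mean pairwise differences.

    Defined as 0 when S = 0 (the statistic's numerator and denominator both
    vanish for an invariant sample).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if S == 0:
        return 0.0
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (kbar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


from functools import lru_cache


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1:] = row[:-1]  # |s(m-1, k-1)|
        with np.errstate(invalid="ignore"):
            new = np.logaddexp(new, np.log(m - 1) + row) if m > 1 else new
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | θ, n) under the Ewens sampling distribution, k = 1..n."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = _log_stirling_row(n)[1:]
    k = np.arange(1, n + 1)
    log_poch = np.sum(np.log(theta + np.arange(n)))
    return ls + k * np.log(theta) - log_poch


def fus_fs_value(n: int, k_obs: int, theta: float) -> float | None:
    """Fu's Fs = ln(S′/(1−S′)) with S′ = Pr(K ≥ k_obs | θ) under Ewens.

    θ is taken as the observed mean number of pairwise differences.  For a
    monomorphic sample (k_obs = 1 and θ = 0) the statistic is undefined and
    ``None`` is returned; for k_obs = 1 with θ > 0, S′ = 1 and Fs = +inf.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if theta <= 0.0:
        return None
    if k_obs <= 1:
        return math.inf
    logp = ewens_log_pmf(n, theta)
    # log S' and log(1-S') via the two tails, for numerical symmetry
    from scipy.special import logsumexp

    log_sp = logsumexp(logp[k_obs - 1 :])
    log_one_minus = logsumexp(logp[: k_obs - 1])
    return float(log_sp - log_one_minus)


def tajima_p_value(n: int, S: int, kbar: float, nsim: int = 10_000, seed: int = 0) -> float:
    """Lower-tail simulation p-value for Tajima's D.

    Neutral constant-size coalescent replicates conditioned on θ̂_π = k̄;
    p = Pr(D_sim ≤ D_obs) with the (b+1)/(B+1) estimator, ties counted.
    """
    D_obs = tajimas_d_value(n, S, kbar)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(nsim):
        sim = simulate_sample(n, kbar, rng) if kbar > 0 else None
        if sim is None:
            D_sim = 0.0
        else:
            D_sim = tajimas_d_value(n, sim.S, sim.kbar)
        if D_sim <= D_obs:
            hits += 1
    return (hits + 1) / (nsim + 1)


def neutrality_tests(
    sample: RegionalSample,
    dist: PairwiseDistanceMatrix,
    sites: VariableSiteTable | None = None,
    aln: HaplotypeAlignment | None = None,
    nsim: int = 10_000,
    seed: int = 0,
) -> NeutralityResult:
    """Tajima's D and Fu's Fs with coalescent-simulation p-values.

    The neutral null is a constant-size coalescent conditioned on the
    observed θ̂_π = k̄ (not on S).  ``p = Pr(stat_sim ≤ stat_obs)`` with ties
    counted and the (b+1)/(B+1) estimator.  S is taken from ``sites`` when
    given (substitution-segregating sites under the default gap mode),
    otherwise computed from ``aln`` restricted to the sample's haplotypes.
    """
    n = sample.n
    kbar = mean_pairwise_differences(sample, dist)
    if sites is None:
        if aln is None:
            raise ValueError("provide either a VariableSiteTable or the alignment")
        sites = variable_sites(aln, subset=set(sample.haplotypes()))
    S = sites.S
    k_obs = len(sample.haplotypes())

    D_obs = tajimas_d_value(n, S, kbar)
    Fs_obs = fus_fs_value(n, k_obs, kbar) if k_obs >= 2 else None

    rng = np.random.default_rng(seed)
    d_hits = 0
    fs_hits = 0
    for _ in range(nsim):
        sim = simulate_sample(n, kbar, rng)
        D_sim = tajimas_d_value(n, sim.S, sim.kbar)
        if D_sim <= D_obs:
            d_hits += 1
        if Fs_obs is not None:
            if sim.kbar <= 0.0 or sim.n_haplotypes == 1:
                fs_sim = math.inf
            else:
                fs_sim = fus_fs_value(n, sim.n_haplotypes, sim.kbar)
            if fs_sim <= Fs_obs:
                fs_hits += 1
    p_D = (d_hits + 1) / (nsim + 1)
    p_Fs = (fs_hits + 1) / (nsim + 1) if Fs_obs is not None else None
    return NeutralityResult(D=D_obs, p_D=p_D, Fs=Fs_obs, p_Fs=p_Fs, S=S, k_obs=k_obs, kbar=kbar)


# ---------------------------------------------------------------------------
# Report table


def diversity_table(
    samples: list[RegionalSample],
    dist: PairwiseDistanceMatrix,
    aln: HaplotypeAlignment,
    L: int | None = None,
    g_contemporary: int = 6,
    g_historic: int = 5,
    nsim: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample diversity summary (one row per (region, era) sample).

    Rarefaction is standardized within era: contemporary samples at
    ``g_contemporary``, historic at ``g_historic``; private-haplotype
    rarefaction compares samples of the same era.  Raw private counts (H_P)
    are relative to all other samples of either era.
    """
    L = L if L is not None else aln.L
    regional = [s for s in samples if s.region != "ALL"]
    by_era = {"contemporary": [], "historic": []}
    for s in regional:
        by_era[s.era].append(s)
    rows = []
    for i, s in enumerate(regional):
        g = g_contemporary if s.era == "contemporary" else g_historic
        era_mates = by_era[s.era]
        pi, sd_pi = nucleotide_diversity(s, dist, L)
        h, sd_h = haplotype_diversity(s)
        hr = len(s.haplotypes())
        g_eff = min(g, min(x.n for x in era_mates))
        hr_std = rarefied_richness(s, g_eff)
        hp = private_count(regional, s.label)
        hp_std = (
            rarefied_private(era_mates, s.label, g_eff) if len(era_mates) >= 2 else float("nan")
        )
        neut = neutrality_tests(s, dist, aln=aln, nsim=nsim, seed=seed + i)
        rows.append(
            {
                "region": s.region,
                "era": s.era,
                "n": s.n,
                "pi": round(pi, 3),
                "sd_pi": round(sd_pi, 3),
                "h": round(h, 2),
                "sd_h": round(sd_h, 2),
                "H_R": hr,
                "H_Rstd": round(hr_std, 2),
                "H_P": hp,
                "H_Pstd": round(hp_std, 2),
                "D": round(neut.D, 2),
                "p_D": round(neut.p_D, 2),
                "Fs": round(neut.Fs, 2) if neut.Fs is not None and math.isfinite(neut.Fs) else None,
                "p_Fs": round(neut.p_Fs, 2) if neut.p_Fs is not None else None,
            }
        )
    return pd.DataFrame(rows)
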