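"""Mismatch distributions and sudden-expansion inference.

The mismatch distribution is the histogram of pairwise sequence differences
over all individual pairs in a sample.  Under the sudden-expansion model a
population at mutation-drift equilibrium with θ0 grows instantaneously to θ1
at scaled time τ = 2ut before the present; the expected distribution of
pairwise differences is

    F_i(τ, θ0, θ1) = F̂_i(θ1)
        + exp(−τ(θ1+1)/θ1) · Σ_{j=0}^{i} τ^j/j! · [F̂_{i−j}(θ0) − F̂_{i−j}(θ1)]

with the equilibrium geometric form F̂_i(θ) = θ^i/(1+θ)^{i+1}.  At τ = 0 or
θ0 = θ1 this reduces to the equilibrium form; for θ0 → 0 and large τ the
distribution approaches a Poisson peak at i ≈ τ.

Goodness of fit is the sum of squared deviations (SSD) between observed and
expected class frequencies, with a full parametric bootstrap (coalescent
samples simulated under the fitted expansion, each refitted) for its
p-value, and Harpending's raggedness index r = Σ (x_i − x_{i−1})² with the
same bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .coalescent import simulate_sample
from .distance import PairwiseDistanceMatrix
from .samples import RegionalSample

__all__ = [
    "MismatchDistribution",
    "mismatch_observed",
    "expansion_expected",
    "raggedness",
    "SuddenExpansionModel",
    "ExpansionResults",
]


@dataclass(frozen=True)
class MismatchDistribution:
    """Observed frequency of each pairwise-difference class i = 0..max."""

    counts: np.ndarray

    def __post_init__(self):
        if (self.counts < 0).any() or self.counts.sum() == 0:
            raise ValueError("mismatch counts must be nonnegative and nonempty")

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def mean(self) -> float:
        return float(np.arange(len(self.counts)) @ self.frequencies)


def mismatch_observed(
    sample: RegionalSample, dist: PairwiseDistanceMatrix
) -> MismatchDistribution:
    """Histogram of haplotype distances over all n(n−1)/2 individual pairs."""
    haps = sample.haplotypes()
    c = np.array([sample.counts[h] for h in haps], dtype=np.int64)
    if c.sum() < 2:
        raise ValueError("need n >= 2")
    D = dist.submatrix(haps).d.astype(np.int64)
    max_d = int(D.max()) if D.size else 0
    counts = np.zeros(max_d + 1, dtype=np.int64)
    counts[0] += int(np.sum(c * (c - 1) // 2))  # same-haplotype pairs
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            counts[D[i, j]] += int(c[i] * c[j])
    return MismatchDistribution(counts)


def _equilibrium(theta: float, m: int) -> np.ndarray:
    i = np.arange(m + 1)
    if not math.isfinite(theta):
        return np.zeros(m + 1)
    if theta <= 0.0:
        out = np.zeros(m + 1)
        out[0] = 1.0
        return out
    return np.exp(i * math.log(theta) - (i + 1) * math.log1p(theta))


def expansion_expected(
    tau: float, theta0: float, theta1: float, max_class: int
) -> np.ndarray:
    """Probabilities of difference classes 0..max_class under sudden expansion.

    The final entry absorbs the renormalized tail so the vector sums to 1.
    """
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise ValueError("parameters must be nonnegative")
    m = max_class + 60  # evaluate beyond the window before pooling the tail
    f1 = _equilibrium(theta1, m)
    f0 = _equilibrium(theta0, m)
    decay = math.exp(-tau * (theta1 + 1.0) / theta1) if theta1 > 0 else math.exp(-tau)
    # convolution of Poisson(tau) weights with the equilibrium difference
    pois = np.exp(-0.0) * np.array(
        [math.exp(j * math.log(tau) - math.lgamma(j + 1)) if tau > 0 else (1.0 if j == 0 else 0.0) for j in range(m + 1)]
    )
    diff = f0 - f1
    conv = np.convolve(pois, diff)[: m + 1]
    F = f1 + decay * conv
    F = np.clip(F, 0.0, None)
    out = np.empty(max_class + 1)
    out[:max_class] = F[:max_class]
    out[max_class] = max(0.0, 1.0 - F[:max_class].sum())
    return out


def raggedness(frequencies: np.ndarray) -> float:
    """Harpending's raggedness r = Σ_{i=1}^{d} (x_i − x_{i−1})².

    Small for smooth unimodal (expansion-like) distributions, large for
    multimodal/alternating ones.
    """
    x = np.asarray(frequencies, dtype=float)
    return float(np.sum(np.diff(x) ** 2))


@dataclass(frozen=True)
class ExpansionResults:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    p_ssd: float | None
    raggedness: float
    p_raggedness: float | None
    n: int
    nboot: int
    expected: np.ndarray
    observed: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": ["tau", "theta0", "theta1", "SSD", "p_SSD", "raggedness", "p_raggedness"],
                "value": [
                    self.tau, self.theta0, self.theta1,
                    self.ssd, self.p_ssd, self.raggedness, self.p_raggedness,
                ],
            }
        )

    def histogram(self) -> pd.DataFrame:
        k = len(self.observed)
        return pd.DataFrame(
            {"class": np.arange(k), "observed": self.observed, "expected": self.expected}
        )


class SuddenExpansionModel:
    """Least-squares fit of the sudden-expansion model to a mismatch distribution.

    Estimation minimizes the SSD between observed relative class frequencies
    and the model expectation, seeded on a coarse (τ, θ0, θ1) grid and
    polished with bounded local optimization: τ ∈ [0, 30], θ0 ∈ [0, θ̂_π],
    θ1 ∈ [max(θ̂_π, θ0), 10⁴], θ̂_π being the observed mean pairwise
    difference.  ``fit(nboot=...)`` adds full parametric-bootstrap p-values
    (each replicate is a coalescent sample of size n simulated under the
    fitted history and refitted).
    """

    def __init__(self, obs: MismatchDistribution, n: int, pool_tail: int = 5):
        if n < 2:
            raise ValueError("need n >= 2")
        self.obs = obs
        self.n = n
        self.pool_tail = pool_tail

    def _window(self, counts: np.ndarray) -> np.ndarray:
        """Observed relative frequencies on classes 0..max_obs+pool_tail."""
        freqs = counts / counts.sum()
        return np.concatenate([freqs, np.zeros(self.pool_tail + 1)])

    def _ssd(self, params: np.ndarray, obs_vec: np.ndarray, theta_pi: float) -> float:
        tau, th0, th1 = params
        # box constraints enforced by penalty (Nelder-Mead polish)
        if not (0.0 <= tau <= 30.0 and 0.0 <= th0 <= theta_pi and th0 <= th1 <= 1e4):
            return 1e9
        exp_vec = expansion_expected(tau, th0, th1, len(obs_vec) - 1)
        return float(np.sum((obs_vec - exp_vec) ** 2))

    def _fit_point(self, counts: np.ndarray) -> tuple[float, float, float, float, np.ndarray, np.ndarray]:
        obs_vec = self._window(counts)
        theta_pi = float(np.arange(len(counts)) @ (counts / counts.sum()))
        theta_pi = max(theta_pi, 1e-3)
        best = None
        taus = np.linspace(0.0, 30.0, 13)
        th0s = np.array([0.0, 0.25, 0.5, 1.0]) * theta_pi
        th1s = np.geomspace(max(theta_pi, 0.1), 1e4, 6)
        for t in taus:
            for a in th0s:
                for b in th1s:
                    v = self._ssd(np.array([t, a, b]), obs_vec, theta_pi)
                    if best is None or v < best[1]:
                        best = (np.array([t, a, b]), v)
        res = minimize(
            self._ssd,
            best[0],
            args=(obs_vec, theta_pi),
            method="Nelder-Mead",
            options={"maxiter": 400, "fatol": 1e-12, "xatol": 1e-8},
        )
        params, ssd = (res.x, float(res.fun)) if res.fun <= best[1] else best
        if not math.isfinite(ssd) or ssd >= 1e9:
            raise RuntimeError(f"sudden-expansion optimization failed: {res.message}")
        exp_vec = expansion_expected(params[0], params[1], params[2], len(obs_vec) - 1)
        return params[0], params[1], params[2], float(ssd), obs_vec, exp_vec

    def fit(self, nboot: int = 0, seed: int = 0) -> ExpansionResults:
        tau, th0, th1, ssd, obs_vec, exp_vec = self._fit_point(self.obs.counts)
        r_obs = raggedness(obs_vec)
        p_ssd = p_r = None
        if nboot:
            rng = np.random.default_rng(seed)
            # coalescent time units have E[pair coalescence] = 1 and per-pair
            # mutation rate theta, so tau = 2ut maps to t_c = tau/theta1
            t_c = tau / th1 if th1 > 0 else 0.0
            rel0 = th0 / th1 if th1 > 0 else 1.0
            hits_ssd = hits_r = 0
            for _ in range(nboot):
                sim = simulate_sample(
                    self.n, th1, rng, size_history=[(t_c, max(rel0, 1e-9))], mismatch=True
                )
                n_pairs = self.n * (self.n - 1) // 2
                counts = sim.mismatch if sim.mismatch is not None else np.array([n_pairs])
                _, _, _, ssd_sim, obs_sim, _ = self._fit_point(counts)
                if ssd_sim >= ssd:
                    hits_ssd += 1
                if raggedness(obs_sim) >= r_obs:
                    hits_r += 1
            p_ssd = hits_ssd / nboot
            p_r = hits_r / nboot
        return ExpansionResults(
            tau=float(tau), theta0=float(th0), theta1=float(th1),
            ssd=ssd, p_ssd=p_ssd, raggedness=r_obs, p_raggedness=p_r,
            n=self.n, nboot=nboot, expected=exp_vec, observed=obs_vec,
        )
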