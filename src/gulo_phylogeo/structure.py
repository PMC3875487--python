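"""Distance-based population structure: ΦST, AMOVA, SAMOVA, and Mantel IBD.

The molecular variance decomposition follows the classical three-level
analysis of molecular variance: pairwise nucleotide-difference counts enter
directly as squared Euclidean distances, sums of squared deviations are
computed from population count vectors, and the unequal-sample-size
coefficients convert mean squares into variance components.  Negative
components are retained (not truncated to zero) so that weakly negative
Φ values print as such.

Significance testing is by permutation: individuals among populations for
Φ_ST, individuals among populations within groups for Φ_SC, and whole
populations among groups for Φ_CT, with p = (b+1)/(B+1) and ties counted as
exceedances.

Model/Results layout: :class:`Amova`, :class:`Samova` and :class:`MantelIBD`
are constructed from data and ``fit()`` returns a results object carrying
estimates, permutation p-values and a ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import PairwiseDistanceMatrix
from .samples import RegionalSample

__all__ = [
    "Amova",
    "AmovaResults",
    "Samova",
    "SamovaResults",
    "MantelIBD",
    "MantelResults",
    "phi_st_pair",
    "phist_matrix",
    "haversine_km",
]


def _count_matrix(
    samples: list[RegionalSample], dist: PairwiseDistanceMatrix
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(P, H) count matrix, (H, H) squared-distance matrix, population labels."""
    haps = sorted({h for s in samples for h in s.counts if s.counts[h] > 0})
    C = np.array([[s.counts.get(h, 0) for h in haps] for s in samples], dtype=float)
    D = dist.submatrix(haps).d
    return C, D, [s.label for s in samples]


def _w(c: np.ndarray, D: np.ndarray) -> float:
    """Sum of squared distances over unordered within-set pairs for counts c."""
    return float(0.5 * c @ D @ c)


@dataclass(frozen=True)
class AmovaResults:
    """Variance components, Φ statistics and permutation p-values."""

    sigma2_a: float  # among groups (or among populations, two-level)
    sigma2_b: float | None  # among populations within groups (None if two-level)
    sigma2_c: float  # within populations
    phi_ST: float
    phi_CT: float | None
    phi_SC: float | None
    df: dict[str, int]
    ssd: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    nperm: int = 0

    @property
    def components(self) -> list[float]:
        return [v for v in (self.sigma2_a, self.sigma2_b, self.sigma2_c) if v is not None]

    @property
    def percentages(self) -> list[float]:
        total = sum(self.components)
        return [100.0 * v / total for v in self.components]

    def summary(self) -> pd.DataFrame:
        labels = (
            ["Among groups", "Among populations within groups", "Within populations"]
            if self.sigma2_b is not None
            else ["Among populations", "Within populations"]
        )
        phis = (
            [self.phi_CT, self.phi_SC, self.phi_ST]
            if self.sigma2_b is not None
            else [self.phi_ST, None]
        )
        pkeys = ["phi_CT", "phi_SC", "phi_ST"] if self.sigma2_b is not None else ["phi_ST", None]
        return pd.DataFrame(
            {
                "source": labels,
                "variance": self.components,
                "percentage": self.percentages,
                "phi": phis,
                "p": [self.p_values.get(k) if k else None for k in pkeys],
            }
        )


class Amova:
    """Analysis of molecular variance over regional haplotype samples.

    Parameters
    ----------
    samples : populations (per-region haplotype counts).
    dist : haplotype distance matrix; entries are used as squared distances.
    grouping : mapping from population label to group name.  Omitted or
        constant grouping collapses to the two-level decomposition.
    """

    def __init__(
        self,
        samples: list[RegionalSample],
        dist: PairwiseDistanceMatrix,
        grouping: dict[str, str] | None = None,
    ):
        if len(samples) < 2:
            raise ValueError("need at least two populations")
        self.samples = samples
        self.labels = [s.label for s in samples]
        if grouping is not None:
            missing = set(self.labels) - set(grouping)
            if missing:
                raise KeyError(f"populations without a group: {sorted(missing)}")
        self.grouping = grouping
        self.C, self.D, _ = _count_matrix(samples, dist)
        self.sizes = self.C.sum(axis=1)
        self.N = float(self.sizes.sum())
        # expanded individual representation used by the permutation schemes
        self._hap_of_ind = np.concatenate(
            [np.repeat(np.arange(self.C.shape[1]), c.astype(int)) for c in self.C]
        )
        self._pop_slices = np.concatenate([[0], np.cumsum(self.sizes.astype(int))])

    # -- decomposition ------------------------------------------------------

    def _two_level(self, C: np.ndarray) -> tuple[float, float, dict, dict]:
        sizes = C.sum(axis=1)
        N, P = sizes.sum(), len(sizes)
        ssd_wp = sum(_w(c, self.D) / n for c, n in zip(C, sizes) if n > 0)
        ssd_tot = _w(C.sum(axis=0), self.D) / N
        ssd_ap = ssd_tot - ssd_wp
        df = {"among_populations": int(P - 1), "within_populations": int(N - P)}
        sigma2_c = ssd_wp / (N - P) if N > P else 0.0
        n_c = (N - np.sum(sizes**2) / N) / (P - 1)
        sigma2_a = (ssd_ap / (P - 1) - sigma2_c) / n_c
        ssd = {"among_populations": ssd_ap, "within_populations": ssd_wp, "total": ssd_tot}
        return sigma2_a, sigma2_c, df, ssd

    def _three_level(
        self, C: np.ndarray, group_of_pop: np.ndarray
    ) -> tuple[float, float, float, dict, dict]:
        sizes = C.sum(axis=1)
        N, P = sizes.sum(), len(sizes)
        groups = np.unique(group_of_pop)
        G = len(groups)
        ssd_wp = sum(_w(c, self.D) / n for c, n in zip(C, sizes) if n > 0)
        ssd_tot = _w(C.sum(axis=0), self.D) / N
        ssd_wg = 0.0
        Ng = {}
        for g in groups:
            mask = group_of_pop == g
            Ng[g] = sizes[mask].sum()
            ssd_wg += _w(C[mask].sum(axis=0), self.D) / Ng[g]
        ssd_ap_wg = ssd_wg - ssd_wp
        ssd_ag = ssd_tot - ssd_wg
        df = {
            "among_groups": int(G - 1),
            "among_populations_within_groups": int(P - G),
            "within_populations": int(N - P),
        }
        sigma2_c = ssd_wp / (N - P) if N > P else 0.0
        scg = sum(np.sum(sizes[group_of_pop == g] ** 2) / Ng[g] for g in groups)
        n2 = (scg - np.sum(sizes**2) / N) / (G - 1)
        n3 = (N - sum(Ng[g] ** 2 for g in groups) / N) / (G - 1)
        if P > G:
            n1 = (N - scg) / (P - G)
            sigma2_b = (ssd_ap_wg / (P - G) - sigma2_c) / n1
        else:
            sigma2_b = 0.0  # singleton groups: no among-population-within level
        sigma2_a = (ssd_ag / (G - 1) - sigma2_c - n2 * sigma2_b) / n3
        ssd = {
            "among_groups": ssd_ag,
            "among_populations_within_groups": ssd_ap_wg,
            "within_populations": ssd_wp,
            "total": ssd_tot,
        }
        return sigma2_a, sigma2_b, sigma2_c, df, ssd

    def _phi(self, C: np.ndarray, group_of_pop: np.ndarray | None):
        if group_of_pop is None:
            a, cmp_c, df, ssd = self._two_level(C)
            denom = a + cmp_c
            phi_st = a / denom if denom != 0 else 0.0
            return AmovaResults(
                sigma2_a=a, sigma2_b=None, sigma2_c=cmp_c,
                phi_ST=phi_st, phi_CT=None, phi_SC=None, df=df, ssd=ssd,
            )
        a, b, c, df, ssd = self._three_level(C, group_of_pop)
        tot = a + b + c
        return AmovaResults(
            sigma2_a=a, sigma2_b=b, sigma2_c=c,
            phi_ST=(a + b) / tot if tot != 0 else 0.0,
            phi_CT=a / tot if tot != 0 else 0.0,
            phi_SC=b / (b + c) if (b + c) != 0 else 0.0,
            df=df, ssd=ssd,
        )

    def _group_array(self) -> np.ndarray | None:
        if self.grouping is None:
            return None
        arr = np.array([self.grouping[l] for l in self.labels])
        if len(np.unique(arr)) < 2:
            return None
        return arr

    def _counts_from_perm(self, hap_of_ind: np.ndarray) -> np.ndarray:
        H = self.C.shape[1]
        return np.array(
            [
                np.bincount(hap_of_ind[self._pop_slices[p] : self._pop_slices[p + 1]], minlength=H)
                for p in range(len(self.labels))
            ],
            dtype=float,
        )

    def fit(self, nperm: int = 10_100, seed: int = 0) -> AmovaResults:
        groups = self._group_array()
        obs = self._phi(self.C, groups)
        if nperm <= 0:
            return obs
        rng = np.random.default_rng(seed)
        hits = {"phi_ST": 0, "phi_SC": 0, "phi_CT": 0}

        for _ in range(nperm):
            # phi_ST: individuals permuted among all populations
            perm = rng.permutation(self._hap_of_ind)
            r = self._phi(self._counts_from_perm(perm), groups)
            if r.phi_ST >= obs.phi_ST:
                hits["phi_ST"] += 1
            if groups is not None:
                # phi_SC: individuals permuted among populations within groups
                perm_wg = self._hap_of_ind.copy()
                for g in np.unique(groups):
                    idx = np.concatenate(
                        [
                            np.arange(self._pop_slices[p], self._pop_slices[p + 1])
                            for p in np.flatnonzero(groups == g)
                        ]
                    )
                    perm_wg[idx] = perm_wg[rng.permutation(idx)]
                r = self._phi(self._counts_from_perm(perm_wg), groups)
                if r.phi_SC >= obs.phi_SC:
                    hits["phi_SC"] += 1
                # phi_CT: whole populations permuted among groups
                r = self._phi(self.C, groups[rng.permutation(len(groups))])
                if r.phi_CT >= obs.phi_CT:
                    hits["phi_CT"] += 1

        p = {"phi_ST": (hits["phi_ST"] + 1) / (nperm + 1)}
        if groups is not None:
            p["phi_SC"] = (hits["phi_SC"] + 1) / (nperm + 1)
            p["phi_CT"] = (hits["phi_CT"] + 1) / (nperm + 1)
        return AmovaResults(
            sigma2_a=obs.sigma2_a, sigma2_b=obs.sigma2_b, sigma2_c=obs.sigma2_c,
            phi_ST=obs.phi_ST, phi_CT=obs.phi_CT, phi_SC=obs.phi_SC,
            df=obs.df, ssd=obs.ssd, p_values=p, nperm=nperm,
        )


def phi_st_pair(
    a: RegionalSample,
    b: RegionalSample,
    dist: PairwiseDistanceMatrix,
    nperm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pairwise Φ_ST between two samples with an individual-permutation p-value.

    Degenerate case (no molecular variation in the pooled pair) returns
    Φ_ST = 0 with p = 1.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both samples need n >= 2")
    model = Amova([a, b], dist)
    if model._phi(model.C, None).ssd["total"] == 0.0:
        return 0.0, 1.0
    res = model.fit(nperm=nperm, seed=seed)
    return res.phi_ST, res.p_values["phi_ST"]


def phist_matrix(
    samples: list[RegionalSample],
    dist: PairwiseDistanceMatrix,
    nperm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Φ_ST below the diagonal, permutation p above, per sample label."""
    labels = [s.label for s in samples]
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            phi, p = phi_st_pair(samples[i], samples[j], dist, nperm=nperm, seed=seed + 997 * i + j)
            out.iloc[j, i] = phi
            out.iloc[i, j] = p
    return out


# ---------------------------------------------------------------------------
# SAMOVA


@dataclass(frozen=True)
class SamovaResults:
    K: int
    assignment: dict[str, int]
    phi_CT: float
    trace: list[tuple[int, float]]
    amova: AmovaResults

    def groups(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for pop, g in self.assignment.items():
            out.setdefault(g, []).append(pop)
        return [sorted(v) for _, v in sorted(out.items())]

    def summary(self) -> pd.DataFrame:
        return self.amova.summary()


class Samova:
    """Search for the K-group partition of populations maximizing Φ_CT.

    Simulated annealing over assignments: initial partitions are seeded by
    Voronoi tessellation around K randomly chosen populations (geography
    enters only through initialization — groups carry no hard contiguity
    constraint), moves reassign a single population to another group while
    keeping all K groups nonempty, and a geometric cooling schedule accepts
    uphill moves early.  Best assignment over ``n_init`` restarts is kept,
    first-found on ties.
    """

    def __init__(
        self,
        samples: list[RegionalSample],
        dist: PairwiseDistanceMatrix,
        coords: dict[str, tuple[float, float]] | None = None,
    ):
        self.samples = samples
        self.labels = [s.label for s in samples]
        self.model = Amova(samples, dist)
        self.coords = coords

    def _phi_ct(self, assign: np.ndarray) -> float:
        res = self.model._phi(self.model.C, assign.astype(str))
        return res.phi_CT

    def _voronoi_init(self, K: int, rng: np.random.Generator) -> np.ndarray:
        P = len(self.labels)
        if self.coords is None:
            assign = np.concatenate([np.arange(K), rng.integers(K, size=P - K)])
            return assign[rng.permutation(P)]
        seeds = rng.choice(P, size=K, replace=False)
        assign = np.empty(P, dtype=int)
        for i, lab in enumerate(self.labels):
            lat, lon = self.coords[lab]
            dists = [
                haversine_km(lat, lon, *self.coords[self.labels[s]]) for s in seeds
            ]
            assign[i] = int(np.argmin(dists))
        for g in range(K):  # guarantee nonempty groups
            if not np.any(assign == g):
                assign[seeds[g]] = g
        return assign

    def fit(
        self,
        K: int,
        n_init: int = 100,
        n_iter: int = 10_000,
        seed: int = 0,
        t0: float = 0.05,
        cooling: float = 0.999,
    ) -> SamovaResults:
        P = len(self.labels)
        if not 2 <= K <= P:
            raise ValueError(f"K={K} out of range for {P} populations")
        rng = np.random.default_rng(seed)
        best_assign, best_phi = None, -np.inf
        trace: list[tuple[int, float]] = []
        for restart in range(n_init):
            assign = self._voronoi_init(K, rng)
            phi = self._phi_ct(assign)
            cur_best, cur_best_phi = assign.copy(), phi
            temp = t0
            for it in range(n_iter):
                p = int(rng.integers(P))
                counts = np.bincount(assign, minlength=K)
                if counts[assign[p]] == 1:
                    continue  # would empty a group
                g_new = int(rng.integers(K - 1))
                if g_new >= assign[p]:
                    g_new += 1
                old = assign[p]
                assign[p] = g_new
                phi_new = self._phi_ct(assign)
                if phi_new >= phi or rng.random() < math.exp((phi_new - phi) / max(temp, 1e-12)):
                    phi = phi_new
                    if phi > cur_best_phi:
                        cur_best_phi, cur_best = phi, assign.copy()
                else:
                    assign[p] = old
                temp *= cooling
            trace.append((restart, cur_best_phi))
            if cur_best_phi > best_phi:
                best_phi, best_assign = cur_best_phi, cur_best
        amova_res = self.model._phi(self.model.C, best_assign.astype(str))
        return SamovaResults(
            K=K,
            assignment={l: int(g) for l, g in zip(self.labels, best_assign)},
            phi_CT=best_phi,
            trace=trace,
            amova=amova_res,
        )


# ---------------------------------------------------------------------------
# Mantel isolation by distance


@dataclass(frozen=True)
class MantelResults:
    r: float
    p: float
    n_populations: int
    n_pairs: int
    excluded_pairs: list[tuple[str, str]]
    transform: str = "ln(great-circle km) vs phi/(1-phi)"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": ["Mantel r", "p (permutation)", "populations", "pairs used"],
                "value": [self.r, self.p, self.n_populations, self.n_pairs],
            }
        )


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres."""
    rlat1, rlat2 = math.radians(lat1), math.radians(lat2)
    dlat = rlat2 - rlat1
    dlon = math.radians(lon2 - lon1)
    a = math.sin(dlat / 2) ** 2 + math.cos(rlat1) * math.cos(rlat2) * math.sin(dlon / 2) ** 2
    return 2 * 6371.0088 * math.asin(min(1.0, math.sqrt(a)))


class MantelIBD:
    """Isolation by distance: Mantel test of linearized Φ_ST on log distance.

    Genetic distance is Rousset-linearized Φ_ST/(1−Φ_ST); geographic distance
    is the natural log of great-circle distance between population centroids.
    Populations below ``min_n`` individuals are dropped before testing;
    pairs with Φ_ST = 1 (infinite transform) are excluded with a warning.
    """

    def __init__(
        self,
        phi: pd.DataFrame,
        coords: dict[str, tuple[float, float]],
        sample_sizes: dict[str, int] | None = None,
        min_n: int = 10,
    ):
        labels = [
            l
            for l in phi.index
            if sample_sizes is None or sample_sizes.get(l, 0) >= min_n
        ]
        if len(labels) < 3:
            raise ValueError("need at least three populations after the min-n filter")
        self.labels = labels
        P = len(labels)
        G = np.zeros((P, P))
        X = np.zeros((P, P))
        for i in range(P):
            for j in range(P):
                if i == j:
                    continue
                v = phi.loc[labels[i], labels[j]]
                if pd.isna(v):
                    v = phi.loc[labels[j], labels[i]]
                G[i, j] = v
                km = haversine_km(*coords[labels[i]], *coords[labels[j]])
                if km <= 0:
                    raise ValueError(
                        f"nonpositive geographic distance between {labels[i]} and {labels[j]}"
                    )
                X[i, j] = math.log(km)
        self.G, self.X = G, X

    @staticmethod
    def _condensed(M: np.ndarray) -> np.ndarray:
        iu = np.triu_indices(M.shape[0], 1)
        return M[iu]

    def fit(self, nperm: int = 10_000, seed: int = 0) -> MantelResults:
        P = len(self.labels)
        trans = np.where(self.G >= 1.0, np.inf, self.G / (1.0 - self.G))
        excluded = []
        iu = np.triu_indices(P, 1)
        for i, j in zip(*iu):
            if not np.isfinite(trans[i, j]):
                excluded.append((self.labels[i], self.labels[j]))
        if excluded:
            warnings.warn(f"excluding {len(excluded)} pair(s) with phi_ST = 1 from the Mantel test")

        def corr(g_matrix: np.ndarray) -> float:
            gv = self._condensed(g_matrix)
            xv = self._condensed(self.X)
            mask = np.isfinite(gv)
            if mask.sum() < 3:
                return float("nan")
            return float(np.corrcoef(gv[mask], xv[mask])[0, 1])

        r_obs = corr(trans)
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(nperm):
            perm = rng.permutation(P)
            if corr(trans[np.ix_(perm, perm)]) >= r_obs:
                hits += 1
        p = (hits + 1) / (nperm + 1)
        return MantelResults(
            r=r_obs,
            p=p,
            n_populations=P,
            n_pairs=int(np.isfinite(self._condensed(trans)).sum()),
            excluded_pairs=excluded,
        )
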