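"""Approximate Bayesian computation model choice among colonization scenarios.

The engine follows the classic rejection + multinomial-logistic-regression
recipe: simulate a reference table of parameter draws and summary
statistics under each scenario, standardize the statistics by their median
absolute deviation across the table, retain the accepted fraction closest
(Euclidean) to the observed vector, and estimate per-scenario posterior
probabilities with a distance-weighted (Epanechnikov kernel) multinomial
logistic regression evaluated at the observed point.  Plain rejection
proportions are reported alongside; they are also the fallback when the
regression is degenerate.

Summary statistics (fixed layout, identical for simulated and observed
data): per population the number of haplotypes, segregating sites, mean
pairwise differences and haplotype diversity; per population pair the
pairwise Φ_ST and the mean between-population difference count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import HaplotypeAlignment
from .distance import PairwiseDistanceMatrix
from .samples import RegionalSample
from .scenarios import (
    POPULATIONS,
    POPULATION_REGIONS,
    Scenario,
    ScenarioPriors,
    DemographicParameters,
    draw_valid_parameters,
    simulate_variant_matrix,
)

__all__ = [
    "summary_names",
    "summaries_from_counts",
    "summaries_from_matrix",
    "observed_summaries",
    "AbcReferenceTable",
    "build_reference_table",
    "AbcModelChoice",
    "AbcResults",
    "confusion_analysis",
]


def summary_names(pop_names=POPULATIONS) -> list[str]:
    names = []
    for p in pop_names:
        names += [f"K_{p}", f"S_{p}", f"kbar_{p}", f"h_{p}"]
    for i in range(len(pop_names)):
        for j in range(i + 1, len(pop_names)):
            names += [f"phist_{pop_names[i]}_{pop_names[j]}", f"dbar_{pop_names[i]}_{pop_names[j]}"]
    return names


def _phi_st_counts(ca: np.ndarray, cb: np.ndarray, D: np.ndarray) -> float:
    """Two-level molecular variance Φ_ST from two haplotype count vectors."""
    na, nb = ca.sum(), cb.sum()
    N = na + nb
    w_a = 0.5 * ca @ D @ ca
    w_b = 0.5 * cb @ D @ cb
    pooled = ca + cb
    ssd_tot = 0.5 * pooled @ D @ pooled / N
    ssd_w = w_a / na + w_b / nb
    sigma_c = (ssd_w) / (N - 2)
    n_c = N - (na * na + nb * nb) / N
    sigma_a = ((ssd_tot - ssd_w) - sigma_c) / n_c
    denom = sigma_a + sigma_c
    return float(sigma_a / denom) if denom != 0 else 0.0


def summaries_from_counts(
    counts: np.ndarray,
    D: np.ndarray,
    hap_sites: np.ndarray,
) -> np.ndarray:
    """Summary vector from per-population haplotype counts.

    Parameters
    ----------
    counts : (P, H) haplotype counts per population.
    D : (H, H) pairwise difference counts between haplotypes.
    hap_sites : (H, S) integer site codes per haplotype; negative codes mark
        missing/excluded characters and never segregate.
    """
    P, H = counts.shape
    out = []
    for p in range(P):
        c = counts[p].astype(float)
        n = c.sum()
        present = c > 0
        K = int(present.sum())
        if hap_sites.size and present.any():
            sub = hap_sites[present]
            S = 0
            for col in range(sub.shape[1]):
                vals = sub[:, col]
                vals = vals[vals >= 0]
                if vals.size and np.unique(vals).size > 1:
                    S += 1
        else:
            S = 0
        if n >= 2:
            kbar = float(c @ D @ c) / (n * (n - 1))
            p_freq = c / n
            h = n / (n - 1) * (1.0 - float(np.sum(p_freq**2)))
        else:
            kbar, h = 0.0, 0.0
        out += [K, S, kbar, h]
    for i in range(P):
        for j in range(i + 1, P):
            ci, cj = counts[i].astype(float), counts[j].astype(float)
            ni, nj = ci.sum(), cj.sum()
            phi = _phi_st_counts(ci, cj, D) if ni >= 2 and nj >= 2 else 0.0
            dbar = float(ci @ D @ cj) / (ni * nj) if ni and nj else 0.0
            out += [phi, dbar]
    return np.asarray(out, dtype=float)


def summaries_from_matrix(G: np.ndarray, pops: np.ndarray, n_pops: int) -> np.ndarray:
    """Summary vector from a simulated genotype matrix (individuals x sites)."""
    if G.size == 0:
        H = 1
        hap_of_ind = np.zeros(len(pops), dtype=np.int64)
        hap_sites = np.zeros((1, 0), dtype=np.int64)
    else:
        haps, hap_of_ind = np.unique(G, axis=0, return_inverse=True)
        H = haps.shape[0]
        hap_sites = haps.astype(np.int64)
    counts = np.zeros((n_pops, H))
    for p in range(n_pops):
        counts[p] = np.bincount(hap_of_ind[pops == p], minlength=H)
    if G.size == 0:
        D = np.zeros((1, 1))
    else:
        D = (hap_sites[:, None, :] != hap_sites[None, :, :]).sum(axis=2).astype(float)
    return summaries_from_counts(counts, D, hap_sites)


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": -1, "N": -2}


def observed_summaries(
    samples: list[RegionalSample],
    aln: HaplotypeAlignment,
    dist: PairwiseDistanceMatrix,
    population_regions: dict[str, list[str]] | None = None,
) -> np.ndarray:
    """Summary vector for observed data pooled into the scenario populations.

    Shares the statistics code path with the simulator output, which
    guarantees layout identity.  Regions not covered by the mapping are
    ignored; a population pooling to zero individuals raises ``ValueError``.
    """
    mapping = population_regions or POPULATION_REGIONS
    by_label = {s.label: s for s in samples if s.region != "ALL"}
    haps = list(aln.ids)
    hap_index = {h: i for i, h in enumerate(haps)}
    counts = np.zeros((len(POPULATIONS), len(haps)))
    for p_i, pop in enumerate(POPULATIONS):
        for region in mapping[pop]:
            s = by_label.get(region)
            if s is None:
                continue
            for h, c in s.counts.items():
                counts[p_i, hap_index[h]] += c
        if counts[p_i].sum() == 0:
            raise ValueError(f"population {pop} pools no sampled individuals")
    D = np.array([[dist.d[hap_index[a], hap_index[b]] for b in haps] for a in haps])
    arr = aln.as_array()
    hap_sites = np.vectorize(_CODE.get)(arr).astype(np.int64)
    return summaries_from_counts(counts, D, hap_sites)


# ---------------------------------------------------------------------------
# Reference table


@dataclass
class AbcReferenceTable:
    scenario_ids: np.ndarray  # (R,)
    parameters: pd.DataFrame  # (R, n_params)
    stats: np.ndarray  # (R, n_stats)
    stat_names: list[str]
    seed: int
    n_failed: int = 0

    def __post_init__(self):
        if not (len(self.scenario_ids) == len(self.parameters) == len(self.stats)):
            raise ValueError("reference table row counts disagree")

    @property
    def n_rows(self) -> int:
        return len(self.scenario_ids)

    def to_csv(self, path) -> None:
        df = self.parameters.copy()
        df.insert(0, "scenario", self.scenario_ids)
        for i, name in enumerate(self.stat_names):
            df[name] = self.stats[:, i]
        df.to_csv(path, index=False)


def build_reference_table(
    scenarios: list[Scenario],
    n_sim: int,
    sample_sizes: dict[str, int],
    priors: ScenarioPriors | None = None,
    seed: int = 1,
    L: int = 318,
    bottleneck: bool = True,
) -> AbcReferenceTable:
    """Simulate ``n_sim`` datasets per scenario and collect summary statistics.

    Rows are generated in a streaming loop (one simulation in memory at a
    time); a failing simulation is skipped and counted, never imputed.
    """
    priors = priors or ScenarioPriors()
    rng = np.random.default_rng(seed)
    ids, rows, stats = [], [], []
    n_failed = 0
    for scen in scenarios:
        for _ in range(n_sim):
            params = draw_valid_parameters(scen, priors, rng)
            sim_seed = int(rng.integers(1, 2**31 - 1))
            try:
                G, pops = simulate_variant_matrix(
                    scen, params, sample_sizes, L=L, seed=sim_seed, bottleneck=bottleneck
                )
                vec = summaries_from_matrix(G, pops, len(POPULATIONS))
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"simulation failed for scenario {scen.id}: {exc}")
                n_failed += 1
                continue
            ids.append(scen.id)
            rows.append(params.as_row())
            stats.append(vec)
    return AbcReferenceTable(
        scenario_ids=np.asarray(ids),
        parameters=pd.DataFrame(rows),
        stats=np.asarray(stats),
        stat_names=summary_names(),
        seed=seed,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# Model choice


@dataclass(frozen=True)
class AbcResults:
    posterior_probabilities: dict[int, float]
    rejection_proportions: dict[int, float]
    selected: int
    accepted_fraction: float
    n_accepted: int
    used_fallback: bool
    dropped_stats: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        ids = sorted(self.posterior_probabilities)
        return pd.DataFrame(
            {
                "scenario": ids,
                "posterior_probability": [self.posterior_probabilities[i] for i in ids],
                "rejection_proportion": [self.rejection_proportions[i] for i in ids],
            }
        )


class AbcModelChoice:
    """Scenario choice from a reference table and an observed summary vector."""

    def __init__(self, table: AbcReferenceTable, observed: np.ndarray):
        if table.n_rows == 0:
            raise ValueError("empty reference table")
        observed = np.asarray(observed, dtype=float)
        if observed.shape != (table.stats.shape[1],):
            raise ValueError("observed summary layout does not match the table")
        self.table = table
        self.observed = observed

    def fit(
        self, accept_fraction: float = 0.01, seed: int = 0, lda: bool = True
    ) -> AbcResults:
        """Run rejection + weighted multinomial logistic regression.

        With ``lda=True`` (default) the standardized statistics are first
        projected onto the linear discriminant axes separating the
        scenarios, and rejection distances and the regression both operate
        in that (n_scenarios − 1)-dimensional space — the pre-processing
        used by the reference ABC model-choice implementations.
        """
        stats = self.table.stats
        med = np.median(stats, axis=0)
        mad = np.median(np.abs(stats - med), axis=0)
        keep = mad > 0
        dropped = [n for n, k in zip(self.table.stat_names, keep) if not k]
        if dropped:
            warnings.warn(f"dropping zero-spread summary statistics: {dropped}")
        z = (stats[:, keep] - med[keep]) / mad[keep]
        z_obs = (self.observed[keep] - med[keep]) / mad[keep]
        n_classes = len(set(int(i) for i in self.table.scenario_ids))
        if lda and n_classes >= 2:
            from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

            proj = LinearDiscriminantAnalysis(n_components=n_classes - 1)
            z = proj.fit_transform(z, self.table.scenario_ids)
            z_obs = proj.transform(z_obs[None, :])[0]
        d = np.sqrt(np.sum((z - z_obs) ** 2, axis=1))
        n_accept = max(1, int(round(accept_fraction * len(d))))
        order = np.argsort(d, kind="stable")
        acc = order[:n_accept]
        ids = self.table.scenario_ids
        all_ids = sorted(set(int(i) for i in ids))
        acc_ids = ids[acc]
        rejection = {
            s: float(np.mean(acc_ids == s)) for s in all_ids
        }
        missing = [s for s in all_ids if rejection[s] == 0.0]
        if missing:
            warnings.warn(f"scenario(s) {missing} absent from the accepted set")
        dmax = d[acc].max()
        w = 1.0 - (d[acc] / dmax) ** 2 if dmax > 0 else np.ones(n_accept)
        w = np.clip(w, 1e-8, None)
        posterior, fallback = self._logistic(z[acc], acc_ids, z_obs, w, all_ids, seed)
        if posterior is None:
            posterior = dict(rejection)
            fallback = True
        sel = max(posterior, key=posterior.get)
        return AbcResults(
            posterior_probabilities=posterior,
            rejection_proportions=rejection,
            selected=int(sel),
            accepted_fraction=accept_fraction,
            n_accepted=n_accept,
            used_fallback=fallback,
            dropped_stats=dropped,
        )

    @staticmethod
    def _logistic(X, y, x_obs, w, all_ids, seed):
        present = np.unique(y)
        if len(present) < 2:
            return None, True
        from sklearn.linear_model import LogisticRegression

        try:
            clf = LogisticRegression(max_iter=2000, C=1.0, random_state=seed)
            clf.fit(X, y, sample_weight=w)
            probs = clf.predict_proba(x_obs[None, :])[0]
        except Exception:
            return None, True
        out = {int(s): 0.0 for s in all_ids}
        for cls, p in zip(clf.classes_, probs):
            out[int(cls)] = float(p)
        total = sum(out.values())
        return {k: v / total for k, v in out.items()}, False


def confusion_analysis(
    scenarios: list[Scenario],
    n_pods: int,
    n_sim: int,
    sample_sizes: dict[str, int],
    priors: ScenarioPriors | None = None,
    accept_fraction: float = 0.01,
    seed: int = 1,
    L: int = 318,
    bottleneck: bool = True,
    table: AbcReferenceTable | None = None,
) -> tuple[dict[int, float], dict[int, float]]:
    """Type I / type II error rates from pseudo-observed datasets (pods).

    For each scenario s, ``n_pods`` datasets are simulated from its prior and
    classified against the reference table.  type1(s) is the fraction of
    pods generated under s for which the selected scenario differs from s;
    type2(s) is the fraction of pods generated under the *other* scenarios
    for which s is (wrongly) selected.
    """
    priors = priors or ScenarioPriors()
    if table is None:
        table = build_reference_table(
            scenarios, n_sim, sample_sizes, priors, seed=seed, L=L, bottleneck=bottleneck
        )
    rng = np.random.default_rng(seed + 1)
    selections: dict[int, list[int]] = {}
    for scen in scenarios:
        picks = []
        for _ in range(n_pods):
            params = draw_valid_parameters(scen, priors, rng)
            G, pops = simulate_variant_matrix(
                scen, params, sample_sizes, L=L,
                seed=int(rng.integers(1, 2**31 - 1)), bottleneck=bottleneck,
            )
            obs = summaries_from_matrix(G, pops, len(POPULATIONS))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = AbcModelChoice(table, obs).fit(accept_fraction=accept_fraction)
            picks.append(res.selected)
        selections[scen.id] = picks
    type1 = {
        s: float(np.mean([p != s for p in selections[s]])) for s in selections
    }
    type2 = {}
    for s in selections:
        others = [p for s2, picks in selections.items() if s2 != s for p in picks]
        type2[s] = float(np.mean([p == s for p in others])) if others else 0.0
    return type1, type2
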