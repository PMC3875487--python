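"""Population structure: ΦST, AMOVA variance components, SAMOVA, Mantel IBD."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gulo_phylogeo.distance import PairwiseDistanceMatrix, pairwise_differences
from gulo_phylogeo.samples import RegionalSample
from gulo_phylogeo.structure import (
    Amova,
    MantelIBD,
    Samova,
    haversine_km,
    phi_st_pair,
    phist_matrix,
)


def _sample(region, counts, era="contemporary", lat=None, lon=None):
    return RegionalSample(region, era, dict(counts), latitude=lat, longitude=lon)


def _dist(ids, pairs):
    k = len(ids)
    d = np.zeros((k, k))
    for (a, b), v in pairs.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    return PairwiseDistanceMatrix(tuple(ids), d)


def brute_force_amova(pop_of_ind, hap_of_ind, D, group_of_pop=None):
    """Independent sums-of-squared-deviations computation at individual level."""
    N = len(pop_of_ind)
    pops = sorted(set(pop_of_ind))
    d2 = np.array([[D[a][b] for b in hap_of_ind] for a in hap_of_ind], dtype=float)

    def ssd(idx):
        idx = list(idx)
        return sum(d2[i][j] for i in idx for j in idx) / (2.0 * len(idx))

    ssd_tot = ssd(range(N))
    ssd_wp = sum(ssd([i for i in range(N) if pop_of_ind[i] == p]) for p in pops)
    sizes = {p: sum(1 for q in pop_of_ind if q == p) for p in pops}
    if group_of_pop is None:
        P = len(pops)
        sigma_c = ssd_wp / (N - P)
        n_c = (N - sum(v * v for v in sizes.values()) / N) / (P - 1)
        sigma_a = ((ssd_tot - ssd_wp) / (P - 1) - sigma_c) / n_c
        return sigma_a, sigma_c
    groups = sorted(set(group_of_pop.values()))
    G, P = len(groups), len(pops)
    ssd_wg = sum(
        ssd([i for i in range(N) if group_of_pop[pop_of_ind[i]] == g]) for g in groups
    )
    Ng = {g: sum(sizes[p] for p in pops if group_of_pop[p] == g) for g in groups}
    sigma_c = ssd_wp / (N - P)
    scg = sum(
        sum(sizes[p] ** 2 for p in pops if group_of_pop[p] == g) / Ng[g] for g in groups
    )
    n1 = (N - scg) / (P - G)
    n2 = (scg - sum(v * v for v in sizes.values()) / N) / (G - 1)
    n3 = (N - sum(v * v for v in Ng.values()) / N) / (G - 1)
    sigma_b = ((ssd_wg - ssd_wp) / (P - G) - sigma_c) / n1
    sigma_a = ((ssd_tot - ssd_wg) / (G - 1) - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


class TestPhiStPair:
    def test_scandinavian_configuration(self, swe_nor):
        """61+1 vs 108 with 3-step distance prints as 0.01 with P ~ 0.36."""
        aln, swe, nor = swe_nor
        dist = pairwise_differences(aln, gap_mode="fifth_state")
        phi, p = phi_st_pair(swe, nor, dist, nperm=10_000, seed=7)
        assert phi == pytest.approx(0.009427, abs=1e-5)
        assert round(phi, 2) == 0.01
        # analytic permutation probability: the variant individual must land
        # in the size-62 group, 62/170
        assert p == pytest.approx(62 / 170, abs=0.015)

    def test_fixed_difference_is_one(self):
        d = _dist(["x", "y"], {("x", "y"): 4})
        a = _sample("A", {"x": 10})
        b = _sample("B", {"y": 12})
        phi, _ = phi_st_pair(a, b, d, nperm=50, seed=0)
        assert phi == pytest.approx(1.0)

    def test_identical_distributions_nonpositive(self):
        d = _dist(["x", "y"], {("x", "y"): 2})
        a = _sample("A", {"x": 6, "y": 6})
        b = _sample("B", {"x": 6, "y": 6})
        phi, _ = phi_st_pair(a, b, d, nperm=50, seed=0)
        assert phi <= 0.0

    def test_degenerate_defined_zero(self):
        d = _dist(["x"], {})
        phi, p = phi_st_pair(_sample("A", {"x": 5}), _sample("B", {"x": 5}), d, nperm=10, seed=0)
        assert (phi, p) == (0.0, 1.0)

    def test_symmetry_and_relabeling(self):
        d = _dist(["x", "y", "z"], {("x", "y"): 1, ("x", "z"): 3, ("y", "z"): 2})
        a = _sample("A", {"x": 5, "y": 2})
        b = _sample("B", {"y": 3, "z": 4})
        phi_ab, _ = phi_st_pair(a, b, d, nperm=0 or 5, seed=1)
        phi_ba, _ = phi_st_pair(b, a, d, nperm=0 or 5, seed=1)
        assert phi_ab == pytest.approx(phi_ba)
        # relabel haplotypes
        d2 = _dist(["u", "v", "w"], {("u", "v"): 1, ("u", "w"): 3, ("v", "w"): 2})
        a2 = _sample("A", {"u": 5, "v": 2})
        b2 = _sample("B", {"v": 3, "w": 4})
        phi2, _ = phi_st_pair(a2, b2, d2, nperm=5, seed=1)
        assert phi_ab == pytest.approx(phi2)


class TestAmova:
    def test_variance_components_oracle(self, rng):
        haps = ["x", "y", "z"]
        Dmat = {
            "x": {"x": 0, "y": 1, "z": 4},
            "y": {"x": 1, "y": 0, "z": 3},
            "z": {"x": 4, "y": 3, "z": 0},
        }
        d = _dist(haps, {("x", "y"): 1, ("x", "z"): 4, ("y", "z"): 3})
        for rep in range(20):
            P = int(rng.integers(2, 5))
            samples, pop_of_ind, hap_of_ind = [], [], []
            for p in range(P):
                counts = {}
                n_p = int(rng.integers(2, 8))
                for _ in range(n_p):
                    h = haps[int(rng.integers(3))]
                    counts[h] = counts.get(h, 0) + 1
                    pop_of_ind.append(f"P{p}")
                    hap_of_ind.append(h)
                samples.append(_sample(f"P{p}", counts))
            res = Amova(samples, d).fit(nperm=0)
            sa, sc = brute_force_amova(pop_of_ind, hap_of_ind, Dmat)
            assert res.sigma2_a == pytest.approx(sa, abs=1e-10)
            assert res.sigma2_c == pytest.approx(sc, abs=1e-10)

            if P >= 4:
                grouping = {f"P{p}": ("G0" if p < 2 else "G1") for p in range(P)}
                res3 = Amova(samples, d, grouping=grouping).fit(nperm=0)
                sa3, sb3, sc3 = brute_force_amova(
                    pop_of_ind, hap_of_ind, Dmat, group_of_pop=grouping
                )
                assert res3.sigma2_a == pytest.approx(sa3, abs=1e-10)
                assert res3.sigma2_b == pytest.approx(sb3, abs=1e-10)
                assert res3.sigma2_c == pytest.approx(sc3, abs=1e-10)
                assert sum(res3.percentages) == pytest.approx(100.0, abs=0.01)

    def test_two_populations_consistent_with_pair(self, swe_nor):
        aln, swe, nor = swe_nor
        dist = pairwise_differences(aln, gap_mode="fifth_state")
        res = Amova([swe, nor], dist).fit(nperm=0)
        phi, _ = phi_st_pair(swe, nor, dist, nperm=1, seed=0)
        assert res.phi_ST == pytest.approx(phi)

    def test_single_group_collapses_to_two_level(self):
        d = _dist(["x", "y"], {("x", "y"): 2})
        samples = [_sample("A", {"x": 4}), _sample("B", {"y": 4})]
        res = Amova(samples, d, grouping={"A": "g", "B": "g"}).fit(nperm=0)
        assert res.sigma2_b is None and res.phi_CT is None

    def test_unassigned_population_raises(self):
        d = _dist(["x"], {})
        samples = [_sample("A", {"x": 4}), _sample("B", {"x": 4})]
        with pytest.raises(KeyError):
            Amova(samples, d, grouping={"A": "g"})


class TestSamova:
    def _clustered(self):
        """Six populations in two clusters fixed for distant haplotypes."""
        d = _dist(["x", "y"], {("x", "y"): 6})
        samples = [
            _sample("P0", {"x": 8}, lat=60, lon=10),
            _sample("P1", {"x": 7, "y": 1}, lat=61, lon=12),
            _sample("P2", {"x": 8}, lat=62, lon=14),
            _sample("P3", {"y": 8}, lat=40, lon=-100),
            _sample("P4", {"y": 7, "x": 1}, lat=41, lon=-102),
            _sample("P5", {"y": 8}, lat=42, lon=-104),
        ]
        return samples, d

    def test_recovers_true_partition_vs_exhaustive(self):
        samples, d = self._clustered()
        model = Samova(samples, d, coords={s.label: (s.latitude, s.longitude) for s in samples})
        res = model.fit(K=2, n_init=5, n_iter=300, seed=3)
        # exhaustive search over all 2-partitions
        labels = [s.label for s in samples]
        best_phi, best_parts = -np.inf, None
        for mask in range(1, 2 ** len(labels) - 1):
            assign = np.array([(mask >> i) & 1 for i in range(len(labels))])
            phi = model._phi_ct(assign)
            if phi > best_phi:
                best_phi, best_parts = phi, assign
        assert res.phi_CT == pytest.approx(best_phi, abs=1e-12)
        got = frozenset(frozenset(g) for g in res.groups())
        true = frozenset([frozenset(["P0", "P1", "P2"]), frozenset(["P3", "P4", "P5"])])
        assert got == true

    def test_k_equals_p_singletons(self):
        samples, d = self._clustered()
        model = Samova(samples, d)
        res = model.fit(K=6, n_init=1, n_iter=10, seed=0)
        assert sorted(map(len, res.groups())) == [1] * 6
        singleton = Amova(
            samples, d, grouping={s.label: s.label for s in samples}
        ).fit(nperm=0)
        assert res.phi_CT == pytest.approx(singleton.phi_CT)

    def test_k_out_of_range(self):
        samples, d = self._clustered()
        with pytest.raises(ValueError):
            Samova(samples, d).fit(K=7)


class TestMantel:
    def _coords(self):
        return {
            "A": (50.0, 0.0), "B": (52.0, 5.0), "C": (55.0, 15.0),
            "D": (60.0, 30.0), "E": (64.0, 50.0),
        }

    def _phi_from_transform(self, coords, f):
        labels = list(coords)
        P = len(labels)
        phi = pd.DataFrame(0.0, index=labels, columns=labels)
        for i in range(P):
            for j in range(P):
                if i == j:
                    continue
                km = haversine_km(*coords[labels[i]], *coords[labels[j]])
                t = f(math.log(km))
                phi.iloc[i, j] = t / (1 + t)  # so phi/(1-phi) = t
        return phi

    def test_monotone_transform_gives_r_one(self):
        coords = self._coords()
        phi = self._phi_from_transform(coords, lambda x: 0.05 * x + 0.01)
        res = MantelIBD(phi, coords).fit(nperm=500, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-9)
        assert res.p <= 0.05

    def test_independent_matrices_small_r(self, rng):
        coords = self._coords()
        labels = list(coords)
        phi = pd.DataFrame(0.0, index=labels, columns=labels)
        for i in range(5):
            for j in range(i + 1, 5):
                v = rng.uniform(0.05, 0.4)
                phi.iloc[i, j] = phi.iloc[j, i] = v
        res = MantelIBD(phi, coords).fit(nperm=2000, seed=4)
        assert abs(res.r) < 0.9
        assert 0.0 < res.p <= 1.0

    def test_joint_relabeling_invariance(self, rng):
        coords = self._coords()
        phi = self._phi_from_transform(coords, lambda x: 0.02 * x + 0.05)
        # jitter to break exactness
        labels = list(coords)
        for i in range(5):
            for j in range(i + 1, 5):
                phi.iloc[i, j] = phi.iloc[j, i] = phi.iloc[i, j] + rng.uniform(0, 0.05)
        r1 = MantelIBD(phi, coords).fit(nperm=10, seed=0).r
        perm = ["C", "A", "E", "B", "D"]
        phi2 = phi.loc[perm, perm]
        r2 = MantelIBD(phi2, coords).fit(nperm=10, seed=0).r
        assert r1 == pytest.approx(r2)

    def test_phi_one_pairs_excluded_with_warning(self):
        coords = self._coords()
        phi = self._phi_from_transform(coords, lambda x: 0.05 * x + 0.01)
        phi.iloc[0, 1] = phi.iloc[1, 0] = 1.0
        with pytest.warns(UserWarning):
            res = MantelIBD(phi, coords).fit(nperm=100, seed=0)
        assert res.n_pairs == 9
        assert res.excluded_pairs == [("A", "B")]

    def test_min_n_filter(self):
        coords = self._coords()
        phi = self._phi_from_transform(coords, lambda x: 0.05 * x + 0.01)
        sizes = {"A": 30, "B": 30, "C": 5, "D": 30, "E": 30}
        res = MantelIBD(phi, coords, sample_sizes=sizes, min_n=10).fit(nperm=10, seed=0)
        assert res.n_populations == 4
        with pytest.raises(ValueError):
            MantelIBD(phi, coords, sample_sizes={k: 1 for k in coords}, min_n=10)

    def test_against_skbio_oracle(self):
        """Correlation agrees with the reference Mantel implementation."""
        from skbio.stats.distance import DistanceMatrix, mantel

        coords = self._coords()
        labels = list(coords)
        rng = np.random.default_rng(11)
        phi = pd.DataFrame(0.0, index=labels, columns=labels)
        for i in range(5):
            for j in range(i + 1, 5):
                phi.iloc[i, j] = phi.iloc[j, i] = rng.uniform(0.05, 0.5)
        res = MantelIBD(phi, coords).fit(nperm=10, seed=0)
        trans = (phi / (1 - phi)).to_numpy()
        np.fill_diagonal(trans, 0.0)
        geo = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                if i != j:
                    geo[i, j] = math.log(
                        haversine_km(*coords[labels[i]], *coords[labels[j]])
                    )
        r_ref, _, _ = mantel(
            DistanceMatrix(trans, labels), DistanceMatrix(geo, labels),
            permutations=0,
        )
        assert res.r == pytest.approx(r_ref, abs=1e-9)


def test_phist_matrix_layout(mng, swe_nor):
    aln, swe, nor = swe_nor
    dist = pairwise_differences(aln)
    m = phist_matrix([swe, nor], dist, nperm=99, seed=0)
    assert not np.isnan(m.loc["NOR", "SWE"])  # phi below diagonal
    assert not np.isnan(m.loc["SWE", "NOR"])  # p above diagonal
    assert np.isnan(m.loc["SWE", "SWE"])
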