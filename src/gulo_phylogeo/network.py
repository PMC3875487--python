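"""Median-joining haplotype networks.

Classic quasi-median network construction: iterate minimum-spanning-network
(MSN) building over the current vertex set (observed haplotypes plus
inferred median vectors), propose quasi-medians of triplets that are at
least partially linked in the MSN, keep those whose star connection cost is
within tolerance ε of the minimum, and finally prune median vectors that
end with degree ≤ 2.  With ε = 0 and unit pairwise distances the result is
exactly the minimum spanning network.

The MSN is characterized through single-linkage clustering: an edge (u, v)
belongs to the ε-relaxed MSN iff d(u, v) ≤ sl(u, v) + ε, where sl is the
single-linkage (cophenetic) distance — the weight at which u and v first
become connected.  This makes the network the union of all minimum spanning
trees, guaranteeing it contains an MST of the observed haplotypes.

Ties are broken lexicographically by node id for determinism.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .alignment import HaplotypeAlignment

__all__ = ["median_joining", "export_network", "read_network"]

_MISSING = {"N"}


def _distance(a: np.ndarray, b: np.ndarray, gap_mode: str) -> int:
    mask = ~np.isin(a, list(_MISSING)) & ~np.isin(b, list(_MISSING))
    if gap_mode != "fifth_state":
        mask &= (a != "-") & (b != "-")
    return int(np.sum((a != b) & mask))


def _pairwise(seqs: list[np.ndarray], gap_mode: str) -> np.ndarray:
    k = len(seqs)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = _distance(seqs[i], seqs[j], gap_mode)
    return D


def _msn_edges(D: np.ndarray, epsilon: int) -> set[tuple[int, int]]:
    """ε-relaxed minimum-spanning-network edges via single-linkage thresholds."""
    k = D.shape[0]
    if k == 2:
        return {(0, 1)}
    Z = linkage(squareform(D, checks=False), method="single")
    # single-linkage cophenetic distances
    from scipy.cluster.hierarchy import cophenet

    sl = squareform(cophenet(Z))
    edges = set()
    for i in range(k):
        for j in range(i + 1, k):
            if D[i, j] <= sl[i, j] + epsilon:
                edges.add((i, j))
    return edges


def _quasi_medians(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> list[np.ndarray]:
    """Majority-consensus medians of a sequence triple.

    At columns where all three states differ the quasi-median branches into
    one candidate per state; elsewhere the majority state is taken.
    """
    cols = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            cols.append((a,))
        elif b == c:
            cols.append((b,))
        else:
            cols.append((a, b, c))
    out = []
    for combo in itertools.product(*cols):
        out.append(np.array(combo, dtype="U1"))
        if len(out) >= 27:  # cap the branching of fully discordant triples
            break
    return out


def median_joining(
    aln: HaplotypeAlignment,
    freqs: dict[str, int] | None = None,
    epsilon: int = 0,
    gap_mode: str = "exclude",
    region_freqs: dict[str, dict[str, int]] | None = None,
    max_rounds: int = 20,
) -> nx.Graph:
    """Build the median-joining network of an alignment.

    Returns a networkx graph whose nodes carry ``frequency`` (0 for median
    vectors), ``median`` (bool) and ``regions`` (per-region counts, JSON
    string) attributes, and whose edges carry integer ``weight`` mutational
    steps.
    """
    if len(aln) < 2:
        raise ValueError("need at least two haplotypes")
    names = list(aln.ids)
    seqs = [np.array(list(s), dtype="U1") for s in aln.sequences]
    n_observed = len(names)

    def key(seq: np.ndarray) -> str:
        return "".join(seq)

    known = {key(s) for s in seqs}
    for round_no in range(max_rounds):
        D = _pairwise(seqs, gap_mode)
        edges = _msn_edges(D, epsilon)
        linked: dict[int, set[int]] = {}
        for i, j in edges:
            linked.setdefault(i, set()).add(j)
            linked.setdefault(j, set()).add(i)
        candidates: dict[str, tuple[np.ndarray, float]] = {}
        lam_min = np.inf
        for i, j, k in itertools.combinations(range(len(seqs)), 3):
            n_links = sum(
                1 for a, b in ((i, j), (i, k), (j, k)) if b in linked.get(a, ())
            )
            if n_links < 2:
                continue
            for m in _quasi_medians(seqs[i], seqs[j], seqs[k]):
                ks = key(m)
                if ks in known:
                    continue
                cost = (
                    _distance(seqs[i], m, gap_mode)
                    + _distance(seqs[j], m, gap_mode)
                    + _distance(seqs[k], m, gap_mode)
                )
                lam_min = min(lam_min, cost)
                prev = candidates.get(ks)
                if prev is None or cost < prev[1]:
                    candidates[ks] = (m, cost)
        accepted = [
            (ks, m) for ks, (m, cost) in sorted(candidates.items())
            if cost <= lam_min + epsilon
        ]
        if not accepted:
            break
        for ks, m in accepted:
            names.append(f"mv{len(names) - n_observed + 1}")
            seqs.append(m)
            known.add(ks)

    # prune median vectors with degree <= 2, recomputing the MSN each pass
    while True:
        D = _pairwise(seqs, gap_mode)
        edges = _msn_edges(D, epsilon)
        deg = Counter()
        for i, j in edges:
            deg[i] += 1
            deg[j] += 1
        drop = sorted(
            i for i in range(n_observed, len(seqs)) if deg[i] <= 2
        )
        if not drop:
            break
        for i in reversed(drop):
            del names[i], seqs[i]

    freqs = freqs or {}
    region_freqs = region_freqs or {}
    G = nx.Graph()
    for i, name in enumerate(names):
        is_median = i >= n_observed
        G.add_node(
            name,
            frequency=0 if is_median else int(freqs.get(name, 0)),
            median=is_median,
            regions=json.dumps({} if is_median else region_freqs.get(name, {})),
        )
    D = _pairwise(seqs, gap_mode)
    for i, j in _msn_edges(D, epsilon):
        G.add_edge(names[i], names[j], weight=int(D[i, j]))
    return G


def export_network(net: nx.Graph, path: str | Path, edge_list: str | Path | None = None) -> None:
    """Write GraphML (node frequencies, region breakdowns, edge weights) and
    optionally a plain edge-list TSV."""
    nx.write_graphml(net, str(path))
    if edge_list is not None:
        with open(edge_list, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, d in sorted(net.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']}\n")


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
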