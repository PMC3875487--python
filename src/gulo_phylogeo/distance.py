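"""Pairwise nucleotide-difference matrices between haplotypes.

These counts are the molecular distances feeding ΦST/AMOVA (as squared
Euclidean distances, the convention of distance-based molecular variance
analysis), the mismatch distribution, and the haplotype network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import HaplotypeAlignment

__all__ = ["PairwiseDistanceMatrix", "pairwise_differences"]


@dataclass(frozen=True)
class PairwiseDistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray  # (k, k) symmetric, zero diagonal

    def __post_init__(self):
        d = self.d
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if (d < 0).any() or not np.allclose(d, d.T) or np.diag(d).any():
            raise ValueError("distance matrix must be symmetric, nonnegative, zero-diagonal")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])

    def submatrix(self, ids: list[str]) -> "PairwiseDistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return PairwiseDistanceMatrix(tuple(ids), self.d[np.ix_(idx, idx)])


def pairwise_differences(
    aln: HaplotypeAlignment, gap_mode: str = "exclude"
) -> PairwiseDistanceMatrix:
    """Count differing, non-wildcard positions for every haplotype pair.

    ``N`` never contributes.  Under ``gap_mode="exclude"`` positions where
    either sequence is gapped are skipped; ``"fifth_state"`` counts a gap as
    an ordinary character.  Because wildcard masking is pairwise, the
    triangle inequality need not hold for N-rich sequences.
    """
    arr = aln.as_array()
    k = len(aln)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arr[i], arr[j]
            mask = (a != "N") & (b != "N")
            if gap_mode != "fifth_state":
                mask &= (a != "-") & (b != "-")
            d[i, j] = d[j, i] = int(np.sum((a != b) & mask))
    return PairwiseDistanceMatrix(tuple(aln.ids), d)
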