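"""Optional validation against published supplementary haplotype tables.

Surveys of this kind publish (i) a variable-position table listing, for
each haplotype, its state at every segregating position of the alignment
frame, and (ii) a per-region haplotype count (or percent-frequency) table.
Given those two files this module reconstructs the haplotype alignment and
regional samples and recomputes the pooled dataset-level statistics — the
haplotype and variable-site totals, the dominant haplotype frequency, the
pooled Fu's Fs, and the mismatch sudden-expansion goodness of fit — so the
package's output can be validated against a published dataset without
redistributing it.

File formats (tab- or comma-delimited):

* variable positions: first column ``haplotype``; remaining column headers
  are 1-based alignment positions; cells are states in {A,C,G,T,-}.  The
  first data row is taken as the reference haplotype; empty cells or '.'
  inherit the reference state.
* regional counts: first column ``haplotype``; remaining columns are region
  labels; cells are nonnegative counts of individuals.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .alignment import HaplotypeAlignment
from .diversity import fus_fs_value, mean_pairwise_differences
from .distance import pairwise_differences
from .mismatch import SuddenExpansionModel, mismatch_observed
from .samples import CONTEMPORARY, RegionalSample, pooled_sample

__all__ = ["read_variable_position_table", "read_regional_count_table", "validate_supplementary"]


def _rows(path: str | Path) -> list[list[str]]:
    text = Path(path).read_text().strip()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    return [row for row in csv.reader(text.splitlines(), delimiter=delim) if row]


def read_variable_position_table(path: str | Path, L: int = 318) -> HaplotypeAlignment:
    """Reconstruct full-frame haplotype sequences from a variable-position table.

    Positions not listed are filled with a constant background state (they
    are invariant by construction, so every statistic that depends only on
    differences is unaffected by the choice)."""
    rows = _rows(path)
    header = rows[0]
    positions = [int(p) for p in header[1:]]
    if positions and max(positions) > L:
        raise ValueError(f"position {max(positions)} beyond frame length {L}")
    names, states = [], []
    for row in rows[1:]:
        names.append(row[0])
        states.append([s.strip().upper() for s in row[1:]])
    ref = states[0]
    filled = [
        [ref[j] if s in ("", ".") else s for j, s in enumerate(row)]
        for row in states
    ]
    seqs = []
    for row in filled:
        seq = ["A"] * L
        for pos, s in zip(positions, row):
            seq[pos - 1] = s
        seqs.append("".join(seq))
    return HaplotypeAlignment(tuple(names), tuple(seqs))


def read_regional_count_table(path: str | Path) -> list[RegionalSample]:
    rows = _rows(path)
    regions = rows[0][1:]
    counts: dict[str, dict[str, int]] = {r: {} for r in regions}
    for row in rows[1:]:
        hap = row[0]
        for region, cell in zip(regions, row[1:]):
            c = int(round(float(cell or 0)))
            if c > 0:
                counts[region][hap] = c
    out = []
    for region, c in counts.items():
        if c:
            era = "historic" if region.endswith("_H") else CONTEMPORARY
            out.append(RegionalSample(region=region.removesuffix("_H"), era=era, counts=c))
    return out


def validate_supplementary(
    positions_path: str | Path,
    counts_path: str | Path,
    L: int = 318,
    nboot: int = 100,
    seed: int = 1,
) -> dict:
    """Recompute pooled dataset statistics from supplementary-style tables."""
    aln = read_variable_position_table(positions_path, L=L)
    samples = read_regional_count_table(counts_path)
    unknown = {h for s in samples for h in s.counts} - set(aln.ids)
    if unknown:
        raise KeyError(f"count table references unknown haplotypes: {sorted(unknown)}")
    pooled = pooled_sample(samples)
    dist = pairwise_differences(aln)
    from .alignment import variable_sites

    kbar = mean_pairwise_differences(pooled, dist)
    fit = SuddenExpansionModel(mismatch_observed(pooled, dist), pooled.n).fit(
        nboot=nboot, seed=seed
    )
    dominant = max(pooled.counts.values()) / pooled.n
    return {
        "n_individuals": pooled.n,
        "n_haplotypes": len([h for h, c in pooled.counts.items() if c > 0]),
        "n_variable_sites": variable_sites(aln, subset=set(pooled.haplotypes())).S,
        "dominant_frequency": dominant,
        "pooled_fs": fus_fs_value(pooled.n, len(pooled.haplotypes()), kbar),
        "mismatch_ssd": fit.ssd,
        "mismatch_p_ssd": fit.p_ssd,
        "raggedness": fit.raggedness,
        "p_raggedness": fit.p_raggedness,
    }
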