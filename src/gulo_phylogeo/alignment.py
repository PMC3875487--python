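"""Aligned mtDNA haplotype handling.

All statistics downstream consume a :class:`HaplotypeAlignment`: a set of
uniquely named, equal-length sequences over ``{A,C,G,T,-,N}`` on a fixed
alignment frame (318 positions for the control-region fragment this package
was built around).  Positions are 1-based and ranges inclusive throughout.

``N`` is treated as a wildcard: two sequences are considered identical when
they agree at every mutually non-N position (degraded historic material
routinely yields partial reads).  Gaps (``-``) are excluded from
variable-site and distance computations by default; ``gap_mode="fifth_state"``
counts them as an ordinary fifth character.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "HaplotypeAlignment",
    "VariableSiteTable",
    "HaplotypeCatalogue",
    "AlignmentError",
    "read_alignment",
    "write_alignment",
    "truncate_frame",
    "collapse_haplotypes",
    "variable_sites",
    "merge_catalogue",
]

_VALID = set("ACGT-N")


class AlignmentError(ValueError):
    """Raised for malformed or mutually inconsistent alignment input."""


@dataclass(frozen=True)
class HaplotypeAlignment:
    """Named aligned haplotype sequences over a fixed frame of length L."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if not self.ids:
            raise AlignmentError("alignment must contain at least one sequence")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("haplotype ids must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
        bad = set("".join(self.sequences)) - _VALID
        if bad:
            raise AlignmentError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def L(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, hap_id: str) -> bool:
        return hap_id in self.ids

    def sequence(self, hap_id: str) -> str:
        return self.sequences[self.ids.index(hap_id)]

    def as_array(self) -> np.ndarray:
        """(n_haplotypes, L) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def subset(self, keep: set[str] | list[str]) -> "HaplotypeAlignment":
        keep = set(keep)
        missing = keep - set(self.ids)
        if missing:
            raise KeyError(f"unknown haplotype ids: {sorted(missing)}")
        pairs = [(i, s) for i, s in zip(self.ids, self.sequences) if i in keep]
        return HaplotypeAlignment(tuple(i for i, _ in pairs), tuple(s for _, s in pairs))


@dataclass(frozen=True)
class VariableSiteTable:
    """1-based segregating positions and their observed character states."""

    positions: tuple[int, ...]
    states: tuple[tuple[str, ...], ...]

    @property
    def S(self) -> int:
        return len(self.positions)


def _clean(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(path: str | Path) -> HaplotypeAlignment:
    """Read an aligned FASTA into a :class:`HaplotypeAlignment`.

    Characters are uppercased and U mapped to T.  Records of unequal length
    raise :class:`AlignmentError`; an empty file raises ``ValueError``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(_clean(str(r.seq)) for r in records)
    return HaplotypeAlignment(ids, seqs)


def write_alignment(aln: HaplotypeAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for hap_id, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{hap_id}\n{seq}\n")


def truncate_frame(aln: HaplotypeAlignment, start: int, end: int) -> HaplotypeAlignment:
    """Restrict the alignment to the 1-based inclusive window [start, end]."""
    if not (1 <= start <= end <= aln.L):
        raise IndexError(f"window [{start}, {end}] out of range for L={aln.L}")
    return HaplotypeAlignment(aln.ids, tuple(s[start - 1 : end] for s in aln.sequences))


def _same_sequence(a: str, b: str) -> bool:
    """N-tolerant identity: equal at every mutually non-N position."""
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


def collapse_haplotypes(
    sequences: list[tuple[str, str]],
    prefix: str = "Hap",
) -> tuple[HaplotypeAlignment, dict[str, str]]:
    """Collapse identical sequences into canonical haplotypes.

    Canonical ids are assigned in first-seen order (``Hap1``, ``Hap2``, ...).
    Comparison is N-tolerant; when a wildcard sequence matches an existing
    haplotype the more informative (fewer-N) sequence is kept as the
    representative.  Returns the collapsed alignment and the mapping from
    input id to canonical haplotype id.
    """
    if not sequences:
        raise ValueError("no input sequences")
    lengths = {len(s) for _, s in sequences}
    if len(lengths) != 1:
        raise AlignmentError(f"sequences have unequal lengths: {sorted(lengths)}")
    reps: list[str] = []
    names: list[str] = []
    mapping: dict[str, str] = {}
    for seq_id, raw in sequences:
        seq = _clean(raw)
        for j, rep in enumerate(reps):
            if _same_sequence(seq, rep):
                mapping[seq_id] = names[j]
                if seq.count("N") < rep.count("N"):
                    reps[j] = seq
                break
        else:
            names.append(f"{prefix}{len(names) + 1}")
            reps.append(seq)
            mapping[seq_id] = names[-1]
    return HaplotypeAlignment(tuple(names), tuple(reps)), mapping


def variable_sites(
    aln: HaplotypeAlignment,
    subset: set[str] | None = None,
    gap_mode: str = "exclude",
) -> VariableSiteTable:
    """Positions with at least two distinct non-N states among the subset.

    Under the default ``gap_mode="exclude"`` a gap is not a state: a site
    segregating only through an indel is not counted.  ``"fifth_state"``
    treats ``-`` as an ordinary character.
    """
    sub = aln if subset is None else aln.subset(subset)
    if len(sub) == 0:
        raise ValueError("empty haplotype subset")
    arr = sub.as_array()
    ignore = {"N"} if gap_mode == "fifth_state" else {"N", "-"}
    positions, states = [], []
    for col in range(arr.shape[1]):
        obs = sorted(set(arr[:, col]) - ignore)
        if len(obs) >= 2:
            positions.append(col + 1)
            states.append(tuple(obs))
    return VariableSiteTable(tuple(positions), tuple(states))


@dataclass
class HaplotypeCatalogue:
    """Cross-study haplotype synonym catalogue.

    Maps each canonical haplotype id to the set of ``(study, label)`` pairs
    that name the same sequence, with every merge recorded.  Naming of
    control-region haplotypes has historically been inconsistent across
    publications, so the catalogue is the single source of truth for
    identity across datasets.
    """

    alignment: HaplotypeAlignment
    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    merge_log: list[tuple[str, str, str]] = field(default_factory=list)

    @classmethod
    def from_alignment(cls, aln: HaplotypeAlignment, study: str = "this_study") -> "HaplotypeCatalogue":
        cat = cls(alignment=aln)
        for hap_id in aln.ids:
            cat.entries[hap_id] = {(study, hap_id)}
        return cat

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("canonical_id\tstudy\tsource_label\n")
            for canon in self.alignment.ids:
                for study, label in sorted(self.entries.get(canon, ())):
                    fh.write(f"{canon}\t{study}\t{label}\n")


def merge_catalogue(
    cat: HaplotypeCatalogue,
    external: list[tuple[str, str, str]],
) -> HaplotypeCatalogue:
    """Attach external ``(study, label, sequence)`` records to the catalogue.

    Labels whose sequence matches a canonical haplotype (N-tolerant, on the
    harmonized frame) become synonyms; novel sequences are appended as new
    canonical entries.  Re-merging an identical record is a no-op.  A label
    matching two distinct canonical haplotypes raises ``ValueError``.
    """
    aln = cat.alignment
    ids = list(aln.ids)
    seqs = list(aln.sequences)
    entries = {k: set(v) for k, v in cat.entries.items()}
    log = list(cat.merge_log)
    for study, label, raw in external:
        seq = _clean(raw)
        if len(seq) != aln.L:
            raise AlignmentError(
                f"external sequence {study}:{label} has length {len(seq)}, frame is {aln.L}"
            )
        hits = [ids[j] for j, rep in enumerate(seqs) if _same_sequence(seq, rep)]
        if len(hits) > 1:
            raise ValueError(
                f"label {study}:{label} matches multiple canonical haplotypes: {hits}"
            )
        if hits:
            canon = hits[0]
            if (study, label) not in entries[canon]:
                entries[canon].add((study, label))
                log.append((canon, f"{study}:{label}", "sequence identical on frame"))
        else:
            canon = f"Hap{len(ids) + 1}"
            ids.append(canon)
            seqs.append(seq)
            entries[canon] = {(study, label)}
            log.append((canon, f"{study}:{label}", "novel sequence"))
    merged = HaplotypeCatalogue(
        alignment=HaplotypeAlignment(tuple(ids), tuple(seqs)),
        entries=entries,
        merge_log=log,
    )
    return merged
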