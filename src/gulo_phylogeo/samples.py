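"""Sample metadata: individuals, regions, eras, and per-region haplotype counts."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SampleRecord",
    "RegionalSample",
    "read_sample_table",
    "tabulate_regions",
    "pooled_sample",
    "write_count_matrix",
]

CONTEMPORARY = "contemporary"
HISTORIC = "historic"


@dataclass(frozen=True)
class SampleRecord:
    """One sampled individual: region code, era, resolved haplotype, optional coordinates."""

    individual_id: str
    region: str
    era: str
    haplotype_id: str
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self):
        if not self.region:
            raise ValueError(f"empty region for individual {self.individual_id}")
        if self.era not in (CONTEMPORARY, HISTORIC):
            raise ValueError(f"unknown era {self.era!r} for individual {self.individual_id}")


@dataclass(frozen=True)
class RegionalSample:
    """Haplotype counts for one (region, era) sample."""

    region: str
    era: str
    counts: dict[str, int]
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self):
        if not self.counts or any(c < 0 for c in self.counts.values()):
            raise ValueError(f"invalid counts for {self.region}/{self.era}")
        if self.n < 1:
            raise ValueError(f"empty sample {self.region}/{self.era}")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def label(self) -> str:
        return self.region if self.era == CONTEMPORARY else f"{self.region}_H"

    def haplotypes(self) -> list[str]:
        return [h for h, c in self.counts.items() if c > 0]


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read a comma- or tab-delimited sample table.

    Expected header: ``individual_id,region,era,haplotype[,lat,lon]``.
    """
    text = Path(path).read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    records = []
    for row in csv.DictReader(text.splitlines(), delimiter=delim):
        lat = row.get("lat") or row.get("latitude")
        lon = row.get("lon") or row.get("longitude")
        records.append(
            SampleRecord(
                individual_id=row["individual_id"],
                region=row["region"],
                era=row["era"],
                haplotype_id=row["haplotype"],
                latitude=float(lat) if lat else None,
                longitude=float(lon) if lon else None,
            )
        )
    return records


def tabulate_regions(
    samples: list[SampleRecord],
    known_haplotypes: set[str] | None = None,
    include_pooled: bool = True,
) -> list[RegionalSample]:
    """Aggregate individuals into per-(region, era) samples, plus a pooled ``ALL`` sample.

    Region/era order follows first appearance in the input.  When
    ``known_haplotypes`` is given, an unresolved haplotype id raises
    ``KeyError`` (statistics need every id present in the alignment).
    """
    if not samples:
        return []
    groups: dict[tuple[str, str], list[SampleRecord]] = {}
    for rec in samples:
        if known_haplotypes is not None and rec.haplotype_id not in known_haplotypes:
            raise KeyError(f"haplotype {rec.haplotype_id!r} not in the alignment")
        groups.setdefault((rec.region, rec.era), []).append(rec)
    out = []
    for (region, era), recs in groups.items():
        counts: dict[str, int] = {}
        for r in recs:
            counts[r.haplotype_id] = counts.get(r.haplotype_id, 0) + 1
        lats = [r.latitude for r in recs if r.latitude is not None]
        lons = [r.longitude for r in recs if r.longitude is not None]
        out.append(
            RegionalSample(
                region=region,
                era=era,
                counts=counts,
                latitude=sum(lats) / len(lats) if lats else None,
                longitude=sum(lons) / len(lons) if lons else None,
            )
        )
    if include_pooled:
        out.append(pooled_sample(out, label="ALL"))
    return out


def pooled_sample(samples: list[RegionalSample], label: str = "ALL") -> RegionalSample:
    counts: dict[str, int] = {}
    for s in samples:
        if s.region == label:
            continue
        for h, c in s.counts.items():
            counts[h] = counts.get(h, 0) + c
    return RegionalSample(region=label, era=CONTEMPORARY, counts=counts)


def write_count_matrix(samples: list[RegionalSample], path: str | Path) -> None:
    """Regions x haplotypes count matrix as CSV."""
    haps = sorted({h for s in samples for h in s.counts})
    rows = {s.label: {h: s.counts.get(h, 0) for h in haps} for s in samples}
    pd.DataFrame.from_dict(rows, orient="index")[haps].to_csv(path, index_label="sample")
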