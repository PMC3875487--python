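"""Synthetic datasets: deterministic fixtures and study-shaped simulations.

Two kinds of inputs are generated here.

*Fixtures* are tiny, fully deterministic configurations whose statistics are
forced by closed-form arithmetic — a two-haplotype Scandinavian pair
(62 = 61+1 individuals vs 108 monomorphic), a six-individual sample with a
5+1 haplotype split, a pair of haplotypes eight mutational steps apart, and
a star of singleton haplotypes around a common center.  They exercise every
statistic at values that can be checked by hand.

*Study-shaped data* replays the whole survey design: a scenario-3
(stepping-stone) coalescent simulation with two extra sampled demes for
Scandinavia (from the Eurasian pool) and historic California (from the
northwestern pool), subsampled to the survey's twenty (region, era) sample
sizes totalling 983 individuals on a 318-bp frame.  Haplotype counts and
variable sites are reported, not enforced: the generator emulates the shape
of the data (skewed haplotype frequencies, ~tens of haplotypes), and its
realized values depend on the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import HaplotypeAlignment, collapse_haplotypes
from .samples import CONTEMPORARY, HISTORIC, RegionalSample, SampleRecord
from .scenarios import (
    GENERATION_TIME_YEARS,
    DemographicParameters,
    Scenario,
    default_scenarios,
    simulate_dataset,
)

__all__ = ["StudyShape", "STUDY_SHAPE", "make_fixture", "make_study_like", "FIXTURES"]

L_DEFAULT = 318

# (region, era, n) rows of the survey design; contemporary then historic
STUDY_SHAPE_ROWS = [
    ("SWE", CONTEMPORARY, 62), ("NOR", CONTEMPORARY, 108), ("MNG", CONTEMPORARY, 6),
    ("RUS", CONTEMPORARY, 54), ("AK", CONTEMPORARY, 148), ("YK", CONTEMPORARY, 49),
    ("NT", CONTEMPORARY, 53), ("NU", CONTEMPORARY, 81), ("BC", CONTEMPORARY, 86),
    ("AB", CONTEMPORARY, 26), ("SK", CONTEMPORARY, 16), ("MB", CONTEMPORARY, 31),
    ("ON", CONTEMPORARY, 54), ("MT", CONTEMPORARY, 148), ("WY", CONTEMPORARY, 13),
    ("ID", CONTEMPORARY, 15),
    ("YK", HISTORIC, 5), ("BC", HISTORIC, 7), ("SK", HISTORIC, 1),
    ("QC/NL", HISTORIC, 13), ("CA", HISTORIC, 7),
]


@dataclass(frozen=True)
class StudyShape:
    """Regional sample sizes and sequence frame of the emulated survey."""

    regions: tuple[tuple[str, str, int], ...] = tuple(STUDY_SHAPE_ROWS)
    L: int = L_DEFAULT

    @property
    def total_n(self) -> int:
        return sum(n for _, _, n in self.regions)


STUDY_SHAPE = StudyShape()


def _seq(base: str, edits: dict[int, str]) -> str:
    s = list(base)
    for pos, ch in edits.items():
        s[pos - 1] = ch
    return "".join(s)


def _base_sequence(L: int = L_DEFAULT) -> str:
    rng = np.random.default_rng(20130)  # fixed: fixtures are literal data
    return "".join(np.random.default_rng(20130).choice(list("ACGT"), size=L))


FIXTURES = ("SWE_NOR", "MNG", "MB_ON_8step", "STAR")


def make_fixture(name: str, star_k: int = 10) -> tuple[HaplotypeAlignment, list[SampleRecord]]:
    """Deterministic fixture datasets with hand-checkable statistics.

    SWE_NOR: 61 copies of HapX + 1 HapY in one region vs 108 HapX in the
    other; HapY differs by two substitutions and one single-base deletion
    (so the substitution-only segregating-site count is 2 while the
    fifth-state distance is 3).  MNG: six individuals, haplotype counts
    {5, 1}, two substitution differences.  MB_ON_8step: two haplotypes eight
    steps apart.  STAR: one central haplotype plus ``star_k`` singleton
    neighbours one step away each.
    """
    base = _base_sequence()
    records: list[SampleRecord] = []

    def add(region, era, hap, count, lat=None, lon=None):
        start = len(records)
        for i in range(count):
            records.append(
                SampleRecord(
                    individual_id=f"{region}_{era[:1]}{start + i:04d}",
                    region=region, era=era, haplotype_id=hap,
                    latitude=lat, longitude=lon,
                )
            )

    if name == "SWE_NOR":
        hap_x = base
        hap_y = _seq(base, {40: "A" if base[39] != "A" else "G",
                            120: "A" if base[119] != "A" else "G",
                            200: "-"})
        aln = HaplotypeAlignment(("HapX", "HapY"), (hap_x, hap_y))
        add("SWE", CONTEMPORARY, "HapX", 61, 62.0, 15.0)
        add("SWE", CONTEMPORARY, "HapY", 1, 62.0, 15.0)
        add("NOR", CONTEMPORARY, "HapX", 108, 65.0, 13.0)
        return aln, records
    if name == "MNG":
        hap_a = base
        hap_b = _seq(base, {10: "A" if base[9] != "A" else "G",
                            250: "C" if base[249] != "C" else "T"})
        aln = HaplotypeAlignment(("HapA", "HapB"), (hap_a, hap_b))
        add("MNG", CONTEMPORARY, "HapA", 5, 47.0, 103.0)
        add("MNG", CONTEMPORARY, "HapB", 1, 47.0, 103.0)
        return aln, records
    if name == "MB_ON_8step":
        positions = [20, 50, 80, 110, 140, 170, 230, 260]
        hap24 = base
        hap25 = _seq(base, {p: ("A" if base[p - 1] != "A" else "G") for p in positions})
        aln = HaplotypeAlignment(("Hap24", "Hap25"), (hap24, hap25))
        add("MB", CONTEMPORARY, "Hap24", 25, 55.0, -98.0)
        add("MB", CONTEMPORARY, "Hap25", 6, 55.0, -98.0)
        add("ON", CONTEMPORARY, "Hap24", 19, 50.0, -85.0)
        add("ON", CONTEMPORARY, "Hap25", 35, 50.0, -85.0)
        return aln, records
    if name == "STAR":
        ids = ["Hap1"]
        seqs = [base]
        free = [p for p in range(1, L_DEFAULT + 1)]
        for k in range(star_k):
            pos = free[3 * k + 5]
            ids.append(f"Hap{k + 2}")
            seqs.append(_seq(base, {pos: "A" if base[pos - 1] != "A" else "G"}))
        aln = HaplotypeAlignment(tuple(ids), tuple(seqs))
        add("AK", CONTEMPORARY, "Hap1", 2 * star_k, 64.0, -150.0)
        for k in range(star_k):
            add("AK", CONTEMPORARY, f"Hap{k + 2}", 1, 64.0, -150.0)
        return aln, records
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")


# region -> (simulated deme, approximate centroid)
_REGION_DEME = {
    "SWE": ("SCAN", (62.0, 15.0)), "NOR": ("SCAN", (65.0, 13.0)),
    "MNG": ("Pop5", (47.0, 103.0)), "RUS": ("Pop5", (62.0, 130.0)),
    "AK": ("Pop1", (64.0, -150.0)), "YK": ("Pop1", (63.0, -136.0)),
    "NT": ("Pop2", (64.0, -119.0)), "NU": ("Pop2", (66.0, -95.0)),
    "BC": ("Pop1", (55.0, -125.0)), "AB": ("Pop1", (55.0, -115.0)),
    "SK": ("Pop2", (56.0, -106.0)), "MB": ("Pop3", (55.0, -98.0)),
    "ON": ("Pop3", (50.0, -85.0)), "MT": ("Pop1", (47.0, -110.0)),
    "WY": ("Pop1", (43.5, -110.0)), "ID": ("Pop1", (45.0, -115.0)),
    "QC/NL": ("Pop4", (53.0, -64.0)), "CA": ("CA", (39.0, -121.0)),
}


def default_study_parameters() -> DemographicParameters:
    """Fixed demographic parameters for the study-shaped generator.

    One point inside the default prior support (moderate Ne, fast
    control-region clock), chosen to yield a few tens of haplotypes and a
    skewed frequency spectrum on 318 bp.
    """
    ne = {p: 800.0 for p in ("Pop1", "Pop2", "Pop3", "Pop4", "Pop5")}
    ne["ancestral"] = 500.0
    return DemographicParameters(
        ne=ne, t_lgm=5500.0, t_lgm2=5800.0, t_holocene=(2700.0, 1750.0, 800.0),
        mu=3.5e-6, kappa=10.0,
    )


def make_study_like(
    shape: StudyShape = STUDY_SHAPE,
    seed: int = 1,
    params: DemographicParameters | None = None,
) -> tuple[HaplotypeAlignment, list[SampleRecord], dict]:
    """Simulate a full study-shaped dataset under the stepping-stone scenario.

    Returns the collapsed haplotype alignment, one record per individual
    (983 at the default shape), and a report dict with the achieved
    haplotype count, variable-site count and dominant haplotype frequency.
    """
    params = params or default_study_parameters()
    scen3 = default_scenarios()[2]
    # extend the five-population history with the two extra sampled demes
    scen = Scenario(
        id=scen3.id,
        name=scen3.name + " + Scandinavia and historic California demes",
        merges=(
            ("t_hol3", "Pop4", "Pop3"),
            ("t_hol2", "Pop3", "Pop2"),
            ("t_hol2b", "CA", "Pop1"),
            ("t_hol1", "Pop2", "Pop1"),
            ("t_hol1b", "SCAN", "Pop5"),
            ("t_lgm", "Pop5", "Pop1"),
        ),
    )

    # deme sample sizes implied by the shape
    deme_sizes: dict[str, int] = {}
    for region, era, n in shape.regions:
        deme = _REGION_DEME[region][0]
        deme_sizes[deme] = deme_sizes.get(deme, 0) + n

    import msprime

    dem = msprime.Demography()
    for name_, size in (
        ("Pop1", params.ne["Pop1"]), ("Pop2", params.ne["Pop2"]),
        ("Pop3", params.ne["Pop3"]), ("Pop4", params.ne["Pop4"]),
        ("Pop5", params.ne["Pop5"]), ("SCAN", 400.0), ("CA", 300.0),
    ):
        dem.add_population(name=name_, initial_size=size / 2.0)
    t = {
        "t_hol3": params.t_holocene[2], "t_hol2": params.t_holocene[1],
        "t_hol2b": params.t_holocene[1] + 50.0, "t_hol1": params.t_holocene[0],
        "t_hol1b": params.t_holocene[0] + 50.0, "t_lgm": params.t_lgm,
    }
    for key, src, dst in scen.merges:
        dem.add_mass_migration(time=t[key], source=src, dest=dst, proportion=1.0)
    dem.add_population_parameters_change(
        time=params.t_lgm, population="Pop1", initial_size=params.ne["ancestral"] / 2.0
    )
    dem.sort_events()

    order = ["Pop1", "Pop2", "Pop3", "Pop4", "Pop5", "SCAN", "CA"]
    ts = msprime.sim_ancestry(
        samples={p: deme_sizes.get(p, 0) for p in order if deme_sizes.get(p, 0)},
        demography=dem, ploidy=1, sequence_length=shape.L,
        random_seed=max(1, seed % (2**31 - 1)),
    )
    from .scenarios import _hky_model

    mts = msprime.sim_mutations(
        ts, rate=params.mu, model=_hky_model(params.kappa),
        random_seed=max(1, (seed + 1) % (2**31 - 1)),
    )
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=shape.L)
    seqs = np.tile(base, (mts.num_samples, 1))
    for var in mts.variants():
        pos = int(var.site.position)
        alleles = np.array([a if a else "N" for a in var.alleles], dtype="U1")
        seqs[:, pos] = alleles[var.genotypes]
    sequences = ["".join(row) for row in seqs]

    # hand out simulated individuals to regions deme by deme
    cursor = {p: 0 for p in order}
    offset = {}
    pos0 = 0
    for p in order:
        offset[p] = pos0
        pos0 += deme_sizes.get(p, 0)
    records: list[SampleRecord] = []
    indiv_seqs: list[tuple[str, str]] = []
    for region, era, n in shape.regions:
        deme, (lat, lon) = _REGION_DEME[region]
        for i in range(n):
            idx = offset[deme] + cursor[deme]
            cursor[deme] += 1
            ind = f"{region.replace('/', '')}_{era[:1]}{i:04d}"
            indiv_seqs.append((ind, sequences[idx]))
            records.append(
                SampleRecord(
                    individual_id=ind, region=region, era=era,
                    haplotype_id="", latitude=lat, longitude=lon,
                )
            )
    aln, mapping = collapse_haplotypes(indiv_seqs)
    records = [
        SampleRecord(
            individual_id=r.individual_id, region=r.region, era=r.era,
            haplotype_id=mapping[r.individual_id],
            latitude=r.latitude, longitude=r.longitude,
        )
        for r in records
    ]
    from .alignment import variable_sites

    counts = {}
    for r in records:
        counts[r.haplotype_id] = counts.get(r.haplotype_id, 0) + 1
    dominant = max(counts.values()) / len(records)
    report = {
        "n_individuals": len(records),
        "n_haplotypes": len(aln),
        "n_variable_sites": variable_sites(aln).S,
        "dominant_frequency": dominant,
    }
    return aln, records, report
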