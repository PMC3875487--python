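"""Coalescent colonization scenarios for the five regional population pools.

Four competing post-glacial colonization histories are modelled for a
Holarctic mtDNA dataset pooled into five populations:

* Pop1 — northwestern North America (AK, YK, BC, AB, MT, WY, ID)
* Pop2 — central Arctic (NU, NT, SK)
* Pop3 — Manitoba/Ontario (MB, ON)
* Pop4 — historic Quebec/Labrador (QC/NL)
* Pop5 — Eurasia east of the sampling gap (RUS, MNG)

Scenario 1: a single ancestral population splits simultaneously into all
five at the last glacial maximum (LGM).  Scenario 2: Beringian incursion
splits Pop5 from the North American ancestor at the LGM; the NA ancestor
splits simultaneously into Pop1–Pop4 during the Holocene.  Scenario 3: a
single incursion founds Pop1 at the LGM, followed by west-to-east
stepping-stone colonization Pop1→Pop2→Pop3→Pop4 at ordered Holocene times.
Scenario 4: two Beringian incursions (Pop1 and Pop2 both split from Pop5 at
LGM times), with Pop2→Pop3→Pop4 stepping-stone afterwards.

There is no migration after divergence.  An optional recent bottleneck
models the 20th-century decline of the MB-ON pool: a 75% reduction of Ne
from 25 generations ago (c. 1900 at 4 years/generation) to the present.
Sequences are simulated as a single non-recombining 318-bp locus under an
HKY mutation model.  The population sizes are parameterized on the census
(equal-sex) scale; the maternally inherited locus is simulated with
effective size Ne/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

__all__ = [
    "ScenarioPriors",
    "DemographicParameters",
    "Scenario",
    "default_scenarios",
    "POPULATIONS",
    "POPULATION_REGIONS",
    "STUDY_SAMPLE_SIZES",
    "GENERATION_TIME_YEARS",
    "draw_valid_parameters",
    "simulate_single_population",
    "simulate_dataset",
    "simulate_variant_matrix",
]

POPULATIONS = ("Pop1", "Pop2", "Pop3", "Pop4", "Pop5")

POPULATION_REGIONS = {
    "Pop1": ["AK", "YK", "YK_H", "BC", "BC_H", "AB", "MT", "WY", "ID"],
    "Pop2": ["NU", "NT", "SK"],
    "Pop3": ["MB", "ON"],
    "Pop4": ["QC/NL_H"],
    "Pop5": ["RUS", "MNG"],
}

# contemporary + historic regional sizes pooled per population
STUDY_SAMPLE_SIZES = {"Pop1": 497, "Pop2": 150, "Pop3": 85, "Pop4": 13, "Pop5": 60}

GENERATION_TIME_YEARS = 4.0
BOTTLENECK_TIME_GENERATIONS = 25.0
BOTTLENECK_REDUCTION = 0.75


@dataclass(frozen=True)
class ScenarioPriors:
    """Prior distributions for the demographic parameters.

    Times are in generations (4 years each): the LGM window spans roughly
    18–26 kya; the three Holocene split times are drawn from ordered,
    disjoint windows (oldest first), so successive colonization steps are
    separated by several hundred generations.  Effective sizes and per-site
    mutation rates are log-uniform; κ is the HKY transition/transversion
    ratio.

    The default ranges are chosen so the four scenarios are statistically
    separable: split-time gaps span several mtDNA coalescent units of the
    default Ne (lineage sorting completes between colonization steps) and
    θ = Ne·μ·L stays in the low range typical of control-region surveys of
    large carnivores (mean pairwise differences of a few substitutions).
    """

    ne_log10: tuple[float, float] = (2.5, 3.2)
    mu_log10: tuple[float, float] = (-5.5, -5.0)
    kappa: tuple[float, float] = (2.0, 20.0)
    t_lgm: tuple[float, float] = (4500.0, 6500.0)
    t_holocene_windows: tuple[tuple[float, float], ...] = (
        (2400.0, 3000.0),
        (1450.0, 2050.0),
        (500.0, 1100.0),
    )

    def _loguniform(self, rng, lo, hi):
        return 10.0 ** rng.uniform(lo, hi)

    def draw(self, rng: np.random.Generator) -> "DemographicParameters":
        ne = {p: self._loguniform(rng, *self.ne_log10) for p in POPULATIONS}
        ne["ancestral"] = self._loguniform(rng, *self.ne_log10)
        hol = tuple(float(rng.uniform(*w)) for w in self.t_holocene_windows)
        return DemographicParameters(
            ne=ne,
            t_lgm=float(rng.uniform(*self.t_lgm)),
            t_lgm2=float(rng.uniform(*self.t_lgm)),
            t_holocene=hol,
            mu=self._loguniform(rng, *self.mu_log10),
            kappa=float(rng.uniform(*self.kappa)),
        )


@dataclass(frozen=True)
class DemographicParameters:
    ne: dict[str, float]  # census-scale effective sizes per population
    t_lgm: float
    t_lgm2: float  # second incursion time (scenario 4 only)
    t_holocene: tuple[float, float, float]  # descending order
    mu: float  # per site per generation
    kappa: float
    generation_time: float = GENERATION_TIME_YEARS

    def as_row(self) -> dict[str, float]:
        row = {f"ne_{p}": self.ne[p] for p in POPULATIONS}
        row["ne_ancestral"] = self.ne["ancestral"]
        row.update(
            t_lgm=self.t_lgm,
            t_lgm2=self.t_lgm2,
            t_hol1=self.t_holocene[0],
            t_hol2=self.t_holocene[1],
            t_hol3=self.t_holocene[2],
            mu=self.mu,
            kappa=self.kappa,
        )
        return row


@dataclass(frozen=True)
class Scenario:
    """A declarative divergence history: backward-in-time lineage merges."""

    id: int
    name: str
    # (time-key, derived population, receiving population); time-key is one of
    # "t_lgm", "t_lgm2", "t_hol1".."t_hol3"
    merges: tuple[tuple[str, str, str], ...]

    def events(self, params: DemographicParameters) -> list[tuple[float, str, str]]:
        tmap = {
            "t_lgm": params.t_lgm,
            "t_lgm2": params.t_lgm2,
            "t_hol1": params.t_holocene[0],
            "t_hol2": params.t_holocene[1],
            "t_hol3": params.t_holocene[2],
        }
        ev = [(tmap[k], src, dst) for k, src, dst in self.merges]
        times = [t for t, _, _ in ev]
        if sorted(times) != times:
            raise ValueError(
                f"scenario {self.id}: merge times must be ordered looking backward"
            )
        merged = set()
        for _, src, dst in ev:
            if src in merged:
                raise ValueError(f"scenario {self.id}: {src} merges twice")
            if dst in merged:
                raise ValueError(f"scenario {self.id}: {dst} already merged away")
            merged.add(src)
        if len(merged) != len(POPULATIONS) - 1:
            raise ValueError(f"scenario {self.id}: populations do not fully coalesce")
        return ev

    def demography(
        self, params: DemographicParameters, bottleneck: bool = True
    ) -> msprime.Demography:
        dem = msprime.Demography()
        for p in POPULATIONS:
            size = params.ne[p] / 2.0  # maternal lineage size
            if bottleneck and p == "Pop3":
                size *= 1.0 - BOTTLENECK_REDUCTION
            dem.add_population(name=p, initial_size=size)
        if bottleneck:
            dem.add_population_parameters_change(
                time=BOTTLENECK_TIME_GENERATIONS,
                population="Pop3",
                initial_size=params.ne["Pop3"] / 2.0,
            )
        events = self.events(params)
        for t, src, dst in events:
            dem.add_mass_migration(time=t, source=src, dest=dst, proportion=1.0)
        # the last receiving population becomes the ancestral lineage
        root = events[-1][2]
        dem.add_population_parameters_change(
            time=events[-1][0], population=root, initial_size=params.ne["ancestral"] / 2.0
        )
        dem.sort_events()
        return dem


def default_scenarios() -> list[Scenario]:
    s1 = Scenario(
        1,
        "simultaneous Holarctic radiation at the LGM",
        (
            ("t_lgm", "Pop2", "Pop1"),
            ("t_lgm", "Pop3", "Pop1"),
            ("t_lgm", "Pop4", "Pop1"),
            ("t_lgm", "Pop5", "Pop1"),
        ),
    )
    s2 = Scenario(
        2,
        "single incursion, simultaneous Holocene radiation in North America",
        (
            ("t_hol1", "Pop2", "Pop1"),
            ("t_hol1", "Pop3", "Pop1"),
            ("t_hol1", "Pop4", "Pop1"),
            ("t_lgm", "Pop5", "Pop1"),
        ),
    )
    s3 = Scenario(
        3,
        "single incursion, west-to-east stepping-stone",
        (
            ("t_hol3", "Pop4", "Pop3"),
            ("t_hol2", "Pop3", "Pop2"),
            ("t_hol1", "Pop2", "Pop1"),
            ("t_lgm", "Pop5", "Pop1"),
        ),
    )
    s4 = Scenario(
        4,
        "two incursions, eastern stepping-stone from the second",
        (
            ("t_hol3", "Pop4", "Pop3"),
            ("t_hol2", "Pop3", "Pop2"),
            ("t_lgm", "Pop1", "Pop5"),
            ("t_lgm2", "Pop2", "Pop5"),
        ),
    )
    return [s1, s2, s3, s4]


def _events_ok(scenario: Scenario, params: DemographicParameters) -> bool:
    try:
        scenario.events(params)
        return True
    except ValueError:
        return False


def draw_valid_parameters(
    scenario: Scenario, priors: ScenarioPriors, rng: np.random.Generator, max_tries: int = 1000
) -> DemographicParameters:
    """Draw from the priors, rejecting draws violating the scenario's event order."""
    for _ in range(max_tries):
        params = priors.draw(rng)
        if _events_ok(scenario, params):
            return params
    raise RuntimeError(f"could not draw valid parameters for scenario {scenario.id}")


def simulate_single_population(
    n: int, ne: float, mu: float, L: int = 318, seed: int = 1, kappa: float = 8.0
) -> np.ndarray:
    """Constant-size single-population control simulation.

    ``ne`` is the haploid effective number of lineages, so a sampled pair
    coalesces ``ne`` generations ago in expectation and carries
    E[pairwise differences] = 2·ne·mu·L.  Returns the genotype matrix
    (individuals x variant sites); used for simulator calibration.
    """
    ts = msprime.sim_ancestry(
        samples=n, population_size=ne, ploidy=1, sequence_length=L,
        random_seed=max(1, seed % (2**31 - 1)),
    )
    mts = msprime.sim_mutations(
        ts, rate=mu, model=_hky_model(kappa),
        random_seed=max(1, (seed + 1) % (2**31 - 1)),
    )
    return mts.genotype_matrix().T.astype(np.int16)


def _hky_model(kappa: float) -> msprime.MatrixMutationModel:
    """HKY with equal base frequencies and exactly normalized rows.

    (The stock constructor's rows can drift a few ulp above 1 for some κ,
    which the mutation generator rejects.)
    """
    p = 1.0 / (kappa + 2.0)
    ts_p = 1.0 - 2.0 * p  # transition probability, exact complement
    M = [
        [0.0, p, ts_p, p],  # A -> (C, G, T); A<->G transition
        [p, 0.0, p, ts_p],  # C<->T transition
        [ts_p, p, 0.0, p],
        [p, ts_p, p, 0.0],
    ]
    return msprime.MatrixMutationModel(
        alleles=["A", "C", "G", "T"],
        root_distribution=[0.25, 0.25, 0.25, 0.25],
        transition_matrix=M,
    )


def _simulate_ts(
    scenario: Scenario,
    params: DemographicParameters,
    sample_sizes: dict[str, int],
    L: int,
    seed: int,
    bottleneck: bool,
):
    dem = scenario.demography(params, bottleneck=bottleneck)
    ts = msprime.sim_ancestry(
        samples={p: n for p, n in sample_sizes.items() if n > 0},
        demography=dem,
        ploidy=1,
        sequence_length=L,
        random_seed=max(1, seed % (2**31 - 1)),
    )
    return msprime.sim_mutations(
        ts,
        rate=params.mu,
        model=_hky_model(params.kappa),
        random_seed=max(1, (seed + 1) % (2**31 - 1)),
    )


def simulate_variant_matrix(
    scenario: Scenario,
    params: DemographicParameters,
    sample_sizes: dict[str, int],
    L: int = 318,
    seed: int = 1,
    bottleneck: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one dataset, returning (genotype matrix, population index).

    The genotype matrix is (n_individuals, n_variant_sites) of small integer
    allele codes; invariant sites carry no information for the summary
    statistics and are omitted.
    """
    mts = _simulate_ts(scenario, params, sample_sizes, L, seed, bottleneck)
    G = mts.genotype_matrix().T  # (individuals, variant sites)
    pops = np.concatenate(
        [
            np.full(sample_sizes.get(p, 0), i, dtype=np.int64)
            for i, p in enumerate(POPULATIONS)
        ]
    )
    return G.astype(np.int16), pops


def simulate_dataset(
    scenario: Scenario,
    params: DemographicParameters,
    sample_sizes: dict[str, int],
    L: int = 318,
    seed: int = 1,
    bottleneck: bool = True,
) -> tuple[list[str], list[str]]:
    """Simulate one dataset as full-length aligned sequences.

    Returns (sequences, population labels), one entry per sampled lineage.
    """
    mts = _simulate_ts(scenario, params, sample_sizes, L, seed, bottleneck)
    n = mts.num_samples
    rng = np.random.default_rng(seed)
    base = rng.choice(list("ACGT"), size=L)
    seqs = np.tile(base, (n, 1))
    for var in mts.variants():
        pos = int(var.site.position)
        alleles = np.array([a if a else "N" for a in var.alleles], dtype="U1")
        seqs[:, pos] = alleles[var.genotypes]
    labels = []
    for p in POPULATIONS:
        labels.extend([p] * sample_sizes.get(p, 0))
    return ["".join(row) for row in seqs], labels
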