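"""Scenario simulation and ABC model-choice machinery."""

import warnings

import numpy as np
import pytest
from scipy import stats

from gulo_phylogeo.abc import (
    AbcModelChoice,
    AbcReferenceTable,
    build_reference_table,
    observed_summaries,
    summaries_from_matrix,
    summary_names,
)
from gulo_phylogeo.scenarios import (
    POPULATIONS,
    Scenario,
    ScenarioPriors,
    default_scenarios,
    draw_valid_parameters,
    simulate_dataset,
    simulate_variant_matrix,
)

SMALL_SIZES = {"Pop1": 12, "Pop2": 8, "Pop3": 8, "Pop4": 5, "Pop5": 6}


@pytest.fixture(scope="module")
def small_table():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_reference_table(
            default_scenarios(), 150, SMALL_SIZES, seed=42
        )


class TestScenarios:
    def test_four_scenarios_validate(self):
        priors = ScenarioPriors()
        rng = np.random.default_rng(0)
        for scen in default_scenarios():
            params = draw_valid_parameters(scen, priors, rng)
            events = scen.events(params)
            assert len(events) == 4
            times = [t for t, _, _ in events]
            assert times == sorted(times)

    def test_bad_event_order_rejected(self):
        bad = Scenario(9, "inverted", (
            ("t_lgm", "Pop5", "Pop1"),
            ("t_hol1", "Pop2", "Pop1"),  # later event at an earlier time
            ("t_hol2", "Pop3", "Pop2"),
            ("t_hol3", "Pop4", "Pop3"),
        ))
        params = ScenarioPriors().draw(np.random.default_rng(1))
        with pytest.raises(ValueError):
            bad.events(params)

    def test_incomplete_coalescence_rejected(self):
        bad = Scenario(9, "partial", (
            ("t_hol1", "Pop2", "Pop1"),
            ("t_lgm", "Pop5", "Pop1"),
            ("t_lgm", "Pop5", "Pop1"),  # duplicate merge, Pop3/Pop4 orphaned
            ("t_lgm", "Pop4", "Pop1"),
        ))
        params = ScenarioPriors().draw(np.random.default_rng(1))
        with pytest.raises(ValueError):
            bad.events(params)

    def test_prior_draws_respect_windows(self):
        priors = ScenarioPriors()
        rng = np.random.default_rng(3)
        draws = [priors.draw(rng) for _ in range(400)]
        t1 = np.array([d.t_holocene[0] for d in draws])
        mus = np.log10([d.mu for d in draws])
        assert t1.min() >= 2400 and t1.max() <= 3000
        # log-uniform marginal: KS against uniform on the log scale
        lo, hi = priors.mu_log10
        p = stats.kstest(mus, stats.uniform(loc=lo, scale=hi - lo).cdf).pvalue
        assert p > 0.01
        # ordered looking forward in colonization sequence
        assert all(d.t_holocene[0] > d.t_holocene[1] > d.t_holocene[2] for d in draws)

    def test_zero_split_time_indistinguishable(self):
        """As divergence time goes to zero, mean phi_ST between demes vanishes."""
        priors = ScenarioPriors()
        rng = np.random.default_rng(5)
        scen = default_scenarios()[0]
        phis = []
        for rep in range(60):
            params = draw_valid_parameters(scen, priors, rng)
            object.__setattr__(params, "t_lgm", 1.0)  # near-zero split
            ne = {k: 500.0 for k in params.ne}
            object.__setattr__(params, "ne", ne)
            G, pops = simulate_variant_matrix(
                scen, params, {"Pop1": 10, "Pop2": 10, "Pop3": 2, "Pop4": 2, "Pop5": 2},
                seed=int(rng.integers(1, 2**31 - 1)), bottleneck=False,
            )
            vec = summaries_from_matrix(G, pops, 5)
            phis.append(vec[len(POPULATIONS) * 4])  # phi(Pop1, Pop2)
        assert abs(np.mean(phis)) < 0.05

    def test_deep_split_orders_divergence(self):
        """phi(Pop5, Pop1) under the stepping-stone history exceeds phi(Pop1, Pop2)."""
        priors = ScenarioPriors()
        rng = np.random.default_rng(6)
        scen3 = default_scenarios()[2]
        d51, d12 = [], []
        names = summary_names()
        i51 = names.index("phist_Pop1_Pop5")
        i12 = names.index("phist_Pop1_Pop2")
        for rep in range(40):
            params = draw_valid_parameters(scen3, priors, rng)
            G, pops = simulate_variant_matrix(
                scen3, params, SMALL_SIZES, seed=int(rng.integers(1, 2**31 - 1))
            )
            vec = summaries_from_matrix(G, pops, 5)
            d51.append(vec[i51])
            d12.append(vec[i12])
        assert np.mean(d51) > np.mean(d12)

    def test_sequence_output_matches_variant_matrix_path(self):
        """Full sequences fed through the observed-statistics path reproduce
        the simulator's own summary vector (shared code path)."""
        from gulo_phylogeo.alignment import collapse_haplotypes
        from gulo_phylogeo.distance import pairwise_differences
        from gulo_phylogeo.samples import SampleRecord, tabulate_regions

        scen = default_scenarios()[2]
        params = draw_valid_parameters(scen, ScenarioPriors(), np.random.default_rng(8))
        seqs, labels = simulate_dataset(scen, params, SMALL_SIZES, seed=77)
        G, pops = simulate_variant_matrix(scen, params, SMALL_SIZES, seed=77)
        direct = summaries_from_matrix(G, pops, 5)

        aln, mapping = collapse_haplotypes(
            [(f"i{k}", s) for k, s in enumerate(seqs)]
        )
        records = [
            SampleRecord(f"i{k}", labels[k], "contemporary", mapping[f"i{k}"])
            for k in range(len(seqs))
        ]
        samples = tabulate_regions(records, include_pooled=False)
        dist = pairwise_differences(aln)
        via_observed = observed_summaries(
            samples, aln, dist,
            population_regions={p: [p] for p in POPULATIONS},
        )
        np.testing.assert_allclose(via_observed, direct, atol=1e-9)


class TestReferenceTable:
    def test_row_count_and_layout(self, small_table):
        assert small_table.n_rows == 4 * 150 - small_table.n_failed
        assert small_table.stats.shape[1] == len(summary_names())
        assert set(small_table.scenario_ids) == {1, 2, 3, 4}

    def test_deterministic_under_seed(self):
        kw = dict(n_sim=20, sample_sizes=SMALL_SIZES, seed=9)
        a = build_reference_table(default_scenarios()[:2], **kw)
        b = build_reference_table(default_scenarios()[:2], **kw)
        np.testing.assert_array_equal(a.stats, b.stats)
        assert a.parameters.equals(b.parameters)

    def test_csv_export(self, small_table, tmp_path):
        p = tmp_path / "table.csv"
        small_table.to_csv(p)
        header = p.read_text().splitlines()[0].split(",")
        assert header[0] == "scenario"
        assert set(summary_names()) <= set(header)


class TestModelChoice:
    def test_self_consistency(self, small_table):
        """An observed vector copied from a table row favors its own scenario."""
        hits = 0
        rng = np.random.default_rng(1)
        rows = rng.choice(small_table.n_rows, size=12, replace=False)
        for r in rows:
            res = AbcModelChoice(small_table, small_table.stats[r]).fit(
                accept_fraction=0.02
            )
            hits += res.selected == small_table.scenario_ids[r]
        assert hits >= 7

    def test_accept_everything_returns_prior_proportions(self, small_table):
        obs = np.median(small_table.stats, axis=0)
        res = AbcModelChoice(small_table, obs).fit(accept_fraction=1.0, lda=False)
        for s in (1, 2, 3, 4):
            assert res.rejection_proportions[s] == pytest.approx(0.25, abs=0.02)

    def test_posteriors_sum_to_one(self, small_table):
        res = AbcModelChoice(small_table, small_table.stats[3]).fit(accept_fraction=0.05)
        assert sum(res.posterior_probabilities.values()) == pytest.approx(1.0, abs=1e-6)

    def test_duplication_invariance(self, small_table):
        doubled = AbcReferenceTable(
            scenario_ids=np.concatenate([small_table.scenario_ids] * 2),
            parameters=__import__("pandas").concat(
                [small_table.parameters] * 2, ignore_index=True
            ),
            stats=np.vstack([small_table.stats] * 2),
            stat_names=small_table.stat_names,
            seed=small_table.seed,
        )
        obs = small_table.stats[10]
        r1 = AbcModelChoice(small_table, obs).fit(accept_fraction=0.1)
        r2 = AbcModelChoice(doubled, obs).fit(accept_fraction=0.1)
        for s in (1, 2, 3, 4):
            assert r1.posterior_probabilities[s] == pytest.approx(
                r2.posterior_probabilities[s], abs=0.02
            )

    def test_layout_mismatch_rejected(self, small_table):
        with pytest.raises(ValueError):
            AbcModelChoice(small_table, np.zeros(3))

    def test_identical_scenarios_near_uniform(self):
        """Duplicated histories cannot be told apart: posteriors ~ 1/4."""
        scen = default_scenarios()[0]
        clones = [
            Scenario(i, f"clone{i}", scen.merges) for i in (1, 2, 3, 4)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = build_reference_table(clones, 150, SMALL_SIZES, seed=21)
            params = draw_valid_parameters(clones[0], ScenarioPriors(), np.random.default_rng(2))
            G, pops = simulate_variant_matrix(clones[0], params, SMALL_SIZES, seed=33)
            obs = summaries_from_matrix(G, pops, 5)
            res = AbcModelChoice(table, obs).fit(accept_fraction=0.2)
        for s in (1, 2, 3, 4):
            assert res.posterior_probabilities[s] == pytest.approx(0.25, abs=0.2)


class TestObservedSummaries:
    def test_region_pooling_counts(self):
        """MB + ON regional samples pool into the third scenario population."""
        from gulo_phylogeo.synthetic import make_study_like
        from gulo_phylogeo.alignment import collapse_haplotypes
        from gulo_phylogeo.distance import pairwise_differences
        from gulo_phylogeo.samples import tabulate_regions

        aln, records, _ = make_study_like(seed=1)
        samples = tabulate_regions(records, include_pooled=False)
        mb_on = sum(s.n for s in samples if s.label in ("MB", "ON"))
        assert mb_on == 85
        dist = pairwise_differences(aln)
        vec = observed_summaries(samples, aln, dist)
        assert vec.shape == (len(summary_names()),)
        assert np.isfinite(vec).all()

    def test_unmapped_population_errors(self, mng):
        aln, sample, dist = mng
        with pytest.raises(ValueError):
            observed_summaries([sample], aln, dist)
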