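"""Selection, filtering, survivor logic and whole-run behaviour."""

import numpy as np
import pandas as pd
import pytest

import mlmga as M
from mlmga.ga_engine import (
    GenerationStats,
    filter_offspring,
    select_parents,
    select_survivors,
)
from mlmga.scoring import Individual, MetricVector


def _ind(smiles: str, fitness: float) -> Individual:
    return Individual(smiles, MetricVector(qed=fitness, sa_norm=fitness), fitness)


class TestSelectParents:
    def test_population_of_one_forces_copies(self):
        pop = [_ind("C", 0.5)]
        parents = select_parents(pop, 7, np.random.default_rng(0))
        assert parents == pop * 7

    def test_returns_mu_parents(self):
        pop = [_ind("C", 0.5), _ind("N", 0.6), _ind("O", 0.7)]
        assert len(select_parents(pop, 11, np.random.default_rng(0))) == 11

    def test_uniform_with_replacement(self):
        pop = [_ind("C", 0.1), _ind("N", 0.9)]  # fitness must not bias draws
        mu = 10_000
        parents = select_parents(pop, mu, np.random.default_rng(3))
        n_c = sum(1 for p in parents if p.canonical_smiles == "C")
        sigma = np.sqrt(mu * 0.25)
        assert abs(n_c - mu / 2) < 3 * sigma

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            select_parents([], 5, np.random.default_rng(0))


class TestFilterOffspring:
    def test_member_of_current_population_is_dropped(self):
        survivors, counts = filter_offspring(["CCO"], current={"CCO"}, initial=set())
        assert survivors == [] and counts["n_unique"] == 0 and counts["n_valid"] == 1

    def test_invalid_strings_are_counted_not_raised(self):
        survivors, counts = filter_offspring(
            ["C((", "CCO"], current=set(), initial=set()
        )
        assert counts["n_proposed"] == 2 and counts["n_valid"] == 1
        assert survivors == ["CCO"]

    def test_two_spellings_collapse_to_one(self):
        survivors, counts = filter_offspring(
            ["OCC", "CCO"], current=set(), initial=set()
        )
        assert len(survivors) == 1 and counts["n_valid"] == 2

    def test_novelty_counted_against_initial(self):
        _, counts = filter_offspring(
            ["CCO", "CCN"], current=set(), initial={"CCO"}
        )
        assert counts["n_novel"] == 1

    def test_counter_ordering_holds(self):
        _, counts = filter_offspring(
            ["CCO", "CCO", "C((", "CCN"], current={"CCN"}, initial=set()
        )
        assert (
            counts["n_unique"] <= counts["n_valid"] <= counts["n_proposed"]
        )


class TestSelectSurvivors:
    def test_enumerated_example(self):
        parents = [_ind("A", 0.9), _ind("B", 0.5)]
        offspring = [_ind("C", 0.7)]
        chosen = select_survivors(parents, offspring, mu=2)
        assert {i.canonical_smiles for i in chosen} == {"A", "C"}

    def test_no_offspring_keeps_population(self):
        parents = [_ind("A", 0.9), _ind("B", 0.5)]
        assert select_survivors(parents, [], mu=2) == parents

    def test_elitism_never_lowers_max_fitness(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            parents = [_ind(f"P{i}", rng.random()) for i in range(5)]
            offspring = [_ind(f"O{i}", rng.random()) for i in range(8)]
            best_before = max(i.fitness for i in parents)
            chosen = select_survivors(parents, offspring, mu=5)
            assert max(i.fitness for i in chosen) >= best_before

    def test_ties_break_lexicographically(self):
        parents = [_ind("B", 0.5), _ind("A", 0.5), _ind("C", 0.5)]
        chosen = select_survivors(parents, [], mu=2)
        assert [i.canonical_smiles for i in chosen] == ["A", "B"]


class TestGenerationStats:
    def test_counter_ordering_enforced(self):
        with pytest.raises(ValueError):
            GenerationStats(1, 0.5, 0.6, n_proposed=5, n_valid=6, n_novel=0,
                            n_unique=2, n_accepted=1)

    def test_max_must_dominate_mean(self):
        with pytest.raises(ValueError):
            GenerationStats(1, 0.7, 0.6, 5, 4, 3, 2, 1)


@pytest.fixture(scope="module")
def population():
    return M.make_gdb9_like(80, seed=21)


class TestRun:
    def test_single_generation_yields_one_stats_row(self, ngram_model, population):
        sched = M.RunSchedule(mu=20, generations=1, n_repeats=2, seed=5)
        result = M.run(sched, ngram_model, population)
        assert all(len(s) == 1 for s in result.stats)

    def test_fixed_strategy_never_adapts(self, ngram_model, population):
        sched = M.RunSchedule(mu=20, generations=3, n_repeats=1, seed=5)
        result = M.run(sched, ngram_model, population)
        assert all(s.adapt_report is None for s in result.stats[0])

    def test_switch_adapts_only_after_threshold(self, ngram_model, population):
        sched = M.RunSchedule(
            mu=20, generations=4, n_repeats=1, seed=5,
            strategy="switch", switch_generation=2,
        )
        result = M.run(sched, ngram_model, population)
        reports = [s.adapt_report for s in result.stats[0]]
        assert reports[0] is None and reports[1] is None
        assert reports[2] is not None and reports[3] is not None

    def test_ngram_runs_are_bit_reproducible(self, small_vocab, population):
        def fresh():
            model = M.NGramPredictor(small_vocab, seed=0)
            model.pretrain([M.encode(small_vocab, s) for s in population], epochs=1)
            return model

        sched = M.RunSchedule(mu=20, generations=3, n_repeats=2, seed=42)
        a = M.run(sched, fresh(), population)
        b = M.run(sched, fresh(), population)
        assert a.stats_frame().equals(b.stats_frame())

    def test_population_stays_unique_and_counters_consistent(self, ngram_model, population):
        sched = M.RunSchedule(mu=25, generations=4, n_repeats=2, seed=9,
                              strategy="adaptive")
        result = M.run(sched, ngram_model, population)
        for pop in result.final_populations:
            canon = [i.canonical_smiles for i in pop]
            assert len(canon) == len(set(canon))
        df = result.stats_frame()
        assert (df.n_accepted <= df.n_unique).all()
        assert (df.n_unique <= df.n_valid).all()
        assert (df.n_valid <= df.n_proposed).all()

    def test_aggregation_reports_mean_and_sd_per_generation(self, ngram_model, population):
        sched = M.RunSchedule(mu=20, generations=2, n_repeats=3, seed=1)
        agg = M.run(sched, ngram_model, population).aggregated()
        assert list(agg.generation) == [1, 2]
        assert agg.sd_fitness.notna().all()

    def test_run_directory_contents(self, ngram_model, population, tmp_path):
        out = tmp_path / "run"
        sched = M.RunSchedule(mu=20, generations=2, n_repeats=2, seed=1)
        M.run(sched, ngram_model, population, out_dir=out)
        stats = pd.read_csv(out / "stats.csv")
        assert len(stats) == 2 * 2  # generations x repeats
        assert (out / "config.json").exists()
        assert (out / "population.csv").exists()
        assert (out / "aggregated.csv").exists()

    def test_missing_population_file_raises_before_compute(self, ngram_model, tmp_path):
        sched = M.RunSchedule(mu=20, generations=1, n_repeats=1)
        with pytest.raises(FileNotFoundError):
            M.run(sched, ngram_model, tmp_path / "nope.smi")

    def test_affinity_mode_fitness_consistency(self, ngram_model, population):
        sched = M.RunSchedule(
            mu=15, generations=2, n_repeats=1, seed=3,
            metric_set=("qed", "sa", "affinity"),
        )
        result = M.run(
            sched, ngram_model, population, affinity_scorer=M.MockAffinityScorer()
        )
        for ind in result.final_populations[0]:
            assert ind.fitness == pytest.approx(
                M.harmonic_mean(ind.metrics.values()), abs=1e-12
            )
            assert len(ind.metrics.values()) == 3


class TestScheduleValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mu=1),
            dict(generations=0),
            dict(mutation_rate=0.0),
            dict(strategy="switch"),
            dict(strategy="switch", switch_generation=99),
            dict(strategy="annealed"),
        ],
    )
    def test_invalid_schedules_rejected(self, kwargs):
        with pytest.raises(ValueError):
            M.RunSchedule(**kwargs)

    def test_switch_schedule_boundaries(self):
        sched = M.RunSchedule(strategy="switch", switch_generation=3, generations=10)
        assert not sched.is_adaptive(3)
        assert sched.is_adaptive(4)


def test_high_fitness_start_favors_adaptation(broad_setup):
    """From a high-fitness initial set with headroom left, one-epoch-per-
    generation adaptation ends above the frozen model in a majority of
    seeds (the mirror image of the low-fitness start)."""
    model = broad_setup["model"]
    top = M.make_top_like(500, pool_factor=2, seed=12)
    wins = 0
    for seed in (0, 1, 2):
        finals = {}
        for strategy in ("fixed", "adaptive"):
            sched = M.RunSchedule(
                mu=200, generations=8, mutation_rate=0.3, n_repeats=1,
                seed=seed, strategy=strategy,
            )
            result = M.run(sched, model, top)
            finals[strategy] = result.stats[0][-1].mean_fitness
        if finals["adaptive"] >= finals["fixed"]:
            wins += 1
    assert wins >= 2


class TestCompareDistributions:
    def test_identical_sets_have_zero_distance(self):
        pop = [_ind("C", 0.4), _ind("N", 0.6)]
        d = M.compare_distributions(pop, pop)
        assert d["qed"]["dmean"] == 0.0 and d["qed"]["dsd"] == 0.0

    def test_translation_shows_up_in_dmean(self):
        a = [Individual("C", MetricVector(qed=0.4, sa_norm=0.5), 0.44),
             Individual("N", MetricVector(qed=0.6, sa_norm=0.7), 0.65)]
        b = [Individual("C", MetricVector(qed=0.5, sa_norm=0.5), 0.5),
             Individual("N", MetricVector(qed=0.7, sa_norm=0.7), 0.7)]
        d = M.compare_distributions(a, b)
        assert d["qed"]["dmean"] == pytest.approx(0.1)
        assert d["qed"]["dsd"] == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            M.compare_distributions([], [_ind("C", 0.5)])
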