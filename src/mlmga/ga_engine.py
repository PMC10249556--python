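"""(μ + 5μ) genetic algorithm with masked-language-model mutations.

Each generation draws μ parents uniformly with replacement, proposes up
to 5 offspring per parent through masked mutation, filters the proposals
for chemical validity and uniqueness, scores the survivors, and keeps
the best μ of population ∪ offspring (elitist truncation selection).

The training *strategy* decides what happens to the mutation model:

* ``fixed`` — the pre-trained predictor is frozen; inference only.
* ``adaptive`` — before proposing, the predictor is trained for exactly
  one epoch on the current selected population, so proposals track the
  population as it moves through chemical space.
* ``switch`` — fixed for the first ``switch_generation`` generations,
  adaptive afterwards; the schedule found to combine fast early gains
  with late adaptation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .mutation import generate_offspring
from .predictor import MaskedPredictor, TrainReport
from .scoring import Individual, PopulationScorer, AffinityScorerFn
from .tokenizer import encode

__all__ = [
    "RunSchedule",
    "GenerationStats",
    "RunResult",
    "select_parents",
    "filter_offspring",
    "select_survivors",
    "run_generation",
    "run",
    "generate_without_selection",
    "compare_distributions",
]

logger = logging.getLogger(__name__)

Strategy = Literal["fixed", "adaptive", "switch"]


@dataclass(frozen=True)
class RunSchedule:
    """All hyperparameters of a GA run.

    Defaults are desk-scale: μ = 200 for ten generations with the
    standard mutation rate 0.3, five offspring per parent from the top-5
    predictions, two-metric fitness, six repeated runs.  Large-scale
    settings (μ = 10⁵) are configuration values, not code changes.
    """

    mu: int = 200
    offspring_factor: int = 5
    generations: int = 10
    mutation_rate: float = 0.3
    topk: int = 5
    mode: Literal["topk", "sample"] = "topk"
    strategy: Strategy = "fixed"
    switch_generation: int | None = None
    reinit_on_switch: bool = False
    seed: int = 0
    metric_set: tuple[str, ...] = ("qed", "sa")
    n_repeats: int = 6

    def __post_init__(self) -> None:
        if self.mu < 2:
            raise ValueError("mu must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in (0, 1)")
        if self.strategy not in ("fixed", "adaptive", "switch"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "switch":
            g = self.switch_generation
            if g is None or not 0 <= g <= self.generations:
                raise ValueError(
                    "switch strategy requires 0 <= switch_generation <= generations"
                )

    def is_adaptive(self, generation: int) -> bool:
        """Whether the predictor trains this generation (1-based index)."""
        if self.strategy == "fixed":
            return False
        if self.strategy == "adaptive":
            return True
        return generation > (self.switch_generation or 0)


@dataclass(frozen=True)
class GenerationStats:
    """Counters and fitness summary for one generation of one run."""

    generation: int
    mean_fitness: float
    max_fitness: float
    n_proposed: int
    n_valid: int
    n_novel: int
    n_unique: int
    n_accepted: int
    adapt_report: TrainReport | None = None

    def __post_init__(self) -> None:
        if not (
            self.n_accepted <= self.n_unique <= self.n_valid <= self.n_proposed
        ):
            raise ValueError(
                "counter ordering violated: accepted <= unique <= valid <= proposed"
            )
        if self.max_fitness < self.mean_fitness:
            raise ValueError("max_fitness below mean_fitness")


@dataclass
class RunResult:
    """Stats and final populations for a batch of repeated runs."""

    schedule: RunSchedule
    stats: list[list[GenerationStats]]
    final_populations: list[list[Individual]]

    def stats_frame(self) -> pd.DataFrame:
        rows = []
        for run_idx, run_stats in enumerate(self.stats):
            for s in run_stats:
                rows.append(
                    {
                        "run": run_idx,
                        "generation": s.generation,
                        "mean_fitness": s.mean_fitness,
                        "max_fitness": s.max_fitness,
                        "n_proposed": s.n_proposed,
                        "n_valid": s.n_valid,
                        "n_novel": s.n_novel,
                        "n_unique": s.n_unique,
                        "n_accepted": s.n_accepted,
                        "adapted": s.adapt_report is not None,
                    }
                )
        return pd.DataFrame(rows)

    def aggregated(self) -> pd.DataFrame:
        """Mean ± sd of the fitness trajectory over the repeated runs."""
        df = self.stats_frame()
        return (
            df.groupby("generation")
            .agg(
                mean_fitness=("mean_fitness", "mean"),
                sd_fitness=("mean_fitness", "std"),
                max_fitness=("max_fitness", "mean"),
                n_valid=("n_valid", "mean"),
                n_accepted=("n_accepted", "mean"),
            )
            .reset_index()
        )


def select_parents(
    population: Sequence[Individual], mu: int, rng: np.random.Generator
) -> list[Individual]:
    """μ uniform draws with replacement (duplicates allowed)."""
    if not population:
        raise ValueError("cannot select parents from an empty population")
    idx = rng.integers(len(population), size=mu)
    return [population[i] for i in idx]


def filter_offspring(
    candidates: Sequence[str],
    current: set[str],
    initial: set[str],
) -> tuple[list[str], dict[str, int]]:
    """Validity / uniqueness / novelty filter for proposed SMILES.

    Invalid strings are dropped; survivors are canonicalized and
    deduplicated within the batch and against the current population.
    Novelty counts batch-distinct valid molecules absent from the
    initial dataset.  Nothing raises: all failures are counted.
    """
    n_proposed = len(candidates)
    n_valid = 0
    batch_distinct: list[str] = []
    seen: set[str] = set()
    for smi in candidates:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        n_valid += 1
        canon = Chem.MolToSmiles(mol)
        if canon and canon not in seen:
            seen.add(canon)
            batch_distinct.append(canon)
    n_novel = sum(1 for c in batch_distinct if c not in initial)
    survivors = [c for c in batch_distinct if c not in current]
    counts = {
        "n_proposed": n_proposed,
        "n_valid": n_valid,
        "n_novel": n_novel,
        "n_unique": len(survivors),
    }
    return survivors, counts


def select_survivors(
    parents: Sequence[Individual], offspring: Sequence[Individual], mu: int
) -> list[Individual]:
    """Top μ by fitness from parents ∪ offspring; ties by canonical SMILES."""
    pool = list(parents) + list(offspring)
    pool.sort(key=lambda ind: (-ind.fitness, ind.canonical_smiles))
    if len(pool) < mu:
        logger.warning("survivor pool (%d) smaller than mu (%d)", len(pool), mu)
        return pool
    return pool[:mu]


def _propose(
    predictor: MaskedPredictor,
    parents: Sequence[Individual],
    schedule: RunSchedule,
    rng: np.random.Generator,
) -> list[str]:
    candidates: list[str] = []
    for parent in parents:
        seq = encode(predictor.vocab, parent.canonical_smiles)
        candidates.extend(
            generate_offspring(
                predictor,
                seq,
                rate=schedule.mutation_rate,
                k=min(schedule.topk, schedule.offspring_factor),
                mode=schedule.mode,
                rng=rng,
            )
        )
    return candidates


def run_generation(
    population: list[Individual],
    schedule: RunSchedule,
    predictor: MaskedPredictor,
    generation: int,
    rng: np.random.Generator,
    scorer: PopulationScorer,
    initial: set[str],
) -> tuple[list[Individual], GenerationStats]:
    """One generation: (adapt) → select parents → mutate → filter → select."""
    try:
        adapt_report = None
        if schedule.is_adaptive(generation):
            sequences = [encode(predictor.vocab, ind.canonical_smiles) for ind in population]
            adapt_report = predictor.adapt(sequences)
        parents = select_parents(population, schedule.mu, rng)
        candidates = _propose(predictor, parents, schedule, rng)
        current = {ind.canonical_smiles for ind in population}
        survivors, counts = filter_offspring(candidates, current, initial)
        offspring = scorer.score_many(survivors)
        new_population = select_survivors(population, offspring, schedule.mu)
        offspring_canon = {ind.canonical_smiles for ind in offspring}
        n_accepted = sum(
            1 for ind in new_population if ind.canonical_smiles in offspring_canon
        )
        fitnesses = [ind.fitness for ind in new_population]
        stats = GenerationStats(
            generation=generation,
            mean_fitness=float(np.mean(fitnesses)),
            max_fitness=float(np.max(fitnesses)),
            n_accepted=n_accepted,
            adapt_report=adapt_report,
            **counts,
        )
        return new_population, stats
    except Exception as exc:
        raise RuntimeError(f"generation {generation} failed: {exc}") from exc


def _initial_population(
    initial_smiles: Sequence[str], schedule: RunSchedule, scorer: PopulationScorer
) -> list[Individual]:
    seen: set[str] = set()
    individuals: list[Individual] = []
    for smi in initial_smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        individuals.append(scorer.score(canon))
        if len(individuals) >= schedule.mu:
            break
    if len(individuals) < schedule.mu:
        logger.warning(
            "initial population has %d molecules, below mu=%d",
            len(individuals),
            schedule.mu,
        )
    if not individuals:
        raise ValueError("initial population contains no valid molecules")
    return individuals


def run(
    schedule: RunSchedule,
    predictor: MaskedPredictor,
    initial_population: Sequence[str] | str | Path,
    out_dir: str | Path | None = None,
    affinity_scorer: AffinityScorerFn | None = None,
) -> RunResult:
    """Execute ``n_repeats`` independent GA runs and optionally persist them.

    Every repeat restarts from the predictor's current (pre-trained)
    weights and from the same initial population, with its own random
    stream derived from the master seed.  With ``out_dir`` set, the run
    directory receives ``stats.csv`` (one row per generation per run),
    ``aggregated.csv`` (mean ± sd trajectory), ``population.csv`` (final
    populations) and ``config.json``.
    """
    if isinstance(initial_population, (str, Path)):
        path = Path(initial_population)
        if not path.exists():
            raise FileNotFoundError(f"initial population file not found: {path}")
        from .corpus import read_smi

        initial_smiles = read_smi(path)
    else:
        initial_smiles = list(initial_population)

    scorer = PopulationScorer(schedule.metric_set, affinity_scorer)
    population0 = _initial_population(initial_smiles, schedule, scorer)
    initial_canon = {ind.canonical_smiles for ind in population0}
    base_state = predictor.state_dict()

    t0 = time.time()
    all_stats: list[list[GenerationStats]] = []
    final_pops: list[list[Individual]] = []
    seed_seq = np.random.SeedSequence(schedule.seed)
    for child in seed_seq.spawn(schedule.n_repeats):
        predictor.load_state_dict(base_state)
        rng = np.random.default_rng(child)
        population = list(population0)
        run_stats: list[GenerationStats] = []
        for generation in range(1, schedule.generations + 1):
            if (
                schedule.strategy == "switch"
                and schedule.reinit_on_switch
                and generation == (schedule.switch_generation or 0) + 1
            ):
                predictor.load_state_dict(base_state)
            population, stats = run_generation(
                population, schedule, predictor, generation, rng, scorer, initial_canon
            )
            run_stats.append(stats)
        all_stats.append(run_stats)
        final_pops.append(population)
    predictor.load_state_dict(base_state)

    result = RunResult(schedule, all_stats, final_pops)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.stats_frame().to_csv(out / "stats.csv", index=False)
        result.aggregated().to_csv(out / "aggregated.csv", index=False)
        rows = []
        for run_idx, pop in enumerate(final_pops):
            for ind in pop:
                rows.append(
                    {
                        "run": run_idx,
                        "smiles": ind.canonical_smiles,
                        "qed": ind.metrics.qed,
                        "sa_norm": ind.metrics.sa_norm,
                        "affinity": ind.metrics.affinity,
                        "fitness": ind.fitness,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "population.csv", index=False)
        manifest = {
            "schedule": asdict(schedule),
            "predictor": predictor.backend_name,
            "n_initial": len(population0),
            "wall_clock_s": round(time.time() - t0, 3),
        }
        (out / "config.json").write_text(json.dumps(manifest, indent=2))
    return result


def generate_without_selection(
    predictor: MaskedPredictor,
    initial_population: Sequence[str],
    generations: int = 5,
    mutation_rate: float = 0.3,
    k: int = 5,
    mode: Literal["topk", "sample"] = "topk",
    adaptive: bool = False,
    seed: int = 0,
    metric_set: tuple[str, ...] = ("qed", "sa"),
) -> list[Individual]:
    """Mutation-only molecule generation (the GA with selection turned off).

    The parent population stays the initial dataset throughout.  In
    adaptive mode the predictor trains one epoch on that dataset each
    generation before proposing.  Returns the scored unique molecules
    generated across all generations that fall outside the initial data
    — the material for distribution comparisons against a reference set.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scorer = PopulationScorer(metric_set)
    initial_canon = set()
    parents: list[str] = []
    for smi in initial_population:
        mol = Chem.MolFromSmiles(smi)
        if mol is not None:
            canon = Chem.MolToSmiles(mol)
            if canon not in initial_canon:
                initial_canon.add(canon)
                parents.append(canon)
    sequences = [encode(predictor.vocab, p) for p in parents]
    collected: dict[str, None] = {}
    for _generation in range(1, generations + 1):
        if adaptive:
            predictor.adapt(sequences)
        for seq in sequences:
            for smi in generate_offspring(
                predictor, seq, rate=mutation_rate, k=k, mode=mode, rng=rng
            ):
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    continue
                canon = Chem.MolToSmiles(mol)
                if canon and canon not in initial_canon:
                    collected.setdefault(canon)
    return scorer.score_many(collected.keys())


def compare_distributions(
    generated: Sequence[Individual],
    reference: Sequence[Individual],
    metrics: Sequence[str] = ("qed", "sa_norm"),
) -> dict[str, dict[str, float]]:
    """Per-metric |Δmean| and |Δsd| between two scored sets."""
    if not generated or not reference:
        raise ValueError("both sets must be non-empty")
    out: dict[str, dict[str, float]] = {}
    for metric in metrics:
        g = np.array([getattr(ind.metrics, metric) for ind in generated], dtype=float)
        r = np.array([getattr(ind.metrics, metric) for ind in reference], dtype=float)
        out[metric] = {
            "dmean": float(abs(g.mean() - r.mean())),
            "dsd": float(abs(g.std() - r.std())),
        }
    return out
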