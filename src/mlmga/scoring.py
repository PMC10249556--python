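"""Molecular metrics and harmonic-mean fitness.

Fitness of a molecule is the harmonic mean of its metric components,
each scaled to [0, 1]:

* ``qed`` — quantitative estimate of drug-likeness (RDKit);
* ``sa_norm`` — synthetic-accessibility score ``s`` (1 = easy … 10 =
  hard, Ertl–Schuffenhauer heuristic as shipped with RDKit) mapped
  affinely to ``(10 − s) / 9`` so that higher means easier to make;
* ``affinity`` — a predicted −log10 binding affinity from an external
  scorer, divided by 10 and clipped to [0, 1].

The harmonic mean rewards molecules that are good on *every* axis: a
zero in any component zeroes the fitness.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import QED, rdMolDescriptors

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module, resolved via RDConfig)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "InvalidSmilesError",
    "MetricVector",
    "Individual",
    "harmonic_mean",
    "canonicalize",
    "drug_likeness",
    "synthesizability_raw",
    "synthesizability_norm",
    "affinity_score",
    "score_individual",
    "PopulationScorer",
    "MockAffinityScorer",
]

#: An external affinity scorer: list of SMILES -> one finite real each
#: (predicted negative log10 binding affinity).
AffinityScorerFn = Callable[[Sequence[str]], Sequence[float]]


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"not a valid SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Canonical SMILES form; raises :class:`InvalidSmilesError`."""
    return Chem.MolToSmiles(_mol(smiles))


def harmonic_mean(values: Sequence[float]) -> float:
    """k / Σ(1/xᵢ) for xᵢ ∈ [0, 1]; zero if any component is zero.

    For two components this is 2·x₁·x₂ / (x₁ + x₂).  The zero convention
    is the continuous limit and gives degenerate molecules the bottom
    rank instead of a division error.
    """
    vals = list(values)
    if len(vals) < 1:
        raise ValueError("harmonic_mean needs at least one value")
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"metric value {v} outside [0, 1]")
    if any(v == 0.0 for v in vals):
        return 0.0
    return len(vals) / sum(1.0 / v for v in vals)


def drug_likeness(smiles: str) -> float:
    """QED drug-likeness in [0, 1] (canonicalization-invariant)."""
    return float(QED.qed(_mol(smiles)))


def synthesizability_raw(smiles: str) -> float:
    """Raw synthetic-accessibility score in [1, 10] (lower = easier)."""
    return float(sascorer.calculateScore(_mol(smiles)))


def synthesizability_norm(smiles: str) -> float:
    """Normalized synthesizability (10 − s)/9 ∈ [0, 1], higher = easier."""
    s = synthesizability_raw(smiles)
    return float(np.clip((10.0 - s) / 9.0, 0.0, 1.0))


def affinity_score(scorer: AffinityScorerFn, smiles: str) -> float:
    """Map a scorer's −log10 affinity prediction to [0, 1] via pred/10, clipped."""
    pred = float(scorer([smiles])[0])
    if not np.isfinite(pred):
        raise ValueError(f"affinity scorer returned non-finite value {pred}")
    return float(np.clip(pred / 10.0, 0.0, 1.0))


@dataclass(frozen=True)
class MetricVector:
    """Per-molecule metric components; ``affinity`` may be absent."""

    qed: float | None = None
    sa_norm: float | None = None
    affinity: float | None = None

    def values(self) -> list[float]:
        return [v for v in (self.qed, self.sa_norm, self.affinity) if v is not None]


@dataclass(frozen=True)
class Individual:
    """A scored population member: canonical SMILES + metrics + fitness."""

    canonical_smiles: str
    metrics: MetricVector
    fitness: float
    flagged: bool = False


def score_individual(
    smiles: str,
    metric_set: Sequence[str] = ("qed", "sa"),
    scorer: AffinityScorerFn | None = None,
) -> Individual:
    """Canonicalize and score one molecule.

    ``metric_set`` is a subset of ``{"qed", "sa", "affinity"}``; a scorer
    must be supplied iff affinity is requested.  A scorer failure flags
    the molecule and assigns fitness 0 rather than aborting a run.
    """
    requested = set(metric_set)
    unknown = requested - {"qed", "sa", "affinity"}
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}")
    if not requested:
        raise ValueError("metric_set must not be empty")
    if ("affinity" in requested) != (scorer is not None):
        raise ValueError("a scorer is required iff 'affinity' is requested")
    canonical = canonicalize(smiles)
    qed = drug_likeness(canonical) if "qed" in requested else None
    sa = synthesizability_norm(canonical) if "sa" in requested else None
    affinity = None
    flagged = False
    if "affinity" in requested:
        try:
            affinity = affinity_score(scorer, canonical)  # type: ignore[arg-type]
        except Exception:
            flagged = True
    metrics = MetricVector(qed=qed, sa_norm=sa, affinity=affinity)
    fitness = 0.0 if flagged else harmonic_mean(metrics.values())
    return Individual(canonical, metrics, fitness, flagged)


class PopulationScorer:
    """Scores batches of SMILES with a canonical-form cache.

    Populations overlap heavily between generations and runs, so caching
    by canonical SMILES removes most of the RDKit descriptor cost.
    """

    def __init__(
        self,
        metric_set: Sequence[str] = ("qed", "sa"),
        scorer: AffinityScorerFn | None = None,
    ):
        self.metric_set = tuple(metric_set)
        self.scorer = scorer
        self._cache: dict[str, Individual] = {}

    def score(self, canonical_smiles: str) -> Individual:
        ind = self._cache.get(canonical_smiles)
        if ind is None:
            ind = score_individual(canonical_smiles, self.metric_set, self.scorer)
            self._cache[canonical_smiles] = ind
        return ind

    def score_many(self, smiles: Iterable[str]) -> list[Individual]:
        return [self.score(s) for s in smiles]


class MockAffinityScorer:
    """Deterministic stand-in for an external binding-affinity model.

    Synthetic: a fixed function of cheap structural descriptors —
    predicted −log10 affinity rises with ring count and heteroatom
    fraction, saturating inside the plausible 4–9 range.  It exists so
    that three-metric optimization runs are reproducible without any
    model download; it has no pharmacological meaning.
    """

    def __init__(self, base: float = 4.0, ring_weight: float = 2.5, hetero_weight: float = 2.5):
        self.base = base
        self.ring_weight = ring_weight
        self.hetero_weight = hetero_weight

    def __call__(self, smiles_list: Sequence[str]) -> list[float]:
        out = []
        for s in smiles_list:
            mol = _mol(s)
            n_rings = rdMolDescriptors.CalcNumRings(mol)
            n_heavy = mol.GetNumHeavyAtoms()
            n_hetero = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
            hetero_frac = n_hetero / max(n_heavy, 1)
            pred = (
                self.base
                + self.ring_weight * min(n_rings, 4) / 4.0
                + self.hetero_weight * min(2.0 * hetero_frac, 1.0)
            )
            out.append(float(pred))
        return out
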