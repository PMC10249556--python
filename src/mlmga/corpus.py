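"""Synthetic SMILES corpora and initial populations.

Every experiment in this package runs from data generated here, so no
external downloads are required.  Molecules are assembled by random
recombination of a packaged attachment-point fragment library (a cap –
linker* – cap chain of one to four fragments), validity-checked with
RDKit, deduplicated by canonical form, and filtered.

Three generators mirror the datasets molecular-optimization studies
typically start from:

* :func:`generate_corpus` — a broad "pre-training" distribution of valid
  drug-like molecules (optionally filtered by normalized
  synthesizability, the screen commonly applied to augmented corpora);
* :func:`make_gdb9_like` — a low-fitness initial population of small
  molecules (≤ 9 heavy atoms, C/N/O/F only, QM9-style composition);
* :func:`make_top_like` — a high-fitness initial population: the top *n*
  of a larger pool ranked by the harmonic mean of drug-likeness and
  synthesizability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .scoring import PopulationScorer, synthesizability_norm

__all__ = [
    "FragmentLibrary",
    "CorpusSpec",
    "generate_corpus",
    "make_gdb9_like",
    "make_top_like",
    "read_smi",
    "write_smi",
]


def read_smi(path) -> list[str]:
    """Read a .smi file (one SMILES per line, blank lines ignored)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_smi(smiles: Iterable[str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")


@dataclass(frozen=True)
class FragmentLibrary:
    """Caps (one attachment point) and linkers (two attachment points)."""

    caps: tuple[str, ...]
    linkers: tuple[str, ...]

    @classmethod
    def from_packaged(cls, name: str = "druglike") -> "FragmentLibrary":
        """Load a packaged library: ``"druglike"`` or ``"small"``."""
        text = (
            resources.files("mlmga.data")
            .joinpath(f"fragments_{name}.txt")
            .read_text()
        )
        caps: list[str] = []
        linkers: list[str] = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            role, smi = line.split()
            (caps if role == "cap" else linkers).append(smi)
        return cls(tuple(caps), tuple(linkers))


def _assemble(fragments: Sequence[str]) -> str | None:
    """Fuse a cap–linker*–cap chain into one molecule via molzip.

    Attachment dummies of consecutive fragments get matching atom-map
    labels; a single molzip call then forms all the bonds.  Returns the
    canonical SMILES, or None if sanitization fails.
    """
    combined = None
    label = 1
    for i, smi in enumerate(fragments):
        mol = Chem.RWMol(Chem.MolFromSmiles(smi))
        dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if i in (0, len(fragments) - 1):
            if len(dummies) != 1:
                return None
            dummies[0].SetAtomMapNum(label)
        else:
            if len(dummies) != 2:
                return None
            dummies[0].SetAtomMapNum(label)
            label += 1
            dummies[1].SetAtomMapNum(label)
        combined = mol if combined is None else Chem.RWMol(Chem.CombineMols(combined, mol))
    try:
        out = Chem.molzip(combined)
        Chem.SanitizeMol(out)
        return Chem.MolToSmiles(out)
    except Exception:
        return None


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic-corpus draw.

    ``min_sa_norm`` keeps only molecules whose normalized
    synthesizability strictly exceeds the threshold (0.30 is the
    customary screen for augmented training corpora).  ``element_set``
    and ``max_heavy_atoms`` constrain composition; ``None`` disables a
    filter.
    """

    n_molecules: int
    library: str = "druglike"
    max_heavy_atoms: int | None = None
    element_set: frozenset[str] | None = None
    min_sa_norm: float | None = None
    min_fragments: int = 2
    max_fragments: int = 4
    seed: int = 0
    retry_factor: int = 200

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not 2 <= self.min_fragments <= self.max_fragments:
            raise ValueError("need 2 <= min_fragments <= max_fragments")
        if self.element_set is not None:
            object.__setattr__(self, "element_set", frozenset(self.element_set))


def _passes_filters(smiles: str, spec: CorpusSpec) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    if spec.max_heavy_atoms is not None and mol.GetNumHeavyAtoms() > spec.max_heavy_atoms:
        return False
    if spec.element_set is not None:
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() > 1 and atom.GetSymbol() not in spec.element_set:
                return False
    if spec.min_sa_norm is not None and synthesizability_norm(smiles) <= spec.min_sa_norm:
        return False
    return True


def generate_corpus(spec: CorpusSpec) -> list[str]:
    """Generate ``spec.n_molecules`` valid, unique, filtered SMILES.

    Deterministic under ``spec.seed``.  If the retry budget
    (``retry_factor × n_molecules`` assembly attempts) runs out first, a
    partial corpus is returned with a warning.
    """
    lib = FragmentLibrary.from_packaged(spec.library)
    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    seen: set[str] = set()
    budget = spec.retry_factor * spec.n_molecules
    while len(out) < spec.n_molecules and budget > 0:
        budget -= 1
        n_frag = int(rng.integers(spec.min_fragments, spec.max_fragments + 1))
        chain = [lib.caps[rng.integers(len(lib.caps))]]
        for _ in range(n_frag - 2):
            chain.append(lib.linkers[rng.integers(len(lib.linkers))])
        chain.append(lib.caps[rng.integers(len(lib.caps))])
        smiles = _assemble(chain)
        if smiles is None or smiles in seen:
            continue
        if not _passes_filters(smiles, spec):
            continue
        seen.add(smiles)
        out.append(smiles)
    if len(out) < spec.n_molecules:
        warnings.warn(
            f"corpus generator produced {len(out)}/{spec.n_molecules} molecules "
            "before exhausting its retry budget",
            stacklevel=2,
        )
    return out


def make_gdb9_like(n: int, seed: int = 0, path=None) -> list[str]:
    """A low-fitness initial population of small C/N/O/F molecules.

    Molecules carry at most 9 heavy atoms, emulating the composition of
    a QM9-style enumeration; their drug-likeness is intrinsically low,
    which is the premise of the low-fitness starting condition.
    """
    spec = CorpusSpec(
        n_molecules=n,
        library="small",
        max_heavy_atoms=9,
        element_set=frozenset({"C", "N", "O", "F"}),
        min_fragments=2,
        max_fragments=3,
        seed=seed,
    )
    smiles = generate_corpus(spec)
    if path is not None:
        write_smi(smiles, path)
    return smiles


def make_top_like(n: int, pool_factor: int = 4, seed: int = 0, path=None) -> list[str]:
    """A high-fitness initial population.

    Generates ``n × pool_factor`` broad-corpus molecules, scores the
    two-metric harmonic fitness (drug-likeness × synthesizability), and
    keeps the top ``n``.
    """
    if pool_factor < 2:
        raise ValueError("pool_factor must be >= 2")
    pool = generate_corpus(CorpusSpec(n_molecules=n * pool_factor, seed=seed))
    scorer = PopulationScorer(metric_set=("qed", "sa"))
    scored = scorer.score_many(pool)
    scored.sort(key=lambda ind: (-ind.fitness, ind.canonical_smiles))
    smiles = [ind.canonical_smiles for ind in scored[:n]]
    if path is not None:
        write_smi(smiles, path)
    return smiles
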