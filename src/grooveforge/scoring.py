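"""Scorer contracts and concrete scorers.

The search engine is scorer-agnostic: anything exposing ``name``,
``polarity`` and a pure ``score(peptide)`` works.  Docking scores computed
externally (e.g. by a genetic-algorithm docking program) enter through
:class:`ScoreTable`; the :class:`SurrogateGrooveScorer` is a deterministic,
knowingly non-physical stand-in so the whole pipeline runs without any
proprietary software; :class:`MockScorer` draws reproducible additive scores
for testing search behavior.

Polarity is explicit metadata: docking fitness scores are higher-is-better,
free-energy-like scores (kJ/mol) are lower-is-better.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Dict, Mapping, Optional, Protocol

import numpy as np

from .errors import ConfigurationError, InputError, ScoreLookupError
from .mutation_space import (
    DEFAULT_RULES,
    DEFAULT_TABLE,
    AminoAcidTable,
    CandidatePeptide,
    MutationRules,
    enumerate_single_mutations,
)

__all__ = [
    "Polarity",
    "Scorer",
    "ScoreTable",
    "TableScorer",
    "score_from_table",
    "SurrogateParams",
    "SurrogateGrooveScorer",
    "surrogate_groove_score",
    "AdditiveScorer",
    "MockScorer",
    "is_improvement",
    "read_score_table",
    "write_score_table",
]


class Polarity(str, Enum):
    """Direction in which a scorer improves."""

    HIGHER = "higher"
    LOWER = "lower"


class Scorer(Protocol):
    name: str
    polarity: Polarity

    def score(self, peptide: CandidatePeptide) -> float: ...


def is_improvement(
    candidate_score: float, reference_score: float, polarity: Polarity
) -> bool:
    """Strict improvement in the scorer's favorable direction; ties fail."""
    if polarity is Polarity.HIGHER:
        return candidate_score > reference_score
    return candidate_score < reference_score


# ---------------------------------------------------------------------------
# File-backed score tables


@dataclass
class ScoreTable:
    """Externally computed scores keyed by sequence."""

    scores: Dict[str, float]
    name: str = "table"
    polarity: Polarity = Polarity.HIGHER

    def __post_init__(self) -> None:
        self.scores = {seq.upper(): float(s) for seq, s in self.scores.items()}

    def lookup(self, sequence: str) -> float:
        try:
            return self.scores[sequence.upper()]
        except KeyError:
            raise ScoreLookupError(
                f"sequence {sequence!r} not in score table {self.name!r}"
            ) from None


def score_from_table(peptide: CandidatePeptide, table: ScoreTable) -> float:
    return table.lookup(peptide.sequence)


@dataclass
class TableScorer:
    """Scorer adapter over a :class:`ScoreTable`."""

    table: ScoreTable

    @property
    def name(self) -> str:
        return self.table.name

    @property
    def polarity(self) -> Polarity:
        return self.table.polarity

    def score(self, peptide: CandidatePeptide) -> float:
        return score_from_table(peptide, self.table)


def write_score_table(path: os.PathLike | str, table: ScoreTable) -> None:
    """TSV with a ``# scorer=<name> polarity=<higher|lower>`` header."""
    with open(path, "w") as fh:
        fh.write(f"# scorer={table.name} polarity={table.polarity.value}\n")
        for seq in table.scores:
            fh.write(f"{seq}\t{table.scores[seq]!s}\n")


def read_score_table(path: os.PathLike | str) -> ScoreTable:
    name, polarity = "table", Polarity.HIGHER
    scores: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                for tok in line.lstrip("#").split():
                    if tok.startswith("scorer="):
                        name = tok.split("=", 1)[1]
                    elif tok.startswith("polarity="):
                        polarity = Polarity(tok.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(
                    f"{path}:{lineno}: expected 'sequence<TAB>score'"
                )
            seq, val = parts
            if seq.upper() in scores:
                raise InputError(f"{path}:{lineno}: duplicate sequence {seq}")
            try:
                scores[seq.upper()] = float(val)
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: bad score {val!r}"
                ) from None
    return ScoreTable(scores, name=name, polarity=polarity)


# ---------------------------------------------------------------------------
# Surrogate groove-complementarity scorer

@dataclass(frozen=True)
class SurrogateParams:
    """Two-face additive hydropathy model.

    The reference groove binder alternates small/bulky hydrophobics on one
    face (xGxFxGxF, the fibril-contact face) and solubilizing polar/charged
    residues on the other (RxTxExKx).  The surrogate rewards hydrophobicity
    on the contact face and hydrophilicity on the solvent face.
    """

    contact_positions: frozenset = frozenset({2, 4, 6, 8})
    solvent_positions: frozenset = frozenset({1, 3, 5, 7})
    w_contact: float = 1.0
    w_solvent: float = 1.0

    def validate_for_length(self, length: int) -> None:
        if self.contact_positions & self.solvent_positions:
            raise ConfigurationError("contact and solvent faces overlap")
        covered = self.contact_positions | self.solvent_positions
        if covered != set(range(1, length + 1)):
            raise ConfigurationError(
                f"faces {sorted(covered)} do not cover positions 1..{length}"
            )


def surrogate_groove_score(
    peptide: CandidatePeptide,
    params: SurrogateParams = SurrogateParams(),
    table: AminoAcidTable = DEFAULT_TABLE,
) -> float:
    """w_c * sum(h on contact face) - w_s * sum(h on solvent face).

    Higher is better.  Deliberately non-physical: a transparent, pure stand-
    in for a docking score, not a model of binding.
    """
    params.validate_for_length(len(peptide.sequence))
    h = table.hydropathy_of
    contact = sum(h(peptide.sequence[i - 1]) for i in params.contact_positions)
    solvent = sum(h(peptide.sequence[j - 1]) for j in params.solvent_positions)
    return params.w_contact * contact - params.w_solvent * solvent


@dataclass(frozen=True)
class SurrogateGrooveScorer:
    params: SurrogateParams = SurrogateParams()
    table: AminoAcidTable = DEFAULT_TABLE
    name: str = "surrogate"
    polarity: Polarity = Polarity.HIGHER

    def score(self, peptide: CandidatePeptide) -> float:
        return surrogate_groove_score(peptide, self.params, self.table)


# ---------------------------------------------------------------------------
# Additive / mock scorers for tests and search validation


@dataclass
class AdditiveScorer:
    """base + per-mutation gains + optional pairwise interaction terms.

    Gains are keyed by mutation notation ("G2V"); interactions by the
    frozenset of two notations.  Pure and deterministic by construction.
    """

    gains: Mapping[str, float]
    base: float = 0.0
    interactions: Mapping[frozenset, float] = field(default_factory=dict)
    default_gain: Optional[float] = None
    name: str = "additive"
    polarity: Polarity = Polarity.HIGHER

    def score(self, peptide: CandidatePeptide) -> float:
        total = self.base
        notations = sorted(str(m) for m in peptide.mutations)
        for n in notations:
            if n in self.gains:
                total += self.gains[n]
            elif self.default_gain is not None:
                total += self.default_gain
            else:
                raise ScoreLookupError(f"no gain defined for mutation {n}")
        for pair in combinations(notations, 2):
            total += self.interactions.get(frozenset(pair), 0.0)
        return total


def MockScorer(
    reference: str,
    seed: int,
    rules: MutationRules = DEFAULT_RULES,
    gain_scale: float = 1.0,
    pairwise: bool = False,
    pair_scale: float = 0.5,
    name: Optional[str] = None,
) -> AdditiveScorer:
    """Seeded random additive scorer over ``reference``'s single mutations.

    Gains ~ N(0, gain_scale^2) per allowed single mutation; optional
    interaction terms ~ N(0, pair_scale^2) per unordered mutation pair.
    Same seed, same scorer — search runs are bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    singles = [str(m) for m in enumerate_single_mutations(reference, rules)]
    gains = {n: float(g) for n, g in zip(singles, rng.normal(0.0, gain_scale, len(singles)))}
    interactions: Dict[frozenset, float] = {}
    if pairwise:
        for pair in combinations(singles, 2):
            interactions[frozenset(pair)] = float(rng.normal(0.0, pair_scale))
    return AdditiveScorer(
        gains=gains,
        interactions=interactions,
        name=name or f"mock:{seed}",
    )
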