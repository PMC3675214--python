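"""Recursive combine-score-accept search for an Inhibitor Candidate Library.

The methodology: score every allowed single mutant of the reference and keep
the strict improvements (these n1 peptides initiate the ICL).  Then,
repeatedly, form the 2-combinations of the mutation sets of all current
members, score each novel union, and append the ones that strictly beat the
reference.  Cycle 1 turns singles into doubles; cycle 2 pairs 1- and 2-point
members into 3- and 4-point candidates, so two cycles reach the default
stacking cap of 4.  Finally the surviving library is rescored with a second,
independent scorer and filtered again against the reference.

Reachability is deliberately pairwise: a k-point candidate exists only if it
arises as the union of two current members, which is not the same as
enumerating all subsets of accepted singles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, FrozenSet, List, Optional, Set, Tuple

from .errors import GrooveforgeError
from .mutation_space import (
    DEFAULT_RULES,
    CandidatePeptide,
    CombineRejection,
    Mutation,
    MutationRules,
    apply_mutations,
    combine_mutation_sets,
    enumerate_single_mutations,
)
from .scoring import Polarity, Scorer, is_improvement

__all__ = [
    "LibraryMember",
    "CycleStats",
    "CandidateLibrary",
    "SearchConfig",
    "initialize_library",
    "combination_cycle",
    "run_search",
    "rescore_and_filter",
]

# A veto hook models the manual pose inspection step (candidates whose
# docked pose misses the glycine groove are discarded); default accepts all.
VetoHook = Callable[[CandidatePeptide], bool]


@dataclass
class LibraryMember:
    peptide: CandidatePeptide
    primary_score: float
    cycle: int
    secondary_score: Optional[float] = None
    # each entry is the (parent_a, parent_b) notation pair that produced or
    # re-produced this member; empty for cycle-0 singles
    parents: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    @property
    def level(self) -> int:
        return self.peptide.level


@dataclass
class CycleStats:
    cycle: int
    pairs_considered: int = 0
    scored: int = 0
    accepted: int = 0
    rejections: Dict[str, int] = field(default_factory=dict)

    def count(self, reason: str) -> None:
        self.rejections[reason] = self.rejections.get(reason, 0) + 1


@dataclass
class CandidateLibrary:
    """The growing ICL: reference, accepted members, provenance, run log."""

    reference: CandidatePeptide
    reference_score: float
    scorer_name: str
    members: Dict[str, LibraryMember] = field(default_factory=dict)
    cycle_log: List[CycleStats] = field(default_factory=list)
    # sequences scored and rejected (score cached so multi-parent reachable
    # sequences are scored once per scorer)
    rejected: Dict[str, float] = field(default_factory=dict)
    # unordered pairs of member mutation sets already combined
    attempted_pairs: Set[FrozenSet[FrozenSet[Mutation]]] = field(
        default_factory=set
    )
    cycles_run: int = 0

    @property
    def size(self) -> int:
        return len(self.members)

    def level_counts(self, max_level: int = 4) -> Dict[int, int]:
        counts = {lvl: 0 for lvl in range(1, max_level + 1)}
        for member in self.members.values():
            counts[member.level] = counts.get(member.level, 0) + 1
        return counts

    def member_list(self) -> List[LibraryMember]:
        return list(self.members.values())

    def clone(self) -> "CandidateLibrary":
        return CandidateLibrary(
            reference=self.reference,
            reference_score=self.reference_score,
            scorer_name=self.scorer_name,
            members={
                seq: replace(m, parents=list(m.parents))
                for seq, m in self.members.items()
            },
            cycle_log=[
                replace(c, rejections=dict(c.rejections))
                for c in self.cycle_log
            ],
            rejected=dict(self.rejected),
            attempted_pairs=set(self.attempted_pairs),
            cycles_run=self.cycles_run,
        )


@dataclass(frozen=True)
class SearchConfig:
    max_level: int = 4
    max_cycles: int = 2
    target_size: Optional[int] = None
    primary_scorer: Optional[str] = None
    secondary_scorer: Optional[str] = None

    def __post_init__(self) -> None:
        if self.max_level < 1:
            raise ValueError("max_level must be >= 1")
        if self.max_cycles < 0:
            raise ValueError("max_cycles must be >= 0")


def _score(scorer: Scorer, peptide: CandidatePeptide) -> float:
    try:
        return float(scorer.score(peptide))
    except GrooveforgeError as exc:
        raise type(exc)(
            f"scorer {scorer.name!r} failed on {peptide.sequence}: {exc}"
        ) from exc


def initialize_library(
    reference: str,
    scorer: Scorer,
    rules: MutationRules = DEFAULT_RULES,
    veto: Optional[VetoHook] = None,
) -> CandidateLibrary:
    """Score all single mutants; keep strict improvements (the n1 members)."""
    ref_peptide = apply_mutations(reference, frozenset())
    ref_score = _score(scorer, ref_peptide)
    library = CandidateLibrary(
        reference=ref_peptide,
        reference_score=ref_score,
        scorer_name=scorer.name,
    )
    stats = CycleStats(cycle=0)
    for mutation in enumerate_single_mutations(reference, rules):
        peptide = apply_mutations(reference, frozenset({mutation}))
        if veto is not None and not veto(peptide):
            stats.count("vetoed")
            continue
        score = _score(scorer, peptide)
        stats.scored += 1
        if is_improvement(score, ref_score, scorer.polarity):
            library.members[peptide.sequence] = LibraryMember(
                peptide=peptide, primary_score=score, cycle=0
            )
            stats.accepted += 1
        else:
            library.rejected[peptide.sequence] = score
            stats.count("score-not-improved")
    library.cycle_log.append(stats)
    return library


def combination_cycle(
    library: CandidateLibrary,
    scorer: Scorer,
    rules: MutationRules = DEFAULT_RULES,
    veto: Optional[VetoHook] = None,
) -> CandidateLibrary:
    """One pairwise-combination pass over a snapshot of the current members.

    Returns a new library; the input is left untouched.  Pairs already
    combined in an earlier cycle are skipped (cycle 2 therefore only forms
    1+2 and 2+2 unions, the 1+1 pairs having been exhausted in cycle 1).
    """
    out = library.clone()
    out.cycles_run += 1
    stats = CycleStats(cycle=out.cycles_run)
    snapshot = library.member_list()  # members at cycle start only
    reference = library.reference.sequence
    for i in range(len(snapshot)):
        for j in range(i + 1, len(snapshot)):
            a, b = snapshot[i], snapshot[j]
            pair_key = frozenset({a.peptide.mutations, b.peptide.mutations})
            if pair_key in out.attempted_pairs:
                continue
            out.attempted_pairs.add(pair_key)
            stats.pairs_considered += 1
            union = combine_mutation_sets(
                a.peptide.mutations, b.peptide.mutations, rules
            )
            if isinstance(union, CombineRejection):
                stats.count(union.reason)
                continue
            peptide = apply_mutations(reference, union)
            parent_pair = (a.peptide.notation, b.peptide.notation)
            if peptide.sequence in out.members:
                out.members[peptide.sequence].parents.append(parent_pair)
                stats.count("duplicate-member")
                continue
            if peptide.sequence in out.rejected:
                stats.count("cached-rejection")
                continue
            if veto is not None and not veto(peptide):
                stats.count("vetoed")
                continue
            score = _score(scorer, peptide)
            stats.scored += 1
            if is_improvement(score, out.reference_score, scorer.polarity):
                out.members[peptide.sequence] = LibraryMember(
                    peptide=peptide,
                    primary_score=score,
                    cycle=out.cycles_run,
                    parents=[parent_pair],
                )
                stats.accepted += 1
            else:
                out.rejected[peptide.sequence] = score
                stats.count("score-not-improved")
    out.cycle_log.append(stats)
    return out


def run_search(
    reference: str,
    scorer: Scorer,
    rules: MutationRules = DEFAULT_RULES,
    config: SearchConfig = SearchConfig(),
    veto: Optional[VetoHook] = None,
) -> CandidateLibrary:
    """Initialize, then combine up to ``max_cycles`` times.

    Stops early when a cycle adds no members or the target size is reached.
    The stacking cap is ``config.max_level`` (overriding the rules' cap).
    """
    effective_rules = replace(rules, max_mutations=config.max_level)
    library = initialize_library(reference, scorer, effective_rules, veto)
    for _ in range(config.max_cycles):
        if (
            config.target_size is not None
            and library.size >= config.target_size
        ):
            break
        before = library.size
        library = combination_cycle(library, scorer, effective_rules, veto)
        if library.size == before:
            break
    return library


def rescore_and_filter(
    library: CandidateLibrary, second_scorer: Scorer
) -> List[LibraryMember]:
    """Members strictly better than the reference under a second scorer.

    Returns copies carrying both scores, sorted best-first in the second
    scorer's polarity (ties broken by sequence for determinism).
    """
    ref_second = _score(second_scorer, library.reference)
    survivors: List[LibraryMember] = []
    for member in library.member_list():
        second = _score(second_scorer, member.peptide)
        if is_improvement(second, ref_second, second_scorer.polarity):
            survivors.append(replace(member, secondary_score=second))
    sign = -1.0 if second_scorer.polarity is Polarity.HIGHER else 1.0
    survivors.sort(key=lambda m: (sign * m.secondary_score, m.sequence))
    return survivors
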