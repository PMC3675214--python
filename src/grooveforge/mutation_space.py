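"""Chemically restricted mutation space of a reference peptide.

The full sequence space of an L-mer is ``20**L`` (2.56e10 already for an
8-mer), far beyond what docking can assess.  The space is narrowed by
allowing each residue to be replaced only by members of its own chemical
group — nonpolar aliphatic, aromatic, polar uncharged, negatively charged,
positively charged — with an explicit exclusion list on top.  By default the
single exclusion is glycine→methionine, since the methionine derivative of
the reference groove binder is known to be inactive.

Positions are 1-based everywhere a user sees them; the string notation for a
substitution is ``<from><position><to>``, e.g. ``"G2V"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Mapping, Tuple

from .errors import (
    InputError,
    MutationConflictError,
    MutationConsistencyError,
    UnknownResidueError,
)

__all__ = [
    "AminoAcidTable",
    "DEFAULT_TABLE",
    "MutationRules",
    "DEFAULT_RULES",
    "Mutation",
    "CandidatePeptide",
    "enumerate_single_mutations",
    "apply_mutations",
    "diff_mutations",
    "combine_mutation_sets",
    "CombineRejection",
    "sequence_space_size",
    "STANDARD_RESIDUES",
]

# Chemical grouping of the 20 standard residues by side-chain character.
_GROUPS: Mapping[str, str] = {
    "nonpolar-aliphatic": "GAVPLIM",
    "aromatic": "FYW",
    "polar-uncharged": "STCNQ",
    "negatively-charged": "DE",
    "positively-charged": "KHR",
}

# Kyte-Doolittle hydropathy index (dimensionless; positive = hydrophobic).
_KYTE_DOOLITTLE: Mapping[str, float] = {
    "G": -0.4, "A": 1.8, "V": 4.2, "P": 1.6, "L": 3.8, "I": 4.5, "M": 1.9,
    "F": 2.8, "Y": -1.3, "W": -0.9,
    "S": -0.8, "T": -0.7, "C": 2.5, "N": -3.5, "Q": -3.5,
    "D": -3.5, "E": -3.5,
    "K": -3.9, "H": -3.2, "R": -4.5,
}

STANDARD_RESIDUES: FrozenSet[str] = frozenset(_KYTE_DOOLITTLE)


@dataclass(frozen=True)
class AminoAcidTable:
    """Residue groups and hydropathy values.

    Invariants: exactly 20 residues, each in exactly one group.  Histidine
    sits in the positively-charged group; there is no pH-dependent handling.
    """

    groups: Mapping[str, str] = field(default_factory=lambda: dict(_GROUPS))
    hydropathy: Mapping[str, float] = field(
        default_factory=lambda: dict(_KYTE_DOOLITTLE)
    )

    def __post_init__(self) -> None:
        seen: dict = {}
        for name, members in self.groups.items():
            for res in members:
                if res in seen:
                    raise ValueError(
                        f"residue {res} in both {seen[res]} and {name}"
                    )
                seen[res] = name
        if len(seen) != len(self.hydropathy):
            raise ValueError("groups and hydropathy cover different residues")

    def group_of(self, residue: str) -> str:
        for name, members in self.groups.items():
            if residue in members:
                return name
        raise UnknownResidueError(f"unknown residue {residue!r}")

    def group_members(self, residue: str) -> str:
        """All residues sharing ``residue``'s group (including itself)."""
        return self.groups[self.group_of(residue)]

    def hydropathy_of(self, residue: str) -> float:
        try:
            return self.hydropathy[residue]
        except KeyError:
            raise UnknownResidueError(f"unknown residue {residue!r}") from None


DEFAULT_TABLE = AminoAcidTable()


@dataclass(frozen=True)
class MutationRules:
    """Which substitutions are allowed and how many may be stacked.

    Exclusions are directional: the default forbids G→M but leaves M→G
    allowed.
    """

    table: AminoAcidTable = DEFAULT_TABLE
    exclusions: FrozenSet[Tuple[str, str]] = frozenset({("G", "M")})
    max_mutations: int = 4

    def __post_init__(self) -> None:
        if self.max_mutations < 1:
            raise ValueError("max_mutations must be >= 1")

    def allowed_targets(self, residue: str) -> List[str]:
        """Substitution targets for ``residue``, alphabetical, self excluded."""
        return sorted(
            t
            for t in self.table.group_members(residue)
            if t != residue and (residue, t) not in self.exclusions
        )


DEFAULT_RULES = MutationRules()

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True, order=True)
class Mutation:
    """A single residue substitution, 1-based, written ``<from><pos><to>``."""

    position: int
    from_residue: str
    to_residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise InputError(f"position must be 1-based, got {self.position}")
        for res in (self.from_residue, self.to_residue):
            if res not in STANDARD_RESIDUES:
                raise UnknownResidueError(f"unknown residue {res!r}")
        if self.to_residue == self.from_residue:
            raise InputError(f"self-substitution {self}")

    def __str__(self) -> str:
        return f"{self.from_residue}{self.position}{self.to_residue}"

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        m = _MUTATION_RE.match(text.strip())
        if m is None:
            raise InputError(f"cannot parse mutation notation {text!r}")
        return cls(int(m.group(2)), m.group(1), m.group(3))

    def validate(self, reference: str, rules: MutationRules) -> None:
        """Check this substitution against a reference under ``rules``."""
        if self.position > len(reference):
            raise InputError(
                f"{self}: position beyond reference length {len(reference)}"
            )
        ref_res = reference[self.position - 1]
        if ref_res != self.from_residue:
            raise MutationConsistencyError(
                f"{self}: reference has {ref_res} at position {self.position}"
            )
        if self.to_residue not in rules.allowed_targets(self.from_residue):
            raise InputError(f"{self}: substitution not allowed by rules")


@dataclass(frozen=True)
class CandidatePeptide:
    """A peptide plus the substitutions relating it to the reference.

    ``level`` is the number of stacked mutations; the reference itself is
    level 0.
    """

    sequence: str
    mutations: FrozenSet[Mutation] = frozenset()

    @property
    def level(self) -> int:
        return len(self.mutations)

    @property
    def notation(self) -> str:
        """Record id used in FASTA/TSV output, e.g. ``"G2V+F4W"``."""
        if not self.mutations:
            return "reference"
        return "+".join(str(m) for m in sorted(self.mutations))


def _validate_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    if not sequence:
        raise InputError("empty peptide sequence")
    for i, res in enumerate(sequence, start=1):
        if res not in STANDARD_RESIDUES:
            raise UnknownResidueError(
                f"unknown residue {res!r} at position {i}"
            )
    return sequence


def enumerate_single_mutations(
    reference: str, rules: MutationRules = DEFAULT_RULES
) -> List[Mutation]:
    """Every allowed single substitution of ``reference``.

    Deterministic order: by position, then alphabetical target residue.
    For the 8-mer groove binder RGTFEGKF under default rules this yields 23
    substitutions.
    """
    reference = _validate_sequence(reference)
    out: List[Mutation] = []
    for pos, res in enumerate(reference, start=1):
        for target in rules.allowed_targets(res):
            out.append(Mutation(pos, res, target))
    return out


def apply_mutations(
    reference: str, mutations: Iterable[Mutation]
) -> CandidatePeptide:
    """Apply a position-distinct set of substitutions to ``reference``."""
    reference = _validate_sequence(reference)
    mutset = frozenset(mutations)
    seen_positions: dict = {}
    seq = list(reference)
    for mut in sorted(mutset):
        if mut.position in seen_positions:
            raise MutationConflictError(
                f"mutations {seen_positions[mut.position]} and {mut} "
                f"both target position {mut.position}"
            )
        seen_positions[mut.position] = mut
        if mut.position > len(reference):
            raise InputError(
                f"{mut}: position beyond reference length {len(reference)}"
            )
        if reference[mut.position - 1] != mut.from_residue:
            raise MutationConsistencyError(
                f"{mut}: reference has {reference[mut.position - 1]} "
                f"at position {mut.position}"
            )
        seq[mut.position - 1] = mut.to_residue
    return CandidatePeptide("".join(seq), mutset)


def diff_mutations(reference: str, sequence: str) -> FrozenSet[Mutation]:
    """Recover the substitution set turning ``reference`` into ``sequence``."""
    reference = _validate_sequence(reference)
    sequence = _validate_sequence(sequence)
    if len(reference) != len(sequence):
        raise InputError(
            f"length mismatch: reference {len(reference)}, "
            f"sequence {len(sequence)}"
        )
    return frozenset(
        Mutation(i, a, b)
        for i, (a, b) in enumerate(zip(reference, sequence), start=1)
        if a != b
    )


@dataclass(frozen=True)
class CombineRejection:
    """Typed refusal to merge two mutation sets."""

    reason: str  # "position-conflict" | "over-cap" | "no-new-mutation"

    POSITION_CONFLICT = "position-conflict"
    OVER_CAP = "over-cap"
    NO_NEW_MUTATION = "no-new-mutation"


def combine_mutation_sets(
    a: FrozenSet[Mutation],
    b: FrozenSet[Mutation],
    rules: MutationRules = DEFAULT_RULES,
):
    """Union of two mutation sets, or a typed rejection.

    The union is accepted only when all positions are distinct, it stays
    within the stacking cap, and it is strictly larger than both inputs
    (i.e. the pairing actually produced a new combination).
    """
    a, b = frozenset(a), frozenset(b)
    union = a | b
    positions = {m.position for m in union}
    if len(positions) != len(union):
        return CombineRejection(CombineRejection.POSITION_CONFLICT)
    if len(union) > rules.max_mutations:
        return CombineRejection(CombineRejection.OVER_CAP)
    if len(union) <= max(len(a), len(b)):
        return CombineRejection(CombineRejection.NO_NEW_MUTATION)
    return union


def sequence_space_size(length: int, alphabet_size: int = 20) -> int:
    """Exact count of sequences of ``length`` over ``alphabet_size`` letters."""
    if length < 1 or alphabet_size < 1:
        raise InputError("length and alphabet_size must be positive")
    return alphabet_size**length
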