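"""Independent brute-force reference implementations used as test oracles.

Deliberately naive and written without reuse of the package's enumeration
or search logic: substitutions are found by testing all 19 alternatives per
position against the group rules, and the library recursion is a plain
fixed-snapshot loop over all member pairs.
"""

from grooveforge.mutation_space import CandidatePeptide, Mutation
from grooveforge.scoring import Polarity

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

GROUPS = ["GAVPLIM", "FYW", "STCNQ", "DE", "KHR"]

FORBIDDEN = {("G", "M")}


def brute_force_single_mutations(reference):
    """All (position, from, to) substitutions allowed by the group rules."""
    out = []
    for pos, res in enumerate(reference, start=1):
        group = next(g for g in GROUPS if res in g)
        for target in ALPHABET:
            if target == res or target not in group:
                continue
            if (res, target) in FORBIDDEN:
                continue
            out.append((pos, res, target))
    return out


def _sequence_of(reference, triples):
    seq = list(reference)
    for pos, _, to in triples:
        seq[pos - 1] = to
    return "".join(seq)


def _peptide_of(reference, triples):
    return CandidatePeptide(
        _sequence_of(reference, triples),
        frozenset(Mutation(p, f, t) for p, f, t in triples),
    )


def brute_force_search(reference, scorer, max_level=4, max_cycles=2):
    """Fixed-snapshot pairwise-combination recursion.

    Acceptance: strict improvement over the reference in the scorer's
    polarity.  Reachability: a union is admitted only when its positions are
    distinct, it respects the stacking cap, and it is strictly larger than
    both parents.  Returns {sequence: (level, score)} for all members.
    """
    ref_score = scorer.score(CandidatePeptide(reference, frozenset()))

    def better(s):
        if scorer.polarity is Polarity.HIGHER:
            return s > ref_score
        return s < ref_score

    members = {}
    for triple in brute_force_single_mutations(reference):
        muts = frozenset({triple})
        score = scorer.score(_peptide_of(reference, muts))
        if better(score):
            members[_sequence_of(reference, muts)] = (muts, score)

    for _ in range(max_cycles):
        snapshot = list(members.values())
        added = False
        for i in range(len(snapshot)):
            for j in range(i + 1, len(snapshot)):
                a, b = snapshot[i][0], snapshot[j][0]
                union = a | b
                positions = [p for p, _, _ in union]
                if len(set(positions)) != len(union):
                    continue
                if len(union) > max_level:
                    continue
                if len(union) <= max(len(a), len(b)):
                    continue
                seq = _sequence_of(reference, union)
                if seq in members:
                    continue
                score = scorer.score(_peptide_of(reference, union))
                if better(score):
                    members[seq] = (union, score)
                    added = True
        if not added:
            break
    return {seq: (len(muts), score) for seq, (muts, score) in members.items()}
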