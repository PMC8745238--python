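"""Induction of a disease property from labelled patient traces.

The classifier learns ordered *subsequence patterns* of action symbols that
are frequent in metastatic training traces and (by default) absent from
healthy ones, encodes each pattern as a nested least-fixpoint reachability
formula, and labels a new patient metastatic iff the disjunction of the
accepted patterns holds on the patient's LTS.  Subsequence (rather than
substring) semantics lets a pattern match texture milestones on any slices
in cranio-caudal order, which is the point of the multi-slice formal model.

With ``max_support_neg = 0`` the learned property cannot fire on any
healthy training trace, mirroring a precision-first clinical design.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

from .formal_models import PatientLTS
from .model_checker import FF, TT, Diamond, Mu, MuFormula, Or, Var, check

__all__ = [
    "PatternRule",
    "InducedProperty",
    "TraceIndex",
    "contains_subsequence",
    "mine_patterns",
    "encode_pattern",
    "induce_property",
    "classify_patient",
]

METASTATIC = "metastatic"
HEALTHY = "healthy"


@dataclass(frozen=True)
class PatternRule:
    """An ordered action pattern with its class-conditional trace supports."""

    pattern: tuple[str, ...]
    support_pos: float
    support_neg: float

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("pattern must be nonempty")
        if not (0 <= self.support_pos <= 1 and 0 <= self.support_neg <= 1):
            raise ValueError("supports must be fractions")


@dataclass(frozen=True)
class InducedProperty:
    """Disjunction of accepted pattern encodings; ff when no rule survived."""

    formula: MuFormula
    rules: tuple[PatternRule, ...]


class TraceIndex:
    """Positions of each symbol in a trace, for fast subsequence queries."""

    def __init__(self, trace: list[str] | tuple[str, ...]):
        self.length = len(trace)
        self.positions: dict[str, list[int]] = {}
        for i, s in enumerate(trace):
            self.positions.setdefault(s, []).append(i)

    def contains(self, pattern: tuple[str, ...]) -> bool:
        pos = -1
        for s in pattern:
            here = self.positions.get(s)
            if not here:
                return False
            k = bisect_right(here, pos)
            if k == len(here):
                return False
            pos = here[k]
        return True


def contains_subsequence(trace: list[str] | tuple[str, ...],
                         pattern: tuple[str, ...]) -> bool:
    return TraceIndex(trace).contains(pattern)


def _support(indices: list[TraceIndex], pattern: tuple[str, ...]) -> float:
    if not indices:
        return 0.0
    return sum(ix.contains(pattern) for ix in indices) / len(indices)


def mine_patterns(
    traces: list[list[str]],
    labels: list[str],
    max_len: int = 2,
    min_support_pos: float = 0.8,
    max_support_neg: float = 0.0,
) -> list[PatternRule]:
    """Exhaustive level-wise search for discriminating subsequence patterns.

    Candidates are built from the alphabet of the training traces; a pattern
    is accepted when its support among metastatic traces is at least
    ``min_support_pos`` and among healthy traces at most ``max_support_neg``.
    Positive support is antitone under extension, so candidates below the
    positive threshold are pruned before extension.  Accepted rules are
    ordered by support_pos (descending), then length, then lexicographically.
    """
    pos_ix = [TraceIndex(t) for t, l in zip(traces, labels) if l == METASTATIC]
    neg_ix = [TraceIndex(t) for t, l in zip(traces, labels) if l != METASTATIC]
    if not pos_ix or not neg_ix:
        raise ValueError("both classes must be present in the training set")
    alphabet = sorted({s for t in traces for s in t})
    if not alphabet:
        raise ValueError("empty action alphabet")

    accepted: list[PatternRule] = []
    frontier: list[tuple[str, ...]] = [()]
    for _ in range(max_len):
        next_frontier: list[tuple[str, ...]] = []
        for stem in frontier:
            for symbol in alphabet:
                pattern = stem + (symbol,)
                sp = _support(pos_ix, pattern)
                if sp < min_support_pos:
                    continue
                next_frontier.append(pattern)
                sn = _support(neg_ix, pattern)
                if sn <= max_support_neg:
                    accepted.append(
                        PatternRule(pattern=pattern, support_pos=sp, support_neg=sn)
                    )
        frontier = next_frontier
    accepted.sort(key=lambda r: (-r.support_pos, len(r.pattern), r.pattern))
    return accepted


def encode_pattern(pattern: tuple[str, ...] | list[str]) -> MuFormula:
    """Reachability encoding of subsequence containment.

    For a1..ak the formula is
    ``mu X1.(<a1>(mu X2.(<a2>(...) | <->X2)) | <->X1)`` — eventually a1,
    then eventually a2 after it, and so on.  Satisfied at the initial state
    of a chain LTS iff the pattern is a subsequence of the chain's trace.
    """
    if not pattern:
        raise ValueError("pattern must be nonempty")
    phi: MuFormula = TT()
    for depth in range(len(pattern), 0, -1):
        var = f"X{depth}"
        body = Or(Diamond(frozenset({pattern[depth - 1]}), phi), Diamond(None, Var(var)))
        phi = Mu(var, body)
    return phi


def induce_property(rules: list[PatternRule], max_rules: int = 20) -> InducedProperty:
    """Disjoin the top ``max_rules`` rules into one closed disease property."""
    kept = tuple(rules[:max_rules])
    if not kept:
        return InducedProperty(formula=FF(), rules=())
    formula: MuFormula = encode_pattern(kept[0].pattern)
    for rule in kept[1:]:
        formula = Or(formula, encode_pattern(rule.pattern))
    return InducedProperty(formula=formula, rules=kept)


def classify_patient(lts: PatientLTS, prop: InducedProperty) -> str:
    """'metastatic' iff the induced property holds on the patient model."""
    return METASTATIC if check(lts, prop.formula).verdict else HEALTHY
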