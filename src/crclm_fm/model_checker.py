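"""Modal mu-calculus formulas and their evaluation over finite LTSs.

Grammar (ASCII concrete syntax)::

    phi ::= tt | ff | X | phi & phi | phi "|" phi | !phi
          | <A>phi | [A]phi | mu X.phi | nu X.phi | (phi)
    A   ::= - | action | {action, action, ...}

with precedence ``!`` > modalities > ``&`` > ``|``; fixpoint bodies extend
as far right as possible.  ``-`` is the wildcard matching any action.
Negation is restricted to *closed* subformulas, which makes every fixpoint
body syntactically monotone; the parser rejects unbound variables and
negations over open subformulas.

Semantics are the standard ones, computed by naive Knaster–Tarski
iteration over state sets (least fixpoints from the empty set, greatest
from the full set).  The LTSs handled here are linear chains of at most a
few thousand states, so the naive algorithm is ample; state sets are
numpy boolean vectors internally and closed subformulas are evaluated
once per check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .formal_models import PatientLTS

__all__ = [
    "MuFormula",
    "TT", "FF", "Var", "Not", "And", "Or", "Diamond", "Box", "Mu", "Nu",
    "CheckResult",
    "FormulaError",
    "parse_formula",
    "read_formula",
    "sat_states",
    "check",
]


class FormulaError(ValueError):
    """Syntax, binding, or monotonicity error in a formula."""


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MuFormula:
    def __str__(self) -> str:  # pragma: no cover - overridden
        raise NotImplementedError

    def free_vars(self) -> frozenset[str]:
        return frozenset()


@dataclass(frozen=True)
class TT(MuFormula):
    def __str__(self) -> str:
        return "tt"


@dataclass(frozen=True)
class FF(MuFormula):
    def __str__(self) -> str:
        return "ff"


@dataclass(frozen=True)
class Var(MuFormula):
    name: str

    def __str__(self) -> str:
        return self.name

    def free_vars(self) -> frozenset[str]:
        return frozenset({self.name})


@dataclass(frozen=True)
class Not(MuFormula):
    phi: MuFormula

    def __str__(self) -> str:
        return f"!{_atomic(self.phi)}"

    def free_vars(self) -> frozenset[str]:
        return self.phi.free_vars()


@dataclass(frozen=True)
class And(MuFormula):
    left: MuFormula
    right: MuFormula

    def __str__(self) -> str:
        return f"{_below_and(self.left)} & {_below_and(self.right)}"

    def free_vars(self) -> frozenset[str]:
        return self.left.free_vars() | self.right.free_vars()


@dataclass(frozen=True)
class Or(MuFormula):
    left: MuFormula
    right: MuFormula

    def __str__(self) -> str:
        return f"{_below_or(self.left)} | {_below_or(self.right)}"

    def free_vars(self) -> frozenset[str]:
        return self.left.free_vars() | self.right.free_vars()


def _fmt_actions(actions: frozenset[str] | None) -> str:
    if actions is None:
        return "-"
    if len(actions) == 1:
        return next(iter(actions))
    return "{" + ", ".join(sorted(actions)) + "}"


@dataclass(frozen=True)
class Diamond(MuFormula):
    actions: frozenset[str] | None  # None = wildcard "-"
    phi: MuFormula

    def __str__(self) -> str:
        return f"<{_fmt_actions(self.actions)}>{_atomic(self.phi)}"

    def free_vars(self) -> frozenset[str]:
        return self.phi.free_vars()


@dataclass(frozen=True)
class Box(MuFormula):
    actions: frozenset[str] | None
    phi: MuFormula

    def __str__(self) -> str:
        return f"[{_fmt_actions(self.actions)}]{_atomic(self.phi)}"

    def free_vars(self) -> frozenset[str]:
        return self.phi.free_vars()


@dataclass(frozen=True)
class Mu(MuFormula):
    var: str
    phi: MuFormula

    def __str__(self) -> str:
        return f"mu {self.var}.{_atomic(self.phi)}"

    def free_vars(self) -> frozenset[str]:
        return self.phi.free_vars() - {self.var}


@dataclass(frozen=True)
class Nu(MuFormula):
    var: str
    phi: MuFormula

    def __str__(self) -> str:
        return f"nu {self.var}.{_atomic(self.phi)}"

    def free_vars(self) -> frozenset[str]:
        return self.phi.free_vars() - {self.var}


def _atomic(phi: MuFormula) -> str:
    """Render a subformula that must bind tighter than a unary operator."""
    if isinstance(phi, (TT, FF, Var)):
        return str(phi)
    return f"({phi})"


def _below_and(phi: MuFormula) -> str:
    if isinstance(phi, (Or, And, Mu, Nu)):
        return f"({phi})"
    return str(phi)


def _below_or(phi: MuFormula) -> str:
    if isinstance(phi, (Or, Mu, Nu)):
        return f"({phi})"
    return str(phi)


# ---------------------------------------------------------------------------
# Parser (recursive descent)
# ---------------------------------------------------------------------------

_KEYWORDS = {"tt", "ff", "mu", "nu"}


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> FormulaError:
        return FormulaError(f"{msg} at position {self.pos}")

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}")
        self.pos += 1

    def ident(self) -> str:
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos].isalnum() or self.text[self.pos] == "_"
        ):
            self.pos += 1
        if self.pos == start:
            raise self.error("expected identifier")
        return self.text[start:self.pos]

    def action_name(self, stop: str) -> str:
        """An action label: anything up to ',' / closing bracket, trimmed."""
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in (stop, ","):
            self.pos += 1
        name = self.text[start:self.pos].strip()
        if not name:
            raise self.error("expected action name")
        return name

    def action_set(self, stop: str) -> frozenset[str] | None:
        if self.peek() == "-":
            self.pos += 1
            return None
        if self.peek() == "{":
            self.pos += 1
            names = [self.action_name("}")]
            while self.peek() == ",":
                self.pos += 1
                names.append(self.action_name("}"))
            self.expect("}")
            return frozenset(names)
        return frozenset({self.action_name(stop)})

    # precedence: or < and < unary
    def parse_or(self) -> MuFormula:
        left = self.parse_and()
        while self.peek() == "|":
            self.pos += 1
            left = Or(left, self.parse_and())
        return left

    def parse_and(self) -> MuFormula:
        left = self.parse_unary()
        while self.peek() == "&":
            self.pos += 1
            left = And(left, self.parse_unary())
        return left

    def parse_unary(self) -> MuFormula:
        ch = self.peek()
        if ch == "!":
            self.pos += 1
            return Not(self.parse_unary())
        if ch == "<":
            self.pos += 1
            actions = self.action_set(">")
            self.expect(">")
            return Diamond(actions, self.parse_unary())
        if ch == "[":
            self.pos += 1
            actions = self.action_set("]")
            self.expect("]")
            return Box(actions, self.parse_unary())
        if ch == "(":
            self.pos += 1
            phi = self.parse_or()
            self.expect(")")
            return phi
        word_start = self.pos
        word = self.ident()
        if word == "tt":
            return TT()
        if word == "ff":
            return FF()
        if word in ("mu", "nu"):
            var = self.ident()
            if var in _KEYWORDS:
                raise self.error(f"{var!r} cannot be a variable name")
            self.expect(".")
            body = self.parse_or()  # fixpoint body extends maximally right
            return Mu(var, body) if word == "mu" else Nu(var, body)
        if word in _KEYWORDS:
            self.pos = word_start
            raise self.error(f"unexpected keyword {word!r}")
        return Var(word)


def _validate(phi: MuFormula, bound: frozenset[str]) -> None:
    """Reject unbound variables and negation over open subformulas."""
    if isinstance(phi, Var):
        if phi.name not in bound:
            raise FormulaError(f"unbound variable {phi.name!r}")
    elif isinstance(phi, Not):
        if phi.phi.free_vars():
            raise FormulaError(
                "negation over an open subformula breaks monotonicity: "
                f"!({phi.phi})"
            )
        _validate(phi.phi, bound)
    elif isinstance(phi, (And, Or)):
        _validate(phi.left, bound)
        _validate(phi.right, bound)
    elif isinstance(phi, (Diamond, Box)):
        _validate(phi.phi, bound)
    elif isinstance(phi, (Mu, Nu)):
        _validate(phi.phi, bound | {phi.var})


def parse_formula(text: str) -> MuFormula:
    """Parse the concrete syntax into a validated AST."""
    if not text.strip():
        raise FormulaError("empty formula")
    parser = _Parser(text)
    phi = parser.parse_or()
    parser.skip_ws()
    if parser.pos != len(parser.text):
        raise parser.error("trailing input")
    _validate(phi, frozenset())
    return phi


def read_formula(path: str | Path) -> MuFormula:
    """One formula per UTF-8 text file; '#' lines are comments."""
    lines = [
        ln
        for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    return parse_formula(" ".join(lines))


# ---------------------------------------------------------------------------
# Semantics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CheckResult:
    verdict: bool
    satisfying_states: frozenset[int]
    iterations: int


class _Evaluator:
    def __init__(self, lts: PatientLTS):
        self.n = lts.n_states
        self.src = np.fromiter((t[0] for t in lts.transitions), dtype=np.int64,
                               count=len(lts.transitions))
        self.dst = np.fromiter((t[2] for t in lts.transitions), dtype=np.int64,
                               count=len(lts.transitions))
        self.action = [t[1] for t in lts.transitions]
        self.iterations = 0
        self._closed_cache: dict[int, np.ndarray] = {}
        self._action_mask_cache: dict[frozenset[str] | None, np.ndarray] = {}

    def action_mask(self, actions: frozenset[str] | None) -> np.ndarray:
        if actions not in self._action_mask_cache:
            if actions is None:
                m = np.ones(len(self.action), dtype=bool)
            else:
                m = np.fromiter((a in actions for a in self.action), dtype=bool,
                                count=len(self.action))
            self._action_mask_cache[actions] = m
        return self._action_mask_cache[actions]

    def eval(self, phi: MuFormula, env: dict[str, np.ndarray]) -> np.ndarray:
        key = id(phi)
        closed = not phi.free_vars()
        if closed and key in self._closed_cache:
            return self._closed_cache[key]
        result = self._eval(phi, env)
        if closed:
            self._closed_cache[key] = result
        return result

    def _eval(self, phi: MuFormula, env: dict[str, np.ndarray]) -> np.ndarray:
        if isinstance(phi, TT):
            return np.ones(self.n, dtype=bool)
        if isinstance(phi, FF):
            return np.zeros(self.n, dtype=bool)
        if isinstance(phi, Var):
            return env[phi.name]
        if isinstance(phi, Not):
            return ~self.eval(phi.phi, env)
        if isinstance(phi, And):
            return self.eval(phi.left, env) & self.eval(phi.right, env)
        if isinstance(phi, Or):
            return self.eval(phi.left, env) | self.eval(phi.right, env)
        if isinstance(phi, Diamond):
            target = self.eval(phi.phi, env)
            hit = self.action_mask(phi.actions) & target[self.dst]
            out = np.zeros(self.n, dtype=bool)
            out[self.src[hit]] = True
            return out
        if isinstance(phi, Box):
            target = self.eval(phi.phi, env)
            bad = self.action_mask(phi.actions) & ~target[self.dst]
            out = np.ones(self.n, dtype=bool)
            out[self.src[bad]] = False
            return out
        if isinstance(phi, (Mu, Nu)):
            current = (
                np.zeros(self.n, dtype=bool)
                if isinstance(phi, Mu)
                else np.ones(self.n, dtype=bool)
            )
            while True:
                self.iterations += 1
                new_env = dict(env)
                new_env[phi.var] = current
                nxt = self.eval(phi.phi, new_env)
                if np.array_equal(nxt, current):
                    return current
                current = nxt
        raise TypeError(f"unknown formula node {phi!r}")


def sat_states(lts: PatientLTS, phi: MuFormula) -> frozenset[int]:
    """States of ``lts`` satisfying the closed formula ``phi``."""
    if phi.free_vars():
        raise FormulaError("formula must be closed")
    ev = _Evaluator(lts)
    return frozenset(np.flatnonzero(ev.eval(phi, {})).tolist())


def check(lts: PatientLTS, phi: MuFormula) -> CheckResult:
    """Model-check ``phi`` on ``lts``: True iff the initial state satisfies it."""
    if phi.free_vars():
        raise FormulaError("formula must be closed")
    ev = _Evaluator(lts)
    sat = ev.eval(phi, {})
    states = frozenset(np.flatnonzero(sat).tolist())
    return CheckResult(
        verdict=bool(sat[lts.initial]),
        satisfying_states=states,
        iterations=ev.iterations,
    )
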