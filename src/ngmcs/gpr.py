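"""Boolean gene-protein-reaction (GPR) rules.

A GPR rule states which gene products sustain a reaction: ``AND`` joins the
subunits of an enzyme complex (losing any one disables the reaction),
``OR`` joins isozymes (all must be lost to disable it). Rules are monotone
boolean expressions over gene leaves — there is no negation in the
modelling standard — which is what makes *minimal falsifying sets* (the
minimal combinations of gene losses that switch a rule from true to false)
well defined and computable as the prime implicants of the negated rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union


class GPRSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class GPRComplexityError(RuntimeError):
    """Raised when minimal-falsifying-set expansion exceeds the guard."""


class _TrueType:
    """Singleton for the always-true rule of gene-less reactions."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "TRUE"


TRUE = _TrueType()


@dataclass(frozen=True)
class Gene:
    name: str

    def __repr__(self):
        return self.name


@dataclass(frozen=True)
class And:
    children: tuple

    def __repr__(self):
        return "(" + " and ".join(map(repr, self.children)) + ")"


@dataclass(frozen=True)
class Or:
    children: tuple

    def __repr__(self):
        return "(" + " or ".join(map(repr, self.children)) + ")"


GPR = Union[_TrueType, Gene, And, Or]

_KEYWORDS_AND = {"and", "&", "&&"}
_KEYWORDS_OR = {"or", "|", "||"}


def _tokenize(rule: str):
    """Yield (token, position) pairs; identifiers are maximal runs of
    non-space, non-parenthesis characters."""
    tokens = []
    i, n = 0, len(rule)
    while i < n:
        ch = rule[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append((ch, i))
            i += 1
        else:
            j = i
            while j < n and not rule[j].isspace() and rule[j] not in "()":
                j += 1
            tokens.append((rule[i:j], i))
            i = j
    return tokens


def parse_gpr(rule: str) -> GPR:
    """Parse a GPR string into an expression tree.

    The grammar is the standard one used in SBML-FBC and model JSON:
    ``expr := term ('or' term)* ; term := factor ('and' factor)* ;
    factor := '(' expr ')' | gene``, case-insensitive keywords, ``&``/``|``
    accepted as synonyms. The empty string parses to :data:`TRUE`
    (gene-less reaction, not knockable).
    """
    tokens = _tokenize(rule)
    if not tokens:
        return TRUE
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(rule))

    def parse_expr() -> GPR:
        nonlocal pos
        children = [parse_term()]
        while peek()[0] is not None and peek()[0].lower() in _KEYWORDS_OR:
            pos += 1
            children.append(parse_term())
        if len(children) == 1:
            return children[0]
        flat = []
        for c in children:  # flatten nested ORs into one n-ary node
            flat.extend(c.children if isinstance(c, Or) else [c])
        return Or(tuple(flat))

    def parse_term() -> GPR:
        nonlocal pos
        children = [parse_factor()]
        while peek()[0] is not None and peek()[0].lower() in _KEYWORDS_AND:
            pos += 1
            children.append(parse_factor())
        if len(children) == 1:
            return children[0]
        flat = []
        for c in children:
            flat.extend(c.children if isinstance(c, And) else [c])
        return And(tuple(flat))

    def parse_factor() -> GPR:
        nonlocal pos
        tok, at = peek()
        if tok is None:
            raise GPRSyntaxError("unexpected end of rule", at)
        if tok == "(":
            pos += 1
            inner = parse_expr()
            tok2, at2 = peek()
            if tok2 != ")":
                raise GPRSyntaxError("unbalanced parenthesis", at2)
            pos += 1
            return inner
        if tok == ")":
            raise GPRSyntaxError("unbalanced parenthesis", at)
        if tok.lower() in _KEYWORDS_AND | _KEYWORDS_OR:
            raise GPRSyntaxError(f"unexpected operator {tok!r}", at)
        pos += 1
        return Gene(tok)

    result = parse_expr()
    tok, at = peek()
    if tok is not None:
        raise GPRSyntaxError(f"unexpected token {tok!r}", at)
    return result


def to_string(expr: GPR) -> str:
    """Render an expression back to the standard ``and``/``or`` syntax."""
    if expr is TRUE:
        return ""
    if isinstance(expr, Gene):
        return expr.name
    op = " and " if isinstance(expr, And) else " or "
    parts = []
    for c in expr.children:
        s = to_string(c)
        if isinstance(c, (And, Or)):
            s = f"({s})"
        parts.append(s)
    return op.join(parts)


def genes_in(expr: GPR) -> frozenset:
    """The set of gene names referenced by the rule."""
    if expr is TRUE:
        return frozenset()
    if isinstance(expr, Gene):
        return frozenset({expr.name})
    out = set()
    for c in expr.children:
        out |= genes_in(c)
    return frozenset(out)


def evaluate(expr: GPR, inactive: Iterable[str]) -> bool:
    """Evaluate the rule with the given genes inactive and all others active."""
    inactive = set(inactive)

    def ev(e):
        if e is TRUE:
            return True
        if isinstance(e, Gene):
            return e.name not in inactive
        if isinstance(e, And):
            return all(ev(c) for c in e.children)
        return any(ev(c) for c in e.children)

    return ev(expr)


def _minimize(sets):
    """Drop every set that is a proper superset of another set."""
    out = []
    for s in sorted(sets, key=len):
        if not any(t <= s for t in out):
            out.append(s)
    return out


def minimal_falsifying_sets(expr: GPR, limit: int = 10_000) -> frozenset:
    """Minimal gene sets whose joint loss makes the rule false.

    Computed as the prime implicants of the negated rule by recursive
    expansion: falsifying an AND needs any child falsified (union of the
    children's families), falsifying an OR needs every child falsified
    (cross-product of the families), with superset pruning at each step.
    The exhaustive truth table over all gene subsets is the test oracle.

    Parameters
    ----------
    expr:
        Parsed rule; must not be :data:`TRUE`.
    limit:
        Combinatorial guard — the expansion aborts with
        :class:`GPRComplexityError` once a partial family exceeds this many
        sets, rather than exhausting memory on pathological rules.
    """
    if expr is TRUE:
        raise ValueError("reaction has no gene association")

    def rec(e):
        if isinstance(e, Gene):
            return [frozenset({e.name})]
        if e is TRUE:
            return []  # unfalsifiable branch contributes nothing to an AND
        if isinstance(e, And):
            fam = []
            for c in e.children:
                fam.extend(rec(c))
            fam = _minimize(fam)
            if len(fam) > limit:
                raise GPRComplexityError(
                    f"more than {limit} minimal falsifying sets"
                )
            return fam
        # Or: must falsify every child simultaneously
        fam = [frozenset()]
        for c in e.children:
            child = rec(c)
            if not child:  # an unfalsifiable child makes the OR unfalsifiable
                return []
            fam = _minimize([a | b for a in fam for b in child])
            if len(fam) > limit:
                raise GPRComplexityError(
                    f"more than {limit} minimal falsifying sets"
                )
        return fam

    fam = rec(expr)
    if not fam:
        raise ValueError("reaction has no gene association")
    return frozenset(fam)
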