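"""Boolean expressions over named node literals.

Expressions are built from the three operators AND, OR and NOT, which are
sufficient to express any logical update rule.  The AST is deliberately tiny:
literals, negations and n-ary conjunctions/disjunctions.  ``evaluate`` accepts
either plain 0/1 integers or numpy integer arrays, so a rule can be applied
to a single state vector or, vectorised, to every state of a network at once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping


class Expr:
    """Base class for Boolean expression nodes."""

    __slots__ = ()


@dataclass(frozen=True)
class Lit(Expr):
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr

    def __str__(self) -> str:
        inner = str(self.operand)
        if isinstance(self.operand, (And, Or)):
            inner = f"({inner})"
        return f"NOT {inner}"


@dataclass(frozen=True)
class And(Expr):
    operands: tuple[Expr, ...]

    def __str__(self) -> str:
        return " AND ".join(_paren(o, Or) for o in self.operands)


@dataclass(frozen=True)
class Or(Expr):
    operands: tuple[Expr, ...]

    def __str__(self) -> str:
        return " OR ".join(_paren(o, And) for o in self.operands)


def _paren(child: Expr, *wrap: type) -> str:
    # Parenthesise any nested n-ary operator so the rendered text re-parses
    # unambiguously regardless of precedence conventions.
    if isinstance(child, (And, Or)):
        return f"({child})"
    return str(child)


def lits(*names: str) -> list[Expr]:
    return [Lit(n) for n in names]


def and_(*operands: Expr) -> Expr:
    flat = tuple(operands)
    return flat[0] if len(flat) == 1 else And(flat)


def or_(*operands: Expr) -> Expr:
    flat = tuple(operands)
    return flat[0] if len(flat) == 1 else Or(flat)


def literals(expr: Expr) -> set[str]:
    """The set of node names referenced by ``expr``."""
    out: set[str] = set()
    stack = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, Lit):
            out.add(e.name)
        elif isinstance(e, Not):
            stack.append(e.operand)
        else:
            stack.extend(e.operands)  # type: ignore[union-attr]
    return out


def evaluate(expr: Expr, state: Mapping[str, object]):
    """Evaluate ``expr`` against a mapping node name -> 0/1 (or ndarray)."""
    if isinstance(expr, Lit):
        return state[expr.name]
    if isinstance(expr, Not):
        return 1 - evaluate(expr.operand, state)
    if isinstance(expr, And):
        acc = evaluate(expr.operands[0], state)
        for op in expr.operands[1:]:
            acc = acc & evaluate(op, state)
        return acc
    if isinstance(expr, Or):
        acc = evaluate(expr.operands[0], state)
        for op in expr.operands[1:]:
            acc = acc | evaluate(op, state)
        return acc
    raise TypeError(f"not an expression: {expr!r}")


class ExprError(ValueError):
    """Raised for malformed Boolean expression text."""


_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_/\-.+]+)")
_KEYWORDS = {"AND", "OR", "NOT"}


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ExprError(f"unexpected character {text[pos]!r} in {text!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_expr(text: str) -> Expr:
    """Parse an expression such as ``Sos1E OR ((Vav2 OR Rac1) AND NOT pRacGAP1)``.

    Grammar (NOT binds tightest, then AND, then OR)::

        expr   := term (OR term)*
        term   := factor (AND factor)*
        factor := NOT factor | '(' expr ')' | NAME
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ExprError("empty expression")
    it = _Cursor(tokens, text)
    e = _parse_or(it)
    if it.peek() is not None:
        raise ExprError(f"trailing tokens {it.rest()!r} in {text!r}")
    return e


class _Cursor:
    def __init__(self, tokens: list[str], text: str):
        self.tokens = tokens
        self.i = 0
        self.text = text

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ExprError(f"unexpected end of expression in {self.text!r}")
        self.i += 1
        return tok

    def rest(self) -> str:
        return " ".join(self.tokens[self.i:])


def _parse_or(cur: _Cursor) -> Expr:
    ops = [_parse_and(cur)]
    while cur.peek() == "OR":
        cur.take()
        ops.append(_parse_and(cur))
    return or_(*ops)


def _parse_and(cur: _Cursor) -> Expr:
    ops = [_parse_factor(cur)]
    while cur.peek() == "AND":
        cur.take()
        ops.append(_parse_factor(cur))
    return and_(*ops)


def _parse_factor(cur: _Cursor) -> Expr:
    tok = cur.take()
    if tok == "NOT":
        return Not(_parse_factor(cur))
    if tok == "(":
        e = _parse_or(cur)
        if cur.take() != ")":
            raise ExprError(f"unbalanced parentheses in {cur.text!r}")
        return e
    if tok == ")" or tok in _KEYWORDS:
        raise ExprError(f"unexpected token {tok!r} in {cur.text!r}")
    return Lit(tok)


def iter_subexpressions(expr: Expr) -> Iterator[Expr]:
    stack = [expr]
    while stack:
        e = stack.pop()
        yield e
        if isinstance(e, Not):
            stack.append(e.operand)
        elif isinstance(e, (And, Or)):
            stack.extend(e.operands)
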