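"""Boolean gene-protein-reaction (GPR) rules.

A GPR links a reaction to the genes whose products catalyse it:
``(g1 and g2) or g3`` means the reaction needs either the g1/g2 complex or
the isozyme g3. Knocking out a gene sets its literal to False; a reaction
whose rule evaluates False is disabled.

Grammar: identifiers, ``and``, ``or``, parentheses; keywords are
case-insensitive and ``and`` binds tighter than ``or``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Tuple


class GPRSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class GPRNode:
    """One node of a parsed GPR expression tree.

    ``op`` is "gene", "and" or "or"; leaves carry the gene id in ``gene``,
    inner nodes carry their operands in ``children``.
    """

    op: str
    gene: str = ""
    children: Tuple["GPRNode", ...] = ()

    def evaluate(self, knocked: Iterable[str]) -> bool:
        knocked = set(knocked)
        if self.op == "gene":
            return self.gene not in knocked
        if self.op == "and":
            return all(c.evaluate(knocked) for c in self.children)
        return any(c.evaluate(knocked) for c in self.children)

    @property
    def genes(self) -> FrozenSet[str]:
        if self.op == "gene":
            return frozenset((self.gene,))
        out: set = set()
        for c in self.children:
            out |= c.genes
        return frozenset(out)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            # parenthesise an "or" child under an "and" parent
            if self.op == "and" and c.op == "or":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GPRNode:
    """Parse a GPR rule string into an expression tree.

    ``and`` binds tighter than ``or``; keywords are case-insensitive;
    any other token is a gene identifier.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GPRSyntaxError("empty GPR expression")

    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRNode:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return GPRNode("or", children=tuple(terms))

    def parse_and() -> GPRNode:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        if len(factors) == 1:
            return factors[0]
        return GPRNode("and", children=tuple(factors))

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of GPR in {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRSyntaxError(f"unbalanced parenthesis in {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in {text!r}")
        take()
        return GPRNode("gene", gene=tok)

    node = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens {tokens[pos:]!r} in {text!r}")
    return node
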