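"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule links a reaction to the genes whose products catalyse it:
``OR`` joins isozymes (either enzyme suffices), ``AND`` joins subunits of
a complex (all are required).  When enzyme abundances are attached to the
genes, the effective catalytic abundance of the reaction is evaluated
recursively with OR -> sum (isozyme pools add) and AND -> min (a complex
is limited by its scarcest subunit).

The accepted dialect is the standard one used by genome-scale
reconstructions: gene identifiers, ``and``/``or`` (case-insensitive) and
parentheses.  ``and`` binds tighter than ``or``, so ``a and b or c``
parses as ``(a and b) or c``; curated models parenthesise fully anyway.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = ["GPRRule", "GPRParseError", "parse_gpr"]

#: marker returned when a rule places no kinetic limit on a reaction
UNLIMITED = math.inf

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


class GPRParseError(ValueError):
    """Raised for malformed GPR text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class _Token:
    kind: str  # 'gene' | 'and' | 'or' | '(' | ')'
    text: str
    pos: int


def _tokenize(text: str) -> Iterator[_Token]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tok = m.group(1)
        start = m.start(1)
        low = tok.lower()
        if tok == "(" or tok == ")":
            yield _Token(tok, tok, start)
        elif low == "and" or low == "or":
            yield _Token(low, tok, start)
        else:
            yield _Token("gene", tok, start)
        pos = m.end()


@dataclass(frozen=True)
class GPRRule:
    """Boolean expression tree over gene identifiers.

    ``op`` is ``'gene'`` for a leaf (``children`` empty, ``gene`` set),
    ``'and'``/``'or'`` for internal nodes (>= 2 children), or ``''`` for
    the empty rule, which imposes no constraint.
    """

    op: str = ""
    gene: str = ""
    children: tuple["GPRRule", ...] = field(default_factory=tuple)

    # -- constructors ---------------------------------------------------
    @staticmethod
    def leaf(gene: str) -> "GPRRule":
        return GPRRule(op="gene", gene=gene)

    @staticmethod
    def join(op: str, children: tuple["GPRRule", ...]) -> "GPRRule":
        if len(children) == 1:
            return children[0]
        # flatten nested nodes of the same operator
        flat: list[GPRRule] = []
        for c in children:
            if c.op == op:
                flat.extend(c.children)
            else:
                flat.append(c)
        return GPRRule(op=op, children=tuple(flat))

    # -- predicates -----------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.op == ""

    @property
    def genes(self) -> frozenset[str]:
        if self.is_empty:
            return frozenset()
        if self.op == "gene":
            return frozenset((self.gene,))
        return frozenset().union(*(c.genes for c in self.children))

    # -- serialisation --------------------------------------------------
    def to_string(self) -> str:
        if self.is_empty:
            return ""
        if self.op == "gene":
            return self.gene
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op in ("and", "or") and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()

    def _canonical(self):
        if self.is_empty:
            return ()
        if self.op == "gene":
            return ("gene", self.gene)
        return (self.op, tuple(sorted(c._canonical() for c in self.children)))

    def equivalent(self, other: "GPRRule") -> bool:
        """Structural equivalence up to child order and nesting of
        same-operator nodes (the invariant preserved by round-trips)."""
        return self._canonical() == other._canonical()

    # -- evaluation -----------------------------------------------------
    def effective_abundance(
        self, abundance: Mapping[str, float], missing: float = 0.0
    ) -> float:
        """Effective enzyme abundance of the reaction under this rule.

        OR nodes sum their children (isozymes pool), AND nodes take the
        minimum (complex limited by its scarcest subunit).  Genes absent
        from ``abundance`` contribute ``missing`` (default 0, which is
        conservative under AND and neutral under OR).  The empty rule
        returns ``UNLIMITED``.
        """
        if self.is_empty:
            return UNLIMITED
        if self.op == "gene":
            return float(abundance.get(self.gene, missing))
        vals = (c.effective_abundance(abundance, missing) for c in self.children)
        return sum(vals) if self.op == "or" else min(vals)


def parse_gpr(text: str | None) -> GPRRule:
    """Parse GPR text into a :class:`GPRRule` tree.

    Empty or whitespace-only text yields the empty rule.  Unbalanced
    parentheses or misplaced operators raise :class:`GPRParseError`
    naming the character position.
    """
    if text is None or not text.strip():
        return GPRRule()
    tokens = list(_tokenize(text))
    rule, idx = _parse_or(tokens, 0, text)
    if idx != len(tokens):
        raise GPRParseError(f"unexpected token {tokens[idx].text!r}", tokens[idx].pos)
    return rule


def _parse_or(tokens: list[_Token], idx: int, text: str):
    children = []
    child, idx = _parse_and(tokens, idx, text)
    children.append(child)
    while idx < len(tokens) and tokens[idx].kind == "or":
        child, idx = _parse_and(tokens, idx + 1, text)
        children.append(child)
    return GPRRule.join("or", tuple(children)), idx


def _parse_and(tokens: list[_Token], idx: int, text: str):
    children = []
    child, idx = _parse_atom(tokens, idx, text)
    children.append(child)
    while idx < len(tokens) and tokens[idx].kind == "and":
        child, idx = _parse_atom(tokens, idx + 1, text)
        children.append(child)
    return GPRRule.join("and", tuple(children)), idx


def _parse_atom(tokens: list[_Token], idx: int, text: str):
    if idx >= len(tokens):
        raise GPRParseError("unexpected end of rule", len(text))
    tok = tokens[idx]
    if tok.kind == "(":
        rule, idx = _parse_or(tokens, idx + 1, text)
        if idx >= len(tokens) or tokens[idx].kind != ")":
            raise GPRParseError("unbalanced parenthesis", tok.pos)
        return rule, idx + 1
    if tok.kind == "gene":
        return GPRRule.leaf(tok.text), idx + 1
    raise GPRParseError(f"unexpected token {tok.text!r}", tok.pos)
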