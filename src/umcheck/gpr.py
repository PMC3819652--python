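"""Boolean gene-protein-reaction (GPR) rules.

A GPR rule decides whether a reaction remains catalysable under a set of
gene deletions: an AND node needs all of its children (subunits of a
complex), an OR node any of them (isoenzymes).  Rules are parsed from the
usual ``"(g1 and g2) or g3"`` text form; ``and`` binds tighter than ``or``.
An empty rule means the reaction has no known coding gene (an orphan
reaction) and is unaffected by any knockout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable


class GPRParseError(ValueError):
    """Raised for malformed rule text; carries the token position."""


@dataclass(frozen=True)
class GPRExpression:
    """Boolean tree over gene identifiers.

    ``op`` is ``"gene"`` for leaves (``gene`` holds the identifier) and
    ``"and"`` / ``"or"`` for internal nodes (``children`` non-empty).
    """

    op: str
    gene: str | None = None
    children: tuple["GPRExpression", ...] = field(default_factory=tuple)

    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset([self.gene])
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)

    def evaluate(self, knocked_out: Iterable[str] = ()) -> bool:
        """True when the reaction is still catalysable with the given
        genes deleted (present genes are assumed functional)."""
        knocked = set(knocked_out)
        if self.op == "gene":
            return self.gene not in knocked
        if self.op == "and":
            return all(c.evaluate(knocked) for c in self.children)
        return any(c.evaluate(knocked) for c in self.children)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for child in self.children:
            text = child.to_string()
            if self.op == "and" and child.op == "or":
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]


def parse_gpr(text: str) -> GPRExpression | None:
    """Parse rule text into a :class:`GPRExpression`.

    Returns ``None`` for empty/whitespace text (orphan reaction).
    ``and``/``or`` keywords are case-insensitive; ``&&``/``||`` and
    ``&``/``|`` are accepted as synonyms.  ``and`` binds tighter than
    ``or``; parentheses override.
    """
    tokens = _tokenize(text)
    if not tokens:
        return None
    pos = 0

    def peek() -> tuple[str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> tuple[str, int]:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def kind(tok: str) -> str:
        low = tok.lower()
        if low in ("and", "&", "&&"):
            return "and"
        if low in ("or", "|", "||"):
            return "or"
        if tok in ("(", ")"):
            return tok
        return "gene"

    def parse_or() -> GPRExpression:
        node = parse_and()
        children = [node]
        while (tok := peek()) is not None and kind(tok[0]) == "or":
            advance()
            children.append(parse_and())
        if len(children) == 1:
            return children[0]
        return GPRExpression(op="or", children=tuple(children))

    def parse_and() -> GPRExpression:
        node = parse_atom()
        children = [node]
        while (tok := peek()) is not None and kind(tok[0]) == "and":
            advance()
            children.append(parse_atom())
        if len(children) == 1:
            return children[0]
        return GPRExpression(op="and", children=tuple(children))

    def parse_atom() -> GPRExpression:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR rule: {text!r}")
        word, at = advance()
        k = kind(word)
        if k == "(":
            node = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise GPRParseError(
                    f"unbalanced parenthesis opened at position {at} in {text!r}"
                )
            advance()
            return node
        if k == "gene":
            return GPRExpression(op="gene", gene=word)
        raise GPRParseError(f"unexpected token {word!r} at position {at} in {text!r}")

    node = parse_or()
    if pos != len(tokens):
        word, at = tokens[pos]
        raise GPRParseError(f"unexpected token {word!r} at position {at} in {text!r}")
    return node
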