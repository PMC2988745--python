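"""Gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene locus tags: ``and`` encodes an
enzyme complex (every subunit required), ``or`` encodes isozymes (any one
catalyst suffices).  A reaction with no GPR (``None``) is treated as
spontaneous or orphan and is never disabled by gene deletions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = [
    "Gpr",
    "GprLeaf",
    "GprAnd",
    "GprOr",
    "GprParseError",
    "parse_gpr",
    "evaluate_gpr",
    "gpr_genes",
    "gpr_to_string",
]


class GprParseError(ValueError):
    """Malformed boolean gene-association string; carries token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at token position {position})")
        self.position = position


@dataclass(frozen=True)
class Gpr:
    """Base node of a GPR expression tree."""

    def evaluate(self, deleted: Iterable[str]) -> bool:
        raise NotImplementedError

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def canonical(self) -> str:
        """Order-independent rendering, usable as a deduplication key."""
        raise NotImplementedError


@dataclass(frozen=True)
class GprLeaf(Gpr):
    gene: str

    def evaluate(self, deleted: Iterable[str]) -> bool:
        return self.gene not in set(deleted)

    def genes(self) -> frozenset[str]:
        return frozenset({self.gene})

    def to_string(self) -> str:
        return self.gene

    def canonical(self) -> str:
        return self.gene


def _wrap(child: Gpr) -> str:
    if isinstance(child, GprLeaf):
        return child.to_string()
    return f"({child.to_string()})"


@dataclass(frozen=True)
class GprAnd(Gpr):
    children: tuple[Gpr, ...]

    def evaluate(self, deleted: Iterable[str]) -> bool:
        dead = set(deleted)
        return all(c.evaluate(dead) for c in self.children)

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def to_string(self) -> str:
        return " and ".join(_wrap(c) for c in self.children)

    def canonical(self) -> str:
        return "(" + " and ".join(sorted(c.canonical() for c in self.children)) + ")"


@dataclass(frozen=True)
class GprOr(Gpr):
    children: tuple[Gpr, ...]

    def evaluate(self, deleted: Iterable[str]) -> bool:
        dead = set(deleted)
        return any(c.evaluate(dead) for c in self.children)

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def to_string(self) -> str:
        return " or ".join(_wrap(c) for c in self.children)

    def canonical(self) -> str:
        return "(" + " or ".join(sorted(c.canonical() for c in self.children)) + ")"


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: Optional[str]) -> Optional[Gpr]:
    """Parse a boolean gene-association string into an expression tree.

    Grammar (case-insensitive keywords, ``and`` binds tighter than ``or``)::

        expr   := term ("or" term)*
        term   := factor ("and" factor)*
        factor := "(" expr ")" | GENE

    An empty or whitespace-only string parses to ``None`` (no gene
    requirement).
    """
    if text is None or not text.strip():
        return None
    tokens = _TOKEN.findall(text)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_factor() -> Gpr:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GprParseError("unexpected end of expression", pos)
        if tok == "(":
            take()
            node = parse_expr()
            if peek() != ")":
                raise GprParseError("unbalanced parentheses", pos)
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r}", pos)
        return GprLeaf(take())

    def parse_term() -> Gpr:
        children = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            take()
            children.append(parse_factor())
        return children[0] if len(children) == 1 else GprAnd(tuple(children))

    def parse_expr() -> Gpr:
        children = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            take()
            children.append(parse_term())
        return children[0] if len(children) == 1 else GprOr(tuple(children))

    node = parse_expr()
    if pos != len(tokens):
        raise GprParseError(f"stray token {tokens[pos]!r}", pos)
    return node


def evaluate_gpr(expr: Optional[Gpr], deleted: Iterable[str]) -> bool:
    """True iff the reaction remains catalysed after deleting ``deleted`` genes.

    An empty expression (``None``) always evaluates True: reactions without
    a gene requirement can never be knocked out.
    """
    if expr is None:
        return True
    return expr.evaluate(set(deleted))


def gpr_genes(expr: Optional[Gpr]) -> frozenset[str]:
    """All gene ids referenced by the expression (empty for ``None``)."""
    if expr is None:
        return frozenset()
    return expr.genes()


def gpr_to_string(expr: Optional[Gpr]) -> str:
    """Serialise back to the ``and``/``or`` string dialect ('' for ``None``)."""
    if expr is None:
        return ""
    return expr.to_string()
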