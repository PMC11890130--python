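"""Three-level PubMed boolean query assembly.

The query for one (page, thematic category) pair is built in three levels:

1. *sub-subqueries* — MeSH terms sharing a top-level tree category are
   OR-ed together;
2. *subqueries* — the category sub-subqueries are AND-ed into the MeSH
   subquery; extracted keyphrases are AND-ed into the keyphrase subquery;
3. *final query* — the subqueries are OR-ed.

Queries are represented as explicit trees so that the emitted string can
be re-parsed and checked for structural fidelity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence, Union

from .terms import KeyPhrase, MeshTerm

logger = logging.getLogger(__name__)

MESH_FIELD_TAG = "MeSH Terms"
#: Reserved category letter for terms lacking tree numbers.
MISC_CATEGORY = "X"


@dataclass(frozen=True)
class Term:
    """A leaf: quoted-if-multiword term text plus an optional field tag."""

    text: str
    field_tag: str | None = None

    def emit(self) -> str:
        text = self.text.replace('"', "")  # embedded quotes are stripped
        out = f'"{text}"' if re.search(r"\s", text) else text
        if self.field_tag:
            out += f"[{self.field_tag}]"
        return out


@dataclass(frozen=True)
class Op:
    """An internal node: AND/OR over at least two children."""

    operator: str
    children: tuple["BooleanQuery", ...]

    def __post_init__(self) -> None:
        if self.operator not in ("AND", "OR"):
            raise ValueError(f"unknown operator {self.operator!r}")
        if len(self.children) < 2:
            raise ValueError("Op nodes need >= 2 children")

    def emit(self) -> str:
        parts = []
        for c in self.children:
            s = c.emit()
            if isinstance(c, Op):
                s = f"({s})"
            parts.append(s)
        return f" {self.operator} ".join(parts)


BooleanQuery = Union[Term, Op]

#: Marker for a subquery with no material; dropped at final assembly.
EMPTY_QUERY = None


def query_terms(q: BooleanQuery) -> list[str]:
    """All leaf term texts of a query tree, left to right."""
    if isinstance(q, Term):
        return [q.text]
    out: list[str] = []
    for c in q.children:
        out.extend(query_terms(c))
    return out


def count_operators(q: BooleanQuery) -> dict[str, int]:
    counts = {"AND": 0, "OR": 0}
    if isinstance(q, Op):
        counts[q.operator] += len(q.children) - 1
        for c in q.children:
            sub = count_operators(c)
            counts["AND"] += sub["AND"]
            counts["OR"] += sub["OR"]
    return counts


# ---------------------------------------------------------------------------
# Grouping and subquery construction
# ---------------------------------------------------------------------------


def group_terms_by_category(terms: Sequence[MeshTerm]) -> dict[str, list[MeshTerm]]:
    """Group MeSH terms by the leading letter of their tree numbers.

    A term with tree numbers in k categories appears in all k groups (once
    per group); a term without tree numbers goes to the reserved group
    ``"X"`` with a warning.  Groups are returned in alphabetical order and
    never stored empty.
    """
    groups: dict[str, list[MeshTerm]] = {}
    for term in terms:
        letters = sorted({tn[0] for tn in term.tree_numbers})
        if not letters:
            logger.warning("MeSH term %r has no tree numbers; routed to group %s",
                           term.descriptor, MISC_CATEGORY)
            letters = [MISC_CATEGORY]
        for letter in letters:
            bucket = groups.setdefault(letter, [])
            if all(t.descriptor != term.descriptor for t in bucket):
                bucket.append(term)
    return {k: groups[k] for k in sorted(groups)}


def build_mesh_subquery(groups: dict[str, list[MeshTerm]]) -> BooleanQuery | None:
    """AND over tree categories of (OR over that category's terms).

    Terms carry the ``[MeSH Terms]`` field tag; singleton groups emit the
    bare term.  Empty input yields the empty-subquery marker.
    """
    if not groups:
        return EMPTY_QUERY
    category_nodes: list[BooleanQuery] = []
    for letter in sorted(groups):
        members = groups[letter]
        if not members:
            continue
        leaves = [Term(t.descriptor, MESH_FIELD_TAG) for t in members]
        category_nodes.append(leaves[0] if len(leaves) == 1 else Op("OR", tuple(leaves)))
    if not category_nodes:
        return EMPTY_QUERY
    if len(category_nodes) == 1:
        return category_nodes[0]
    return Op("AND", tuple(category_nodes))


def build_keyphrase_subquery(phrases: Sequence[KeyPhrase | str]) -> BooleanQuery | None:
    """AND over keyphrases, untagged (all-fields search)."""
    texts = [p.phrase if isinstance(p, KeyPhrase) else p for p in phrases]
    if not texts:
        return EMPTY_QUERY
    leaves = [Term(t) for t in texts]
    if len(leaves) == 1:
        return leaves[0]
    return Op("AND", tuple(leaves))


def build_final_query(subqueries: Sequence[BooleanQuery | None]) -> str:
    """OR the non-empty subqueries into the final PubMed query string."""
    active = [q for q in subqueries if q is not EMPTY_QUERY]
    if not active:
        raise ValueError("no non-empty subqueries: the category had no extractable terms")
    if len(active) == 1:
        return active[0].emit()
    parts = []
    for q in active:
        s = q.emit()
        parts.append(f"({s})" if isinstance(q, Op) else s)
    return " OR ".join(parts)


# ---------------------------------------------------------------------------
# Round-trip parser
# ---------------------------------------------------------------------------

_TOKEN_SPEC = [
    ("LPAREN", r"\("),
    ("RPAREN", r"\)"),
    ("QUOTED", r'"[^"]*"'),
    ("FIELD", r"\[[^\]]+\]"),
    ("WORD", r"[^\s()\[\]\"]+"),
    ("WS", r"\s+"),
]
_TOKEN_RE = re.compile("|".join(f"(?P<{n}>{p})" for n, p in _TOKEN_SPEC))


class QueryParseError(ValueError):
    pass


def _lex(s: str) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if not m:
            raise QueryParseError(f"cannot tokenize query at offset {pos}: {s[pos:pos+20]!r}")
        pos = m.end()
        if m.lastgroup != "WS":
            tokens.append((m.lastgroup, m.group()))
    return tokens


class _Parser:
    """Recursive-descent parser for the emitted query grammar.

    expr := conj (OR conj)* ; conj := atom (AND atom)* ;
    atom := '(' expr ')' | term [field] ; term := quoted | word+ .
    OR binds loosest, matching how the builder parenthesizes.
    """

    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise QueryParseError("unexpected end of query")
        self.i += 1
        return tok

    def parse(self) -> BooleanQuery:
        node = self.expr()
        if self.peek() is not None:
            raise QueryParseError(f"trailing tokens at {self.i}: {self.peek()!r}")
        return node

    def expr(self) -> BooleanQuery:
        children = [self.conj()]
        while self.peek() == ("WORD", "OR"):
            self.next()
            children.append(self.conj())
        return children[0] if len(children) == 1 else Op("OR", tuple(children))

    def conj(self) -> BooleanQuery:
        children = [self.atom()]
        while self.peek() == ("WORD", "AND"):
            self.next()
            children.append(self.atom())
        return children[0] if len(children) == 1 else Op("AND", tuple(children))

    def atom(self) -> BooleanQuery:
        kind, value = self.next()
        if kind == "LPAREN":
            node = self.expr()
            if self.next()[0] != "RPAREN":
                raise QueryParseError("unbalanced parentheses")
            return node
        if kind == "QUOTED":
            text = value[1:-1]
        elif kind == "WORD":
            if value in ("AND", "OR"):
                raise QueryParseError(f"operator {value} in term position")
            words = [value]
            while (tok := self.peek()) and tok[0] == "WORD" and tok[1] not in ("AND", "OR"):
                words.append(self.next()[1])
            text = " ".join(words)
        else:
            raise QueryParseError(f"unexpected token {value!r}")
        field = None
        if (tok := self.peek()) and tok[0] == "FIELD":
            field = self.next()[1][1:-1]
        return Term(text, field)


def parse_query(query: str) -> BooleanQuery:
    """Parse an emitted query string back into its tree."""
    if not query.strip():
        raise QueryParseError("empty query string")
    return _Parser(_lex(query)).parse()
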