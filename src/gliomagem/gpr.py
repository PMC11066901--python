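"""Gene-protein-reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers, e.g.
``(g1 and g2) or g3``: AND encodes complex-subunit requirements, OR
encodes isozymes.  Rules decide whether a reaction survives a gene
knockout and, in ternary form, whether expression evidence marks a
reaction active, inactive or unknown.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Union

__all__ = ["GprRule", "GprParseError"]


class GprParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or"}


@dataclass(frozen=True)
class _Node:
    op: str  # "and" | "or"
    children: tuple  # of _Node | str (gene leaf)


_Tree = Union[_Node, str, None]


class GprRule:
    """A parsed GPR boolean tree.

    Leaves are gene ids; internal nodes are AND/OR.  The empty rule
    (no gene requirement) is represented by ``GprRule("")`` and always
    evaluates active — a reaction without gene annotation is never
    disabled by a deletion.
    """

    __slots__ = ("_tree", "_genes")

    def __init__(self, text: str = ""):
        self._tree = _parse(text)
        self._genes = frozenset(_leaves(self._tree))

    @property
    def genes(self) -> frozenset:
        return self._genes

    @property
    def is_empty(self) -> bool:
        return self._tree is None

    def evaluate(self, deleted: Iterable[str] = ()) -> bool:
        """True iff the reaction stays active after deleting ``deleted``."""
        deleted = set(deleted)
        return _eval_bool(self._tree, deleted)

    def score(self, calls: dict) -> int:
        """Ternary activity score: AND -> min, OR -> max over {-1, 0, +1}.

        ``calls`` maps gene id to a ternary expression call; missing
        genes count as unknown (0).  An empty rule scores 0 (unknown).
        """
        return _eval_ternary(self._tree, calls)

    def to_string(self) -> str:
        return _unparse(self._tree)

    def __str__(self) -> str:
        return self.to_string()

    def __repr__(self) -> str:
        return f"GprRule({self.to_string()!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, GprRule) and self._tree == other._tree

    def __hash__(self) -> int:
        return hash(self._tree)


def _parse(text: str) -> _Tree:
    if text is None:
        return None
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def _node(op: str, children: list) -> _Tree:
        if len(children) == 1:
            return children[0]
        # flatten nested same-operator nodes so logically identical
        # nestings share one canonical tree (round-trip stability)
        flat = []
        for child in children:
            if isinstance(child, _Node) and child.op == op:
                flat.extend(child.children)
            else:
                flat.append(child)
        return _Node(op, tuple(flat))

    def parse_or() -> _Tree:
        children = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            children.append(parse_and())
        return _node("or", children)

    def parse_and() -> _Tree:
        children = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            children.append(parse_atom())
        return _node("and", children)

    def parse_atom() -> _Tree:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR rule: {text!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise GprParseError(f"unbalanced parentheses in GPR rule: {text!r}")
            take()
            return inner
        if tok == ")":
            raise GprParseError(f"unexpected ')' in GPR rule: {text!r}")
        if tok.lower() in _KEYWORDS:
            raise GprParseError(f"misplaced operator {tok!r} in GPR rule: {text!r}")
        return take()

    tree = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR rule: {text!r}")
    return tree


def _leaves(tree: _Tree):
    if tree is None:
        return
    if isinstance(tree, str):
        yield tree
        return
    for child in tree.children:
        yield from _leaves(child)


def _eval_bool(tree: _Tree, deleted: set) -> bool:
    if tree is None:
        return True
    if isinstance(tree, str):
        return tree not in deleted
    if tree.op == "and":
        return all(_eval_bool(c, deleted) for c in tree.children)
    return any(_eval_bool(c, deleted) for c in tree.children)


def _eval_ternary(tree: _Tree, calls: dict) -> int:
    if tree is None:
        return 0
    if isinstance(tree, str):
        return int(calls.get(tree, 0))
    vals = [_eval_ternary(c, calls) for c in tree.children]
    return min(vals) if tree.op == "and" else max(vals)


def _unparse(tree: _Tree, parent_op: str | None = None) -> str:
    if tree is None:
        return ""
    if isinstance(tree, str):
        return tree
    sep = f" {tree.op} "
    body = sep.join(_unparse(c, tree.op) for c in tree.children)
    # parenthesize AND under OR is unnecessary, but OR under AND is required;
    # keep explicit parens whenever precedence differs for faithful round-trips
    if parent_op is not None and parent_op != tree.op:
        return f"({body})"
    return body
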