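"""Gene–protein–reaction (GPR) boolean rules.

A GPR rule states which gene products enable a reaction: ``and`` encodes an
enzyme complex (all subunits required), ``or`` encodes isozymes (any one
suffices). When a rule is evaluated over per-gene activity scores, ``and``
collapses to the minimum child score (the limiting subunit) and ``or`` to the
maximum (the most active isozyme). The gene whose score survives the collapse
is the reaction's *main determinant* and its score becomes the reaction
activity level (RAL).

Grammar
-------
operands   : gene tokens (alphanumerics plus ``. _ : -``)
operators  : ``and`` / ``or``, case-insensitive; ``or`` binds looser
parentheses group; associative chains are flattened into one n-ary node.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import GPRSyntaxError

__all__ = [
    "GeneRef",
    "AndNode",
    "OrNode",
    "GPRRule",
    "RuleEvaluation",
    "parse_gpr",
    "evaluate",
    "genes_in",
]


# ---------------------------------------------------------------------------
# Expression tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRef:
    gene: str


@dataclass(frozen=True)
class AndNode:
    children: tuple


@dataclass(frozen=True)
class OrNode:
    children: tuple


def _make_node(cls, children):
    """Build an n-ary node, flattening same-type children and collapsing
    single-child chains."""
    flat = []
    for c in children:
        if isinstance(c, cls):
            flat.extend(c.children)
        else:
            flat.append(c)
    if len(flat) == 1:
        return flat[0]
    return cls(tuple(flat))


@dataclass(frozen=True)
class GPRRule:
    """A parsed rule. ``root is None`` encodes the empty rule (a reaction
    that carries no gene association)."""

    root: object  # GeneRef | AndNode | OrNode | None
    source_text: str = ""

    @property
    def is_empty(self) -> bool:
        return self.root is None


@dataclass(frozen=True)
class RuleEvaluation:
    value: float
    determinant: str


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

_GENE_CHARS = r"[A-Za-z0-9_.:\-]+"
_TOKEN_RE = re.compile(rf"\(|\)|{_GENE_CHARS}")


def _tokenize(text: str):
    tokens = []
    pos = 0
    n = len(text)
    while pos < n:
        ch = text[pos]
        if ch.isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise GPRSyntaxError(f"unexpected character {ch!r} at position {pos}")
        tok = m.group()
        low = tok.lower()
        if tok == "(":
            kind = "lpar"
        elif tok == ")":
            kind = "rpar"
        elif low == "and":
            kind = "and"
        elif low == "or":
            kind = "or"
        else:
            kind = "gene"
        tokens.append((kind, tok, pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _fail(self, msg: str):
        tok = self._peek()
        where = f"position {tok[2]}" if tok else "end of rule"
        raise GPRSyntaxError(f"{msg} at {where} in rule {self.text!r}")

    def parse(self):
        node = self._or_expr()
        if self._peek() is not None:
            self._fail(f"unexpected token {self._peek()[1]!r}")
        return node

    def _or_expr(self):
        children = [self._and_expr()]
        while self._peek() and self._peek()[0] == "or":
            self.i += 1
            children.append(self._and_expr())
        return _make_node(OrNode, children)

    def _and_expr(self):
        children = [self._atom()]
        while self._peek() and self._peek()[0] == "and":
            self.i += 1
            children.append(self._atom())
        return _make_node(AndNode, children)

    def _atom(self):
        tok = self._peek()
        if tok is None:
            self._fail("expected gene or '('")
        kind, value, pos = tok
        if kind == "gene":
            self.i += 1
            return GeneRef(value)
        if kind == "lpar":
            self.i += 1
            node = self._or_expr()
            closing = self._peek()
            if closing is None or closing[0] != "rpar":
                raise GPRSyntaxError(
                    f"unbalanced parenthesis opened at position {pos} in rule {self.text!r}"
                )
            self.i += 1
            return node
        self._fail(f"unexpected token {value!r}")


def parse_gpr(text: str) -> GPRRule:
    """Parse rule text into a :class:`GPRRule`.

    Blank text yields the empty rule. Malformed text (unbalanced parentheses,
    adjacent or trailing operators) raises :class:`GPRSyntaxError` with the
    offending position.
    """
    if text is None or not text.strip():
        return GPRRule(root=None, source_text=text or "")
    return GPRRule(root=_Parser(text).parse(), source_text=text)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _eval_node(node, scores, missing_policy):
    if isinstance(node, GeneRef):
        if node.gene in scores:
            return RuleEvaluation(float(scores[node.gene]), node.gene)
        if missing_policy == "zero":
            return RuleEvaluation(0.0, node.gene)
        return None  # drop: subtree has no scored gene
    results = []
    for child in node.children:
        r = _eval_node(child, scores, missing_policy)
        if r is not None:
            results.append(r)
    if not results:
        return None
    if isinstance(node, AndNode):
        target = min(r.value for r in results)
    else:
        target = max(r.value for r in results)
    # tie-break: lexicographically smallest determinant gene id
    return min((r for r in results if r.value == target), key=lambda r: r.determinant)


def evaluate(rule: GPRRule, scores, missing_policy: str = "drop"):
    """Evaluate ``rule`` over a gene-id → score mapping.

    ``and`` = min of children, ``or`` = max; the determinant is inherited
    from the selected child, ties broken by lexicographically smallest gene
    id. Under ``missing_policy="drop"`` subtrees with no scored gene are
    removed before evaluation; under ``"zero"`` missing genes score 0.

    Returns a :class:`RuleEvaluation`, or ``None`` when the rule is empty or
    (under drop) no gene in the rule is scored — an undefined, not an error.
    """
    if missing_policy not in ("drop", "zero"):
        raise ValueError(f"missing_policy must be 'drop' or 'zero', got {missing_policy!r}")
    if rule.is_empty:
        return None
    return _eval_node(rule.root, scores, missing_policy)


def genes_in(rule: GPRRule) -> set:
    """Exact set of gene ids referenced by the rule's leaves."""
    out: set = set()

    def walk(node):
        if node is None:
            return
        if isinstance(node, GeneRef):
            out.add(node.gene)
        else:
            for c in node.children:
                walk(c)

    walk(rule.root)
    return out
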