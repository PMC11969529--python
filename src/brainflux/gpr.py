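"""Gene-protein-reaction (GPR) rules: parsing and evidence evaluation.

A GPR is a boolean expression over gene identifiers, e.g.
``"(G0001 and G0002) or G0003"``.  AND nodes model enzyme complexes (all
subunits required), OR nodes model isozymes (any one suffices).  When a GPR
is evaluated against continuous gene evidence (mean TPM), AND maps to ``min``
over children and OR to ``max`` — the standard convention for
complex/isozyme semantics.

An *empty* GPR (spontaneous or transport reaction) evaluates to the sentinel
:data:`NO_EVIDENCE` (``None``), which is distinct from a score of 0: a
reaction without genes carries no evidence for or against its activity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

__all__ = [
    "GPRParseError",
    "GPRScore",
    "NO_EVIDENCE",
    "gpr_genes",
    "parse_gpr",
    "evaluate_gpr",
]

NO_EVIDENCE = None

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


class GPRParseError(ValueError):
    """Raised when a GPR string is not a well-formed and/or expression."""


# AST: either a gene id (str) or (op, [children]) with op in {"and", "or"}
GPRNode = Union[str, tuple]


@dataclass
class GPRScore:
    """Gene-level evidence used to score reactions through their GPRs.

    ``gene_scores`` maps gene id -> nonnegative evidence (e.g. mean TPM).
    Genes absent from the map score ``missing_value`` (default 0), i.e.
    absence of measurement is treated as absence of expression.
    """

    gene_scores: Mapping[str, float]
    missing_value: float = 0.0

    def __post_init__(self) -> None:
        for g, s in self.gene_scores.items():
            if not (s >= 0) or s != s or s == float("inf"):
                raise ValueError(f"gene score for {g!r} must be finite and >= 0, got {s!r}")

    def get(self, gene: str) -> float:
        return float(self.gene_scores.get(gene, self.missing_value))


def _tokenize(expr: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            rest = expr[pos:].strip()
            if not rest:
                break
            raise GPRParseError(f"unexpected character in GPR at position {pos}: {rest[:10]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_gpr(expr: str) -> Optional[GPRNode]:
    """Parse a GPR string into an AST; empty/blank input parses to None.

    Grammar (lowest to highest precedence)::

        or_expr  := and_expr ("or" and_expr)*
        and_expr := atom ("and" atom)*
        atom     := GENE | "(" or_expr ")"
    """
    if expr is None or not expr.strip():
        return None
    tokens = _tokenize(expr)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRNode:
        children = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            children.append(parse_and())
        return children[0] if len(children) == 1 else ("or", children)

    def parse_and() -> GPRNode:
        children = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            children.append(parse_atom())
        return children[0] if len(children) == 1 else ("and", children)

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR: {expr!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in GPR: {expr!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR: {expr!r}")
        return take()

    tree = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR: {expr!r}")
    return tree


def gpr_genes(expr: str) -> frozenset[str]:
    """Return the set of gene ids appearing in a GPR string."""
    tree = parse_gpr(expr)
    if tree is None:
        return frozenset()
    out: set[str] = set()

    def walk(node: GPRNode) -> None:
        if isinstance(node, str):
            out.add(node)
        else:
            for child in node[1]:
                walk(child)

    walk(tree)
    return frozenset(out)


def evaluate_gpr(expr: str, scores: GPRScore) -> Optional[float]:
    """Score a reaction's GPR against gene evidence.

    AND nodes return the min of their children, OR nodes the max.  An empty
    GPR returns :data:`NO_EVIDENCE` (None).
    """
    tree = parse_gpr(expr)
    if tree is None:
        return NO_EVIDENCE

    def walk(node: GPRNode) -> float:
        if isinstance(node, str):
            return scores.get(node)
        op, children = node
        vals = [walk(c) for c in children]
        return min(vals) if op == "and" else max(vals)

    return walk(tree)
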