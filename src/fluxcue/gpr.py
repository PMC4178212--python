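"""Gene–protein–reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers with ``and`` /
``or`` connectives: ``and`` encodes an enzyme complex (every subunit
required), ``or`` encodes isozymes (any one suffices).  The grammar is

    expr    := term  ( "or"  term )*
    term    := factor ( "and" factor )*
    factor  := GENE | "(" expr ")"

with case-insensitive keywords.  Over trinary expression states
(+1 high / 0 moderate / -1 low) the rules are evaluated with
``and`` = min and ``or`` = max, the standard complex/isozyme semantics:
a complex is only as available as its scarcest subunit, while isozymes
are as available as the most abundant one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["Gpr", "GprParseError", "parse_gpr", "gpr_to_string", "evaluate_gpr"]


class GprParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class Gpr:
    """A node of a GPR expression tree.

    ``op`` is ``"gene"`` (leaf, ``gene`` holds the identifier), ``"and"``
    or ``"or"`` (internal, ``children`` hold the operands).
    """

    op: str
    gene: str | None = None
    children: tuple["Gpr", ...] = field(default_factory=tuple)

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_gpr(text: str | None) -> Gpr | None:
    """Parse a GPR string into an expression tree; ``None``/blank -> ``None``."""
    if text is None or not text.strip():
        return None
    tokens = _tokenize(text)
    expr, rest = _parse_or(tokens)
    if rest:
        raise GprParseError(f"trailing tokens in GPR {text!r}: {rest}")
    return expr


def _parse_or(tokens: list[str]) -> tuple[Gpr, list[str]]:
    node, tokens = _parse_and(tokens)
    children = [node]
    while tokens and tokens[0].lower() == "or":
        node, tokens = _parse_and(tokens[1:])
        children.append(node)
    if len(children) == 1:
        return children[0], tokens
    return Gpr("or", children=tuple(children)), tokens


def _parse_and(tokens: list[str]) -> tuple[Gpr, list[str]]:
    node, tokens = _parse_factor(tokens)
    children = [node]
    while tokens and tokens[0].lower() == "and":
        node, tokens = _parse_factor(tokens[1:])
        children.append(node)
    if len(children) == 1:
        return children[0], tokens
    return Gpr("and", children=tuple(children)), tokens


def _parse_factor(tokens: list[str]) -> tuple[Gpr, list[str]]:
    if not tokens:
        raise GprParseError("unexpected end of GPR expression")
    tok = tokens[0]
    if tok == "(":
        node, rest = _parse_or(tokens[1:])
        if not rest or rest[0] != ")":
            raise GprParseError("unbalanced parentheses in GPR expression")
        return node, rest[1:]
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GprParseError(f"unexpected token {tok!r} in GPR expression")
    return Gpr("gene", gene=tok), tokens[1:]


def gpr_to_string(gpr: Gpr | None) -> str:
    """Serialize a GPR tree back to its string form (re-parses to an equal tree)."""
    if gpr is None:
        return ""
    if gpr.op == "gene":
        return gpr.gene  # type: ignore[return-value]
    sep = f" {gpr.op} "
    parts = []
    for child in gpr.children:
        text = gpr_to_string(child)
        if child.op != "gene" and child.op != gpr.op:
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)


def evaluate_gpr(gpr: Gpr | None, gene_states: Mapping[str, int], missing: int = 0) -> int:
    """Evaluate a GPR over trinary gene states (and=min, or=max).

    Genes absent from ``gene_states`` evaluate to ``missing`` (default 0:
    absence of evidence is not a cue).  An empty rule evaluates to 0.
    """
    if gpr is None:
        return 0
    if gpr.op == "gene":
        return int(gene_states.get(gpr.gene, missing))
    values = [evaluate_gpr(c, gene_states, missing) for c in gpr.children]
    return min(values) if gpr.op == "and" else max(values)
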