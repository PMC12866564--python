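"""KEGG-module-style pathway definitions and completeness scoring.

A definition is a boolean expression over KO identifiers in the KEGG
module convention: space separates required steps (AND, lowest
precedence), comma separates alternatives (OR, binds tighter), ``+``
joins subunits of a complex (AND, binds tightest), parentheses group,
and a leading ``-`` marks the following unit optional (pruned before
scoring).

Completeness of a KO set against a definition is scored recursively:
a leaf is 1 if its KO is present else 0, an AND node is the arithmetic
mean of its children (fraction of required steps satisfied), an OR node
is the maximum over its alternatives. The score is reported in percent.
This mean/max semantics preserves the ordering of "more complete"
comparisons; graph-weighted variants of external tools are deliberately
not reproduced.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .io_formats import MetadataTable

_KO_RE = re.compile(r"K\d{5}")


class PathwayParseError(ValueError):
    pass


@dataclass
class Node:
    kind: str  # "leaf" | "and" | "or"
    children: list["Node"] = field(default_factory=list)
    ko: str | None = None
    optional: bool = False
    #: AND node built from a '+' complex (affects unparsing only)
    complex: bool = False

    def __eq__(self, other) -> bool:
        if not isinstance(other, Node):
            return NotImplemented
        return (self.kind, self.ko, self.optional, self.complex,
                self.children) == (other.kind, other.ko, other.optional,
                                   other.complex, other.children)


@dataclass
class PathwayDefinition:
    pathway_id: str
    name: str
    root: Node


class _Tokenizer:
    """Tokens: KO, '(', ')', ',', '+', '-', SPACE (runs collapsed)."""

    def __init__(self, text: str):
        self.tokens: list[tuple[str, str, int]] = []
        i, n = 0, len(text)
        while i < n:
            ch = text[i]
            if ch.isspace():
                j = i
                while j < n and text[j].isspace():
                    j += 1
                self.tokens.append(("SPACE", " ", i))
                i = j
            elif ch in "(),+-":
                self.tokens.append((ch, ch, i))
                i += 1
            else:
                m = _KO_RE.match(text, i)
                if not m:
                    raise PathwayParseError(
                        f"malformed token at position {i}: {text[i:i+8]!r}"
                    )
                self.tokens.append(("KO", m.group(0), i))
                i = m.end()
        # strip leading/trailing space tokens
        while self.tokens and self.tokens[0][0] == "SPACE":
            self.tokens.pop(0)
        while self.tokens and self.tokens[-1][0] == "SPACE":
            self.tokens.pop()
        self.pos = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise PathwayParseError("unexpected end of definition")
        self.pos += 1
        return tok


def parse_definition(text: str, pathway_id: str = "", name: str = "") -> PathwayDefinition:
    """Parse a definition string into an expression tree.

    Grammar (loosest to tightest): space = AND, comma = OR, ``+`` = AND
    within a complex; parentheses group; leading ``-`` marks optional.
    """
    if not text or not text.strip():
        raise PathwayParseError("empty definition")
    if text.count("(") != text.count(")"):
        raise PathwayParseError("unbalanced parentheses")
    tok = _Tokenizer(text)
    root = _parse_expr(tok)
    leftover = tok.peek()
    if leftover is not None:
        raise PathwayParseError(
            f"unexpected {leftover[1]!r} at position {leftover[2]}"
        )
    return PathwayDefinition(pathway_id=pathway_id, name=name, root=root)


def _parse_expr(tok: _Tokenizer) -> Node:
    terms = [_parse_term(tok)]
    while (t := tok.peek()) is not None and t[0] == "SPACE":
        tok.next()
        terms.append(_parse_term(tok))
    return terms[0] if len(terms) == 1 else Node("and", terms)


def _parse_term(tok: _Tokenizer) -> Node:
    factors = [_parse_factor(tok)]
    while (t := tok.peek()) is not None and t[0] == ",":
        tok.next()
        factors.append(_parse_factor(tok))
    return factors[0] if len(factors) == 1 else Node("or", factors)


def _parse_factor(tok: _Tokenizer) -> Node:
    units = [_parse_unit(tok)]
    while (t := tok.peek()) is not None and t[0] == "+":
        tok.next()
        units.append(_parse_unit(tok))
    return units[0] if len(units) == 1 else Node("and", units, complex=True)


def _parse_unit(tok: _Tokenizer) -> Node:
    t = tok.next()
    optional = False
    if t[0] == "-":
        optional = True
        t = tok.next()
    if t[0] == "(":
        node = _parse_expr(tok)
        closing = tok.next()
        if closing[0] != ")":
            raise PathwayParseError(
                f"expected ')' at position {closing[2]}, found {closing[1]!r}"
            )
    elif t[0] == "KO":
        node = Node("leaf", ko=t[1])
    else:
        raise PathwayParseError(f"unexpected {t[1]!r} at position {t[2]}")
    node.optional = optional
    return node


def unparse(node: Node) -> str:
    """Render a tree back to definition syntax; reparses identically."""
    prefix = "-" if node.optional else ""
    if node.kind == "leaf":
        return prefix + node.ko
    if node.kind == "and" and node.complex:
        parts = [_wrap(c, need_parens=c.kind in ("and", "or") and not
                 (c.kind == "and" and c.complex)) for c in node.children]
        body = "+".join(parts)
    elif node.kind == "and":
        parts = [_wrap(c, need_parens=(c.kind == "and" and not c.complex))
                 for c in node.children]
        body = " ".join(parts)
    else:  # or
        parts = [_wrap(c, need_parens=(c.kind == "and" and not c.complex) or
                       c.kind == "or") for c in node.children]
        body = ",".join(parts)
    if prefix:
        return prefix + "(" + body + ")"
    return body


def _wrap(node: Node, need_parens: bool) -> str:
    text = unparse(node)
    if need_parens and not node.optional:
        return "(" + text + ")"
    return text


def prune_optional(node: Node) -> Node | None:
    """Copy of the tree with optional subtrees removed; None when the
    whole tree is optional."""
    if node.optional:
        return None
    if node.kind == "leaf":
        return Node("leaf", ko=node.ko)
    kept = [p for c in node.children if (p := prune_optional(c)) is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return Node(node.kind, kept, complex=node.complex)


def completeness(definition: PathwayDefinition, kos: set[str]) -> float:
    """Completeness of a KO set against a definition, in percent.

    Returns NaN for an all-optional definition (undefined score).
    """
    pruned = prune_optional(definition.root)
    if pruned is None:
        return math.nan
    return 100.0 * _score(pruned, kos)


def _score(node: Node, kos: set[str]) -> float:
    if node.kind == "leaf":
        return 1.0 if node.ko in kos else 0.0
    scores = [_score(c, kos) for c in node.children]
    return float(np.mean(scores)) if node.kind == "and" else max(scores)


def isolate_ko_sets(ann: pd.DataFrame,
                    restrict_to: set[str] | None = None) -> dict[str, set[str]]:
    """Per-isolate KO set: union over its genes, deduplicated.

    ``restrict_to`` keeps only genes whose orthogroup is in the given
    set (e.g. a partition category).
    """
    sub = ann
    if restrict_to is not None:
        sub = ann[ann["orthogroup_id"].isin(restrict_to)]
    out: dict[str, set[str]] = {}
    for isolate, block in sub.groupby("isolate_id"):
        merged: set[str] = set()
        for s in block["kos"]:
            merged |= s
        out[str(isolate)] = merged
    return out


def completeness_matrix(definitions: list[PathwayDefinition], ann: pd.DataFrame,
                        isolates: list[str] | None = None,
                        restrict_to: set[str] | None = None) -> pd.DataFrame:
    """Isolates x pathways completeness percentages."""
    ko_sets = isolate_ko_sets(ann, restrict_to=restrict_to)
    if isolates is None:
        isolates = sorted(ko_sets)
    data = {
        d.pathway_id: [completeness(d, ko_sets.get(i, set())) for i in isolates]
        for d in definitions
    }
    return pd.DataFrame(data, index=pd.Index(isolates, name="isolate_id"))


def compare_completeness_by_source(cm: pd.DataFrame, metadata: MetadataTable,
                                   target_source: str = "leaf",
                                   alpha: float = 0.05,
                                   mwu_mode: str = "auto") -> pd.DataFrame:
    """Per-pathway completeness comparison: target source vs each other
    source, Bonferroni across all pathway x pair tests."""
    sources = metadata.table["source"].reindex(cm.index)
    target_ids = cm.index[sources == target_source]
    if len(target_ids) < 2:
        raise ValueError(f"need >=2 isolates of source {target_source!r}")
    others = [s for s in dict.fromkeys(sources.dropna()) if s != target_source]
    rows = []
    for pathway in cm.columns:
        values = cm[pathway]
        if values.isna().all():
            continue
        target_vals = values[target_ids].dropna().to_numpy()
        for source in others:
            other_vals = values[sources == source].dropna().to_numpy()
            if len(other_vals) < 2 or len(target_vals) < 2:
                continue
            res = stats.mann_whitney_u(target_vals, other_vals, mode=mwu_mode)
            rows.append({
                "pathway_id": pathway, "source": source,
                "mean_target": float(target_vals.mean()),
                "mean_other": float(other_vals.mean()),
                "U": res.statistic, "p": res.p_value,
            })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = stats.bonferroni_adjust(table["p"].to_numpy())
        table["significant"] = table["p_adj"] < alpha
    return table
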