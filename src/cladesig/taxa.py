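"""Taxa, taxonomy maps and named-clade set algebra.

A :class:`TaxonomyMap` links sequence identifiers to taxa (with free-form
group tags used by exception whitelists), and a :class:`CladeDefinitionSet`
stores named clades as explicit, possibly nested/overlapping taxon sets.
Clade targets are written as :class:`CladeExpression` trees over clade
names with UNION (``+``), DIFFERENCE (``-``) and the special atom ``ALL``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class TaxonomyError(ValueError):
    pass


class CladeError(ValueError):
    pass


@dataclass(frozen=True)
class Taxon:
    id: str
    display_name: str = ""
    group_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise TaxonomyError("taxon id must be non-empty")


class TaxonomyMap:
    """seq_id -> taxon mapping plus the taxon registry itself."""

    def __init__(self) -> None:
        self.taxa: dict[str, Taxon] = {}
        self.seq_to_taxon: dict[str, str] = {}

    def add_taxon(self, taxon: Taxon) -> None:
        if taxon.id in self.taxa:
            raise TaxonomyError(f"duplicate taxon id {taxon.id!r}")
        self.taxa[taxon.id] = taxon

    def add_sequence(self, seq_id: str, taxon_id: str) -> None:
        if taxon_id not in self.taxa:
            self.add_taxon(Taxon(taxon_id))
        self.seq_to_taxon[seq_id] = taxon_id

    def taxon_of(self, seq_id: str) -> Taxon | None:
        tid = self.seq_to_taxon.get(seq_id)
        return self.taxa.get(tid) if tid is not None else None

    def all_taxon_ids(self) -> set[str]:
        return set(self.taxa)

    @classmethod
    def from_tsv(cls, path: str) -> "TaxonomyMap":
        """Read `seq_id<TAB>taxon_id<TAB>group_tags(comma-sep)` rows.

        The third column is optional; blank and ``#`` comment lines skipped.
        """
        tm = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise TaxonomyError(
                        f"{path}:{lineno}: expected at least 2 tab-separated columns")
                seq_id, taxon_id = parts[0], parts[1]
                tags = frozenset(t for t in parts[2].split(",") if t) \
                    if len(parts) > 2 and parts[2] else frozenset()
                if taxon_id not in tm.taxa:
                    tm.add_taxon(Taxon(taxon_id, group_tags=tags))
                tm.seq_to_taxon[seq_id] = taxon_id
        return tm

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for seq_id in sorted(self.seq_to_taxon):
                tid = self.seq_to_taxon[seq_id]
                tags = ",".join(sorted(self.taxa[tid].group_tags))
                fh.write(f"{seq_id}\t{tid}\t{tags}\n")


class CladeDefinitionSet:
    """Named clades as explicit taxon-id sets; sets may nest/overlap."""

    def __init__(self, clades: dict[str, set[str]] | None = None,
                 universe: set[str] | None = None):
        self.clades: dict[str, set[str]] = {k: set(v) for k, v in (clades or {}).items()}
        self._universe = set(universe) if universe is not None else None

    def define(self, name: str, taxa: set[str]) -> None:
        self.clades[name] = set(taxa)

    def members(self, name: str) -> set[str]:
        try:
            return set(self.clades[name])
        except KeyError:
            raise CladeError(f"undefined clade name {name!r}") from None

    @property
    def universe(self) -> set[str]:
        if self._universe is not None:
            return set(self._universe)
        out: set[str] = set()
        for s in self.clades.values():
            out |= s
        return out

    def validate(self, known_taxa: set[str]) -> None:
        for name, members in self.clades.items():
            missing = members - known_taxa
            if missing:
                raise CladeError(
                    f"clade {name!r} references unknown taxa: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path: str, universe: set[str] | None = None) -> "CladeDefinitionSet":
        """Read `clade_name<TAB>taxon_id` rows."""
        defs = cls(universe=universe)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise CladeError(f"{path}:{lineno}: expected 2 columns")
                defs.clades.setdefault(parts[0], set()).add(parts[1])
        return defs

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.clades):
                for t in sorted(self.clades[name]):
                    fh.write(f"{name}\t{t}\n")


# -- clade expressions ---------------------------------------------------

@dataclass(frozen=True)
class CladeExpression:
    """Expression tree: op in {name, all, union, difference}."""

    op: str
    name: str | None = None
    operands: tuple["CladeExpression", ...] = field(default=())

    def __str__(self) -> str:
        if self.op == "name":
            return self.name  # type: ignore[return-value]
        if self.op == "all":
            return "ALL"
        sep = "+" if self.op == "union" else "-"
        parts = []
        for i, sub in enumerate(self.operands):
            s = str(sub)
            if i > 0 and sub.op in ("union", "difference"):
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


def clade(name: str) -> CladeExpression:
    return CladeExpression("all") if name == "ALL" else CladeExpression("name", name)


def union(*exprs: CladeExpression) -> CladeExpression:
    return CladeExpression("union", operands=tuple(exprs))


def difference(a: CladeExpression, b: CladeExpression) -> CladeExpression:
    return CladeExpression("difference", operands=(a, b))


_EXPR_TOKEN = re.compile(r"\s*([+\-()]|[^\s+\-()]+)")


def parse_clade_expression(text: str) -> CladeExpression:
    """Parse ``A+B``, ``ALL-CladeA``, ``(A+B)-C`` into an expression tree.

    ``+`` is union, ``-`` is set difference, both left-associative with
    equal precedence; ``ALL`` denotes every taxon in the definition set's
    universe.
    """
    tokens = _EXPR_TOKEN.findall(text)
    if not tokens:
        raise CladeError("empty clade expression")
    pos = 0

    def parse_atom() -> CladeExpression:
        nonlocal pos
        if pos >= len(tokens):
            raise CladeError(f"unexpected end of clade expression {text!r}")
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            inner = parse_expr()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise CladeError(f"missing ')' in clade expression {text!r}")
            pos += 1
            return inner
        if tok in "+-)":
            raise CladeError(f"unexpected {tok!r} in clade expression {text!r}")
        return clade(tok)

    def parse_expr() -> CladeExpression:
        nonlocal pos
        node = parse_atom()
        while pos < len(tokens) and tokens[pos] in "+-":
            op = tokens[pos]
            pos += 1
            rhs = parse_atom()
            node = union(node, rhs) if op == "+" else difference(node, rhs)
        return node

    out = parse_expr()
    if pos != len(tokens):
        raise CladeError(f"trailing tokens in clade expression {text!r}")
    return out


def resolve_clade(expr: CladeExpression, defs: CladeDefinitionSet) -> set[str]:
    """Evaluate an expression to a taxon-id set; empty results are errors."""
    result = _resolve(expr, defs)
    if not result:
        raise CladeError(f"clade expression {expr} evaluates to the empty set")
    return result


def _resolve(expr: CladeExpression, defs: CladeDefinitionSet) -> set[str]:
    if expr.op == "name":
        return defs.members(expr.name)  # type: ignore[arg-type]
    if expr.op == "all":
        return defs.universe
    if expr.op == "union":
        out: set[str] = set()
        for sub in expr.operands:
            out |= _resolve(sub, defs)
        return out
    if expr.op == "difference":
        a, b = expr.operands
        return _resolve(a, defs) - _resolve(b, defs)
    raise CladeError(f"unknown expression op {expr.op!r}")
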