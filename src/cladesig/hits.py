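"""Ingestion of tabular homology-search output (BLAST outfmt-6 dialect).

Supports the standard 12-column layout
``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore`` and a 13-column variant with a trailing ``slen``.
Hits are normalized, annotated with taxon/clade labels from a
:class:`~cladesig.taxa.TaxonomyMap`, grouped per query and sorted by
(evalue asc, bitscore desc, subject_id) — a total, stable order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, TextIO

from .taxa import CladeDefinitionSet, TaxonomyMap

UNKNOWN_FOREIGN = "unknown_foreign"


class HitTableError(ValueError):
    pass


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    subject_length: int | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise HitTableError(f"negative evalue on hit {self.query_id}->{self.subject_id}")
        if self.query_start > self.query_end or self.subject_start > self.subject_end:
            raise HitTableError(
                f"start > end on hit {self.query_id}->{self.subject_id}")
        if self.alignment_length < 1:
            raise HitTableError(
                f"alignment_length < 1 on hit {self.query_id}->{self.subject_id}")


@dataclass(frozen=True)
class AnnotatedHit:
    """A HitRecord extended with subject taxonomy and clade membership."""

    hit: HitRecord
    taxon_id: str
    group_tags: frozenset[str]
    clades: frozenset[str]

    @property
    def evalue(self) -> float:
        return self.hit.evalue

    @property
    def subject_id(self) -> str:
        return self.hit.subject_id


class AnnotatedHitTable:
    """Per-query, E-value-ordered annotated hits."""

    def __init__(self, by_query: dict[str, list[AnnotatedHit]]):
        self.by_query = by_query

    def hits_for(self, query_id: str) -> list[AnnotatedHit]:
        return self.by_query.get(query_id, [])

    def queries(self) -> list[str]:
        return sorted(self.by_query)

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_query.values())


def read_hit_table(stream: TextIO | Iterable[str],
                   dialect: str = "auto") -> list[HitRecord]:
    """Parse outfmt-6 rows into :class:`HitRecord` objects.

    ``dialect`` is ``"12col"``, ``"13col"`` or ``"auto"`` (accept either,
    row by row).  Blank lines and ``#`` comments are skipped; parse errors
    carry the 1-based line number.
    """
    if dialect not in ("12col", "13col", "auto"):
        raise HitTableError(f"unknown dialect {dialect!r}")
    records: list[HitRecord] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if dialect == "12col" and len(parts) != 12 or \
           dialect == "13col" and len(parts) != 13 or \
           dialect == "auto" and len(parts) not in (12, 13):
            raise HitTableError(
                f"line {lineno}: expected {'12 or 13' if dialect == 'auto' else dialect[:2]}"
                f" columns, got {len(parts)}")
        try:
            rec = HitRecord(
                query_id=parts[0],
                subject_id=parts[1],
                percent_identity=float(parts[2]),
                alignment_length=int(parts[3]),
                mismatches=int(parts[4]),
                gap_opens=int(parts[5]),
                query_start=int(parts[6]),
                query_end=int(parts[7]),
                subject_start=int(parts[8]),
                subject_end=int(parts[9]),
                evalue=float(parts[10]),
                bitscore=float(parts[11]),
                subject_length=int(parts[12]) if len(parts) == 13 else None,
            )
        except (ValueError, HitTableError) as exc:
            raise HitTableError(f"line {lineno}: {exc}") from None
        records.append(rec)
    return records


def read_hit_table_file(path: str, dialect: str = "auto") -> list[HitRecord]:
    with open(path) as fh:
        return read_hit_table(fh, dialect=dialect)


def load_subject_lengths(path: str) -> dict[str, int]:
    """Optional `seq_id<TAB>length` sidecar for 12-column tables."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise HitTableError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = int(parts[1])
    return out


def _sort_key(h: AnnotatedHit):
    return (h.hit.evalue, -h.hit.bitscore, h.hit.subject_id)


def annotate_hits(hits: list[HitRecord], taxonomy: TaxonomyMap,
                  defs: CladeDefinitionSet,
                  unknown_policy: str = "strict",
                  subject_lengths: dict[str, int] | None = None) -> AnnotatedHitTable:
    """Attach taxonomy and clade labels, group per query, sort, drop self-hits.

    ``unknown_policy="strict"`` errors on subjects missing from the map
    (listing them); ``"foreign"`` labels them :data:`UNKNOWN_FOREIGN` with
    no clade membership, which makes them count as out-of-clade evidence
    downstream.
    """
    if unknown_policy not in ("strict", "foreign"):
        raise HitTableError(f"unknown policy {unknown_policy!r}")
    clade_of_taxon: dict[str, frozenset[str]] = {}
    for name, members in defs.clades.items():
        for t in members:
            clade_of_taxon.setdefault(t, frozenset())
    for t in list(clade_of_taxon):
        clade_of_taxon[t] = frozenset(
            name for name, members in defs.clades.items() if t in members)

    unmapped: set[str] = set()
    by_query: dict[str, list[AnnotatedHit]] = {}
    for rec in hits:
        if subject_lengths is not None and rec.subject_length is None:
            slen = subject_lengths.get(rec.subject_id)
            if slen is not None:
                rec = replace(rec, subject_length=slen)
        taxon = taxonomy.taxon_of(rec.subject_id)
        if taxon is None:
            if unknown_policy == "strict":
                unmapped.add(rec.subject_id)
                continue
            taxon_id, tags = UNKNOWN_FOREIGN, frozenset()
            clades: frozenset[str] = frozenset()
        else:
            taxon_id, tags = taxon.id, taxon.group_tags
            clades = clade_of_taxon.get(taxon_id, frozenset())
        query_taxon = taxonomy.seq_to_taxon.get(rec.query_id)
        if rec.subject_id == rec.query_id and \
                (query_taxon is None or query_taxon == taxon_id):
            continue  # self-hit
        by_query.setdefault(rec.query_id, []).append(
            AnnotatedHit(hit=rec, taxon_id=taxon_id, group_tags=tags, clades=clades))
    if unmapped:
        raise HitTableError(
            f"subjects missing from taxonomy map (strict policy): {sorted(unmapped)}")
    for q in by_query:
        by_query[q].sort(key=_sort_key)
    return AnnotatedHitTable(by_query)


def write_annotated_tsv(table: AnnotatedHitTable, path: str) -> None:
    cols = ("qseqid sseqid pident length mismatch gapopen qstart qend "
            "sstart send evalue bitscore slen taxon_id clades").split()
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for q in table.queries():
            for ah in table.hits_for(q):
                h = ah.hit
                fh.write("\t".join(str(x) for x in (
                    h.query_id, h.subject_id, h.percent_identity,
                    h.alignment_length, h.mismatches, h.gap_opens,
                    h.query_start, h.query_end, h.subject_start, h.subject_end,
                    f"{h.evalue:.6g}", h.bitscore,
                    h.subject_length if h.subject_length is not None else ".",
                    ah.taxon_id, ",".join(sorted(ah.clades)))) + "\n")
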