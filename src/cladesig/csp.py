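"""Clade-specific protein (CSP) calling.

A query protein is judged *specific* to a clade expression when its
significant homologs are confined to that clade: members of the target
possess a strong homolog (presence), while sequences outside the target
either produce no significant hit (E-value above ``e_sig``) together with a
large E-value jump from the worst in-clade hit, or come only from
whitelisted exception groups / at most a configurable number of isolated
foreign taxa (in which case the call is retained with a note).

Completeness tiers: *core* calls cover every target member; *partial*
calls miss at most ``max_missing`` members (the "asterisk" tier).
Single-taxon proteins are excluded as ORFans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .hits import AnnotatedHit, AnnotatedHitTable
from .taxa import CladeDefinitionSet, CladeExpression, resolve_clade


class CSPError(ValueError):
    pass


@dataclass(frozen=True)
class CSPParams:
    e_sig: float = 1e-4              # significance ceiling for foreign hits
    e_presence: float = 1e-6         # max E to count a member as possessing a homolog
    gap_factor: float = 1e3          # min ratio first-foreign-E / last-in-clade-E
    length_ratio_bounds: tuple[float, float] = (0.7, 1.3)
    min_members: int = 2
    max_missing: int = 2
    exception_groups: frozenset[str] = frozenset({"plastid_eukaryote"})
    # distinct foreign taxa whose significant hits may be excused (with a
    # note) rather than vetoing the call; 0 = every unwhitelisted
    # significant foreign hit disqualifies
    max_isolated_foreign: int = 0
    e_floor: float = 1e-180
    length_check_hard: bool = True   # False: length violations warn, do not veto

    def __post_init__(self) -> None:
        if not (0 < self.e_presence <= self.e_sig < 1):
            raise CSPError("require 0 < e_presence <= e_sig < 1")
        if self.gap_factor <= 1:
            raise CSPError("gap_factor must be > 1")
        if self.min_members < 2:
            raise CSPError("min_members must be >= 2")
        lo, hi = self.length_ratio_bounds
        if not (lo < 1 < hi):
            raise CSPError("length_ratio_bounds must straddle 1")

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "CSPParams":
        kwargs: dict = {}
        for key, raw in d.items():
            if key in ("e_sig", "e_presence", "gap_factor", "e_floor"):
                kwargs[key] = float(raw)
            elif key in ("min_members", "max_missing", "max_isolated_foreign"):
                kwargs[key] = int(raw)
            elif key == "length_ratio_bounds":
                lo, hi = raw.split(",")
                kwargs[key] = (float(lo), float(hi))
            elif key == "exception_groups":
                kwargs[key] = frozenset(t for t in raw.split(",") if t)
            elif key == "length_check_hard":
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            else:
                raise CSPError(f"unknown CSP parameter {key!r}")
        return cls(**kwargs)


@dataclass(frozen=True)
class CSPDecision:
    query_id: str
    target: CladeExpression
    verdict: str  # specific_core | specific_partial | retained_with_exception |
                  # not_specific | orfan_excluded
    presence_taxa: frozenset[str] = frozenset()
    missing_taxa: frozenset[str] = frozenset()
    foreign_evidence: tuple[tuple[str, float], ...] = ()
    gap_ratio: float | None = None
    notes: str = ""

    @property
    def is_call(self) -> bool:
        return self.verdict in ("specific_core", "specific_partial",
                                "retained_with_exception")


@dataclass(frozen=True)
class CSPCall:
    query_id: str
    target: CladeExpression
    decision: CSPDecision
    query_length: int


def _passes_length(hit: AnnotatedHit, query_length: int,
                   params: CSPParams) -> bool:
    slen = hit.hit.subject_length
    if slen is None or query_length <= 0 or not params.length_check_hard:
        return True
    lo, hi = params.length_ratio_bounds
    return lo * query_length <= slen <= hi * query_length


def classify_protein(query: tuple[str, int],
                     hits: list[AnnotatedHit],
                     target: CladeExpression,
                     defs: CladeDefinitionSet,
                     params: CSPParams | None = None,
                     query_taxon: str | None = None) -> CSPDecision:
    """Classify one query protein against one clade-expression target.

    ``query`` is ``(id, length_aa)``; ``hits`` must already be sorted per
    the annotated-hit-table contract.  ``query_taxon``, when given and
    inside the target, counts toward presence (the query's own genome
    trivially possesses the protein; its self-hit has been removed).
    """
    params = params or CSPParams()
    query_id, query_length = query
    target_set = resolve_clade(target, defs)

    # (1) presence: in-target taxa with a qualifying hit
    presence: set[str] = set()
    last_in_clade_e = None  # worst (largest) E among qualifying in-clade hits
    for ah in hits:
        if ah.taxon_id in target_set and ah.evalue <= params.e_presence \
                and _passes_length(ah, query_length, params):
            presence.add(ah.taxon_id)
            if last_in_clade_e is None or ah.evalue > last_in_clade_e:
                last_in_clade_e = ah.evalue
    if query_taxon is not None and query_taxon in target_set:
        presence.add(query_taxon)

    # (2) ORFan exclusion
    if len(presence) < params.min_members:
        return CSPDecision(query_id, target, "orfan_excluded",
                           presence_taxa=frozenset(presence),
                           notes=f"presence below min_members={params.min_members}")

    # (3) foreign hits, minus whitelisted exception groups
    foreign: list[AnnotatedHit] = []
    excepted_sig: list[AnnotatedHit] = []
    for ah in hits:
        if ah.taxon_id in target_set or ah.taxon_id == query_taxon:
            continue
        if ah.group_tags & params.exception_groups:
            if ah.evalue <= params.e_sig:
                excepted_sig.append(ah)
            continue
        foreign.append(ah)

    def best_per_taxon(hs: list[AnnotatedHit]) -> dict[str, float]:
        out: dict[str, float] = {}
        for ah in hs:
            if ah.taxon_id not in out or ah.evalue < out[ah.taxon_id]:
                out[ah.taxon_id] = ah.evalue
        return out

    def clean(hs: list[AnnotatedHit]) -> tuple[bool, float | None]:
        """Foreign set passes: empty, or all weak with a large E-value jump."""
        if not hs:
            return True, None
        min_e = min(ah.evalue for ah in hs)
        denom = max(last_in_clade_e if last_in_clade_e is not None else 0.0,
                    params.e_floor)
        ratio = max(min_e, params.e_floor) / denom
        ok = min_e > params.e_sig and ratio >= params.gap_factor
        return ok, ratio

    ok, gap_ratio = clean(foreign)
    isolated_taxa: list[str] = []
    if not ok:
        sig_taxa = sorted({ah.taxon_id for ah in foreign
                           if ah.evalue <= params.e_sig})
        if sig_taxa and len(sig_taxa) <= params.max_isolated_foreign:
            rest = [ah for ah in foreign if ah.taxon_id not in sig_taxa]
            ok2, gap2 = clean(rest)
            if ok2:
                ok, gap_ratio = True, gap2
                isolated_taxa = sig_taxa

    missing = frozenset(target_set - presence)
    if not ok:
        blockers = sorted(best_per_taxon(
            [ah for ah in foreign if ah.evalue <= params.e_sig]).items())
        if not blockers:  # weak foreign hits but insufficient E-value jump
            blockers = sorted(best_per_taxon(foreign).items())
        return CSPDecision(query_id, target, "not_specific",
                           presence_taxa=frozenset(presence),
                           missing_taxa=missing,
                           foreign_evidence=tuple(blockers),
                           gap_ratio=gap_ratio,
                           notes="blocked by foreign hits")

    # (6) completeness
    if len(missing) > params.max_missing:
        return CSPDecision(query_id, target, "not_specific",
                           presence_taxa=frozenset(presence),
                           missing_taxa=missing,
                           gap_ratio=gap_ratio,
                           notes=f"{len(missing)} target members missing "
                                 f"(> max_missing={params.max_missing})")

    notes_parts: list[str] = []
    evidence: list[tuple[str, float]] = []
    if isolated_taxa:
        notes_parts.append("isolated foreign: " + ",".join(isolated_taxa))
        best = best_per_taxon([ah for ah in foreign if ah.taxon_id in isolated_taxa])
        evidence.extend(sorted(best.items()))
    if excepted_sig:
        taxa = sorted({ah.taxon_id for ah in excepted_sig})
        notes_parts.append("exception-group homologs: " + ",".join(taxa))
        evidence.extend(sorted(best_per_taxon(excepted_sig).items()))

    if isolated_taxa or excepted_sig:
        verdict = "retained_with_exception"
    elif missing:
        verdict = "specific_partial"
    else:
        verdict = "specific_core"
    return CSPDecision(query_id, target, verdict,
                       presence_taxa=frozenset(presence),
                       missing_taxa=missing,
                       foreign_evidence=tuple(evidence),
                       gap_ratio=gap_ratio,
                       notes="; ".join(notes_parts))


def order_targets(targets: list[CladeExpression],
                  defs: CladeDefinitionSet) -> list[CladeExpression]:
    """Most-specific-first: smallest resolved set, ties by listed order."""
    sized = [(len(resolve_clade(t, defs)), i, t) for i, t in enumerate(targets)]
    sized.sort(key=lambda x: (x[0], x[1]))
    return [t for _, _, t in sized]


def call_genome(queries: list[tuple[str, int]],
                table: AnnotatedHitTable,
                targets: list[CladeExpression],
                defs: CladeDefinitionSet,
                params: CSPParams | None = None,
                query_taxa: dict[str, str] | None = None) -> list[CSPCall]:
    """Assign each query to at most one target (most-specific-first).

    A query is reported under the first target, in specificity order, for
    which :func:`classify_protein` yields a clean specific verdict; if no
    target is cleanly specific, the first retained-with-exception verdict
    is used (an exact compound target beats claiming a smaller clade with
    the extra taxa written off as exceptions).  Queries matching no target
    are omitted.  Output is sorted by target expression then query id.
    Duplicate query ids are an error.
    """
    params = params or CSPParams()
    seen: set[str] = set()
    for qid, _ in queries:
        if qid in seen:
            raise CSPError(f"duplicate query id {qid!r}")
        seen.add(qid)
    ordered = order_targets(targets, defs)
    calls: list[CSPCall] = []
    for qid, qlen in queries:
        hits = table.hits_for(qid)
        qtaxon = (query_taxa or {}).get(qid)
        retained: CSPCall | None = None
        chosen: CSPCall | None = None
        for target in ordered:
            decision = classify_protein((qid, qlen), hits, target, defs,
                                        params, query_taxon=qtaxon)
            if decision.verdict in ("specific_core", "specific_partial"):
                chosen = CSPCall(qid, target, decision, qlen)
                break
            if decision.verdict == "retained_with_exception" and retained is None:
                retained = CSPCall(qid, target, decision, qlen)
        chosen = chosen or retained
        if chosen is not None:
            calls.append(chosen)
    calls.sort(key=lambda c: (str(c.target), c.query_id))
    return calls


def write_calls_tsv(calls: list[CSPCall], path: str) -> None:
    """Publication-table-style TSV: one row per called protein."""
    with open(path, "w") as fh:
        fh.write("#query_id\ttarget\tverdict\tn_present\tmissing_taxa"
                 "\texceptions\tlength\n")
        for c in calls:
            d = c.decision
            fh.write("\t".join([
                c.query_id, str(c.target), d.verdict,
                str(len(d.presence_taxa)),
                ",".join(sorted(d.missing_taxa)) or ".",
                d.notes or ".",
                str(c.query_length),
            ]) + "\n")


def calls_to_report(calls: list[CSPCall]) -> dict:
    """JSON-ready evidence dump grouped by target."""
    out: dict[str, list[dict]] = {}
    for c in calls:
        d = c.decision
        out.setdefault(str(c.target), []).append({
            "query_id": c.query_id,
            "verdict": d.verdict,
            "n_present": len(d.presence_taxa),
            "missing_taxa": sorted(d.missing_taxa),
            "foreign_evidence": [[t, e] for t, e in d.foreign_evidence],
            "gap_ratio": d.gap_ratio,
            "notes": d.notes,
            "length": c.query_length,
        })
    return out
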