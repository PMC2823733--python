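"""Conserved signature indel (CSI) scanning.

A CSI is a contiguous alignment region where gap state cleanly separates a
clade from everything else, bracketed by conserved, gap-free flanks:

* pattern A — clade members hold residues, non-clade sequences hold gaps
  (an insert restricted to the clade, or a deletion everywhere else);
* pattern B — the reverse (clade members gapped).

Polarity is decided by designated outgroup sequences: gapped outgroup
under pattern A means the clade gained an insert; residue-bearing outgroup
under pattern B means the clade suffered a deletion.

Column rule, with tolerance ``tau`` (fraction of sequences per side
allowed to violate the gap pattern): a column belongs to pattern A when at
least ``1 - tau`` of the non-clade sequences are gapped and at least one
clade member holds a residue (and symmetrically for pattern B).  The
relaxed "at least one" on the residue-bearing side lets variable-length
indels (e.g. 4-5 aa in different members, aligned into the same columns)
form a single region even at ``tau = 0``; per-member conformance is then
enforced region-wide (violator fraction <= tau among members required to
carry residues).
"""

from __future__ import annotations

from dataclasses import dataclass

from .msa import GAP, MSA


class CSIError(ValueError):
    pass


@dataclass(frozen=True)
class CSIParams:
    flank_width: int = 5
    flank_min_identity: float = 0.6
    flank_gap_free: bool = True
    tau: float = 0.0
    min_length: int = 1

    def __post_init__(self) -> None:
        if self.flank_width < 1:
            raise CSIError("flank_width must be >= 1")
        if not (0 < self.flank_min_identity <= 1):
            raise CSIError("flank_min_identity must be in (0, 1]")
        if not (0 <= self.tau < 0.5):
            raise CSIError("tau must be in [0, 0.5)")
        if self.min_length < 1:
            raise CSIError("min_length must be >= 1")


@dataclass(frozen=True)
class IndelCall:
    aln_id: str
    start: int               # 0-based half-open column region
    end: int
    length_range: tuple[int, int]   # residues carried by the residue side
    pattern: str             # "A" (clade holds residues) or "B" (clade gapped)
    polarity: str | None     # insert_in_clade | deletion_in_clade | None
    clade: str
    flank_scores: tuple[float, float]
    supporting: tuple[str, ...]
    violating: tuple[str, ...]


def _majority_fraction(msa: MSA, col: int) -> float:
    counts: dict[str, int] = {}
    for r in msa.rows:
        ch = r[col]
        if ch != GAP:
            counts[ch] = counts.get(ch, 0) + 1
    return max(counts.values()) / msa.nseq if counts else 0.0


def _flank_ok(msa: MSA, cols: range, params: CSIParams) -> tuple[bool, float]:
    score_sum = 0.0
    ok = True
    for j in cols:
        if params.flank_gap_free and any(r[j] == GAP for r in msa.rows):
            ok = False
        frac = _majority_fraction(msa, j)
        score_sum += frac
        if frac < params.flank_min_identity:
            ok = False
    return ok, score_sum / len(cols)


def scan_indels(msa: MSA, clade_members: set[str], outgroup: set[str],
                params: CSIParams | None = None,
                clade_name: str = "clade",
                aln_id: str = "aln") -> list[IndelCall]:
    """Find clade-diagnostic indel regions in ``msa``.

    ``clade_members`` and ``outgroup`` must be disjoint subsets of the
    alignment ids; the non-clade set (everything outside the clade) must be
    non-empty.  Returns maximal regions of length >= ``min_length`` whose
    flanks of width ``flank_width`` are conserved per the parameters.
    """
    params = params or CSIParams()
    ids = set(msa.ids)
    if clade_members & outgroup:
        raise CSIError("clade and outgroup sets overlap: "
                       f"{sorted(clade_members & outgroup)}")
    for name, group in (("clade", clade_members), ("outgroup", outgroup)):
        missing = group - ids
        if missing:
            raise CSIError(f"{name} ids absent from alignment: {sorted(missing)}")
    if not clade_members:
        raise CSIError("clade_members is empty")
    nonclade = [i for i in msa.ids if i not in clade_members]
    if not nonclade:
        raise CSIError("non-clade set is empty")
    in_rows = [msa.row(i) for i in sorted(clade_members)]
    in_ids = sorted(clade_members)
    out_rows = [msa.row(i) for i in nonclade]
    og_rows = [msa.row(i) for i in sorted(outgroup)]

    def gapfrac(rows: list[str], j: int) -> float:
        return sum(1 for r in rows if r[j] == GAP) / len(rows)

    F, tau = params.flank_width, params.tau
    # classify columns
    pattern_of: list[str | None] = []
    for j in range(msa.ncol):
        gin, gout = gapfrac(in_rows, j), gapfrac(out_rows, j)
        if gout >= 1 - tau and gin < 1.0:
            pattern_of.append("A")
        elif gin >= 1 - tau and gout < 1.0:
            pattern_of.append("B")
        else:
            pattern_of.append(None)

    calls: list[IndelCall] = []
    j = 0
    while j < msa.ncol:
        pat = pattern_of[j]
        if pat is None:
            j += 1
            continue
        k = j
        while k < msa.ncol and pattern_of[k] == pat:
            k += 1
        region = (j, k)
        j = k
        start, end = region
        if end - start < params.min_length:
            continue
        if start - F < 0 or end + F > msa.ncol:
            continue
        left_ok, left_score = _flank_ok(msa, range(start - F, start), params)
        right_ok, right_score = _flank_ok(msa, range(end, end + F), params)
        if not (left_ok and right_ok):
            continue

        # residue-bearing side and per-member conformance
        if pat == "A":
            bearer_ids, bearer_rows = in_ids, in_rows
            gapped_ids = nonclade
            gapped_rows = out_rows
        else:
            bearer_ids, bearer_rows = nonclade, out_rows
            gapped_ids = in_ids
            gapped_rows = in_rows
        res_counts = {sid: sum(1 for c in row[start:end] if c != GAP)
                      for sid, row in zip(bearer_ids, bearer_rows)}
        violators = sorted(sid for sid, n in res_counts.items() if n == 0)
        violators += sorted(
            sid for sid, row in zip(gapped_ids, gapped_rows)
            if any(c != GAP for c in row[start:end]))
        side_n = max(len(bearer_ids), len(gapped_ids))
        if len(violators) > tau * side_n:
            continue
        carried = [n for n in res_counts.values() if n > 0]
        length_range = (min(carried), max(carried))

        polarity: str | None = None
        if og_rows:
            og_gapped = all(all(c == GAP for c in row[start:end]) for row in og_rows)
            og_res = all(any(c != GAP for c in row[start:end]) for row in og_rows)
            if pat == "A" and og_gapped:
                polarity = "insert_in_clade"
            elif pat == "B" and og_res:
                polarity = "deletion_in_clade"

        supporting = tuple(sorted(set(bearer_ids) - set(violators))) if pat == "A" \
            else tuple(sorted(set(gapped_ids) - set(violators)))
        calls.append(IndelCall(
            aln_id=aln_id, start=start, end=end,
            length_range=length_range, pattern=pat, polarity=polarity,
            clade=clade_name, flank_scores=(left_score, right_score),
            supporting=supporting, violating=tuple(violators)))
    return calls


def write_calls_tsv(calls: list[IndelCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#aln_id\tstart\tend\tlen_min\tlen_max\tpattern\tpolarity\tclade\n")
        for c in calls:
            fh.write("\t".join(str(x) for x in (
                c.aln_id, c.start, c.end, c.length_range[0], c.length_range[1],
                c.pattern, c.polarity or ".", c.clade)) + "\n")


def render_call(msa: MSA, call: IndelCall, flank: int = 5) -> str:
    """Dash-notation text rendering of a call +/- ``flank`` columns.

    The first alignment row is the reference; in other rows, residues
    identical to the reference are shown as dashes and gaps as spaces,
    mirroring the figure convention of signature-indel papers.
    """
    lo = max(0, call.start - flank)
    hi = min(msa.ncol, call.end + flank)
    ref = msa.rows[0][lo:hi]
    width = max(len(i) for i in msa.ids) + 2
    lines = [f"{msa.ids[0]:<{width}}{ref}   [{lo}..{hi}) region [{call.start},{call.end})"]
    for sid, row in zip(msa.ids[1:], msa.rows[1:]):
        seg = row[lo:hi]
        shown = "".join(
            " " if c == GAP else ("-" if c == r and r != GAP else c)
            for c, r in zip(seg, ref))
        lines.append(f"{sid:<{width}}{shown}")
    return "\n".join(lines)
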