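"""Protein multiple sequence alignments with FASTA I/O.

Sequences are stored uppercase over the 20 amino-acid letters plus ``-``
(and ``X`` for unknown residues); all rows must have equal length.
Columns are 0-based; regions are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_ALPHABET = set(AA_LETTERS + GAP + "X")


class MSAError(ValueError):
    pass


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise MSAError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise MSAError(f"duplicate sequence ids: {dupes}")
        if self.rows:
            ncol = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != ncol:
                    raise MSAError(
                        f"sequence {sid!r} has length {len(row)}, expected {ncol}")
                bad = set(row) - _ALPHABET
                if bad:
                    raise MSAError(
                        f"illegal characters {sorted(bad)} in sequence {sid!r}")

    @property
    def nseq(self) -> int:
        return len(self.ids)

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise MSAError(f"no sequence {seq_id!r} in alignment") from None

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def select_columns(self, cols: Iterable[int]) -> "MSA":
        cols = list(cols)
        return MSA(list(self.ids), ["".join(r[j] for j in cols) for r in self.rows])

    def to_array(self) -> np.ndarray:
        """(nseq, ncol) uint8 array of character codes."""
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(self.nseq, self.ncol).copy()

    @classmethod
    def from_array(cls, ids: list[str], arr: np.ndarray) -> "MSA":
        rows = [bytes(arr[i]).decode("ascii") for i in range(arr.shape[0])]
        return cls(list(ids), rows)


def parse_fasta(stream: TextIO | Iterable[str]) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    sid: str | None = None
    chunks: list[str] = []
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            if sid is not None:
                records.append((sid, "".join(chunks)))
            sid = line[1:].split()[0] if len(line) > 1 else ""
            if not sid:
                raise MSAError("empty FASTA header")
            chunks = []
        else:
            if sid is None:
                raise MSAError("FASTA data before first header")
            chunks.append(line.strip())
    if sid is not None:
        records.append((sid, "".join(chunks)))
    return records


def read_alignment(stream: TextIO | Iterable[str]) -> MSA:
    """Read a FASTA alignment; uppercase-normalized, '.' gaps rejected."""
    records = parse_fasta(stream)
    if not records:
        raise MSAError("empty alignment")
    ids, rows = [], []
    for sid, seq in records:
        seq = seq.upper()
        if "." in seq:
            raise MSAError(f"sequence {sid!r} uses '.' gaps; only '-' accepted")
        ids.append(sid)
        rows.append(seq)
    return MSA(ids, rows)


def read_alignment_file(path: str) -> MSA:
    with open(path) as fh:
        return read_alignment(fh)


def write_fasta(records: Iterable[tuple[str, str]], path: str,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_alignment(msa: MSA, path: str) -> None:
    write_fasta(zip(msa.ids, msa.rows), path)
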