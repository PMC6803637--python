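"""Domain model for aligned short reads.

Reads are represented close to the SAM text they came from: the eleven
mandatory columns plus any tags are kept as raw strings so that a record can
be written back byte-identically, while SEQ and QUAL are exposed as mutable,
parsed views (the only two fields the denoiser is allowed to touch).

Coordinates follow the SAM convention externally (1-based, inclusive);
helpers that need array indices subtract 1 at the point of use.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

import numpy as np

#: Fixed base alphabet and index order.
BASES = "ACGT"
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASE_BYTES = np.frombuffer(BASES.encode(), dtype=np.uint8)

N_BASES = 4
N_BINS = 8
N_SYMBOLS = N_BASES * N_BINS  # 32 (base, quality-bin) output symbols

PHRED_OFFSET = 33  # Phred+33 ASCII encoding, the only offset supported

# ASCII -> base code lookup; 255 marks anything outside {A,C,G,T}.
SEQ_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    SEQ_CODE_TABLE[ord(_b)] = _i

QUERY_OPS = frozenset("MIS=X")  # CIGAR ops that consume query bases
REF_OPS = frozenset("MDN=X")    # CIGAR ops that consume reference positions
ALIGN_OPS = frozenset("M=X")    # ops that place a query base on the reference

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_FULL = re.compile(r"(?:\d+[MIDNSHP=X])+$")


def symbol_index(base_index: int, quality_bin: int) -> int:
    """Flat (base, bin) output-symbol index ``8*base + (bin-1)``, in 0..31."""
    return (base_index << 3) | (quality_bin - 1)


def symbol_label(flat: int) -> str:
    """Human-readable label like ``A:bin1`` for a flat symbol index."""
    return f"{BASES[flat >> 3]}:bin{(flat & 7) + 1}"


class SamFormatError(ValueError):
    """Raised on malformed SAM records; message carries the line number."""


class ReadClass(Enum):
    PRIMARY_MAPPED = "primary_mapped"
    SECONDARY = "secondary"
    SUPPLEMENTARY = "supplementary"
    UNMAPPED = "unmapped"


FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


def classify_read(flag: int) -> ReadClass:
    """Classify a SAM flag; unmapped dominates secondary/supplementary bits."""
    if flag & FLAG_UNMAPPED:
        return ReadClass.UNMAPPED
    if flag & FLAG_SECONDARY:
        return ReadClass.SECONDARY
    if flag & FLAG_SUPPLEMENTARY:
        return ReadClass.SUPPLEMENTARY
    return ReadClass.PRIMARY_MAPPED


def parse_cigar(text: str) -> Optional[list[tuple[str, int]]]:
    """Parse a CIGAR string into (op, length) pairs; ``*`` parses to None."""
    if text == "*":
        return None
    if not _CIGAR_FULL.match(text):
        raise SamFormatError(f"malformed CIGAR string {text!r}")
    return [(op, int(n)) for n, op in _CIGAR_TOKEN.findall(text)]


def cigar_query_length(cigar: Iterable[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in QUERY_OPS)


def cigar_reference_span(cigar: Iterable[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in REF_OPS)


@dataclass
class AlignedRead:
    """One SAM record.

    ``raw_fields`` holds every column as read (tags included, opaque);
    ``seq``/``qual`` are the mutable parsed views written back by
    :func:`write_sam`. ``qual`` is a numpy int16 array of Phred values, or
    None when the record carries ``*``.
    """

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: Optional[list[tuple[str, int]]]
    seq: Optional[str]
    qual: Optional[np.ndarray]
    raw_fields: list[str] = field(repr=False)

    @classmethod
    def from_line(cls, line: str, lineno: int = 0) -> "AlignedRead":
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise SamFormatError(
                f"line {lineno}: SAM record has {len(fields)} fields, expected >= 11"
            )
        try:
            flag = int(fields[1])
            pos = int(fields[3])
            mapq = int(fields[4])
        except ValueError as exc:
            raise SamFormatError(f"line {lineno}: non-integer FLAG/POS/MAPQ") from exc
        try:
            cigar = parse_cigar(fields[5])
        except SamFormatError as exc:
            raise SamFormatError(f"line {lineno}: {exc}") from exc
        seq = None if fields[9] == "*" else fields[9]
        if fields[10] == "*":
            qual = None
        else:
            qual = (
                np.frombuffer(fields[10].encode("ascii"), dtype=np.uint8).astype(np.int16)
                - PHRED_OFFSET
            )
        if seq is not None and qual is not None and len(seq) != len(qual):
            raise SamFormatError(
                f"line {lineno}: read {fields[0]!r} has SEQ length {len(seq)} "
                f"but QUAL length {len(qual)}"
            )
        if seq is not None and cigar is not None:
            qlen = cigar_query_length(cigar)
            if qlen != len(seq):
                raise SamFormatError(
                    f"line {lineno}: read {fields[0]!r} CIGAR consumes {qlen} "
                    f"query bases but SEQ has {len(seq)}"
                )
        return cls(
            qname=fields[0],
            flag=flag,
            rname=fields[2],
            pos=pos,
            mapq=mapq,
            cigar=cigar,
            seq=seq,
            qual=qual,
            raw_fields=fields,
        )

    def to_line(self) -> str:
        fields = list(self.raw_fields)
        fields[9] = self.seq if self.seq is not None else "*"
        if self.qual is None:
            fields[10] = "*"
        else:
            fields[10] = (
                (self.qual.astype(np.uint8) + PHRED_OFFSET).tobytes().decode("ascii")
            )
        return "\t".join(fields)

    def seq_codes(self) -> np.ndarray:
        """SEQ as base codes 0..3 (255 for non-ACGT characters)."""
        if self.seq is None:
            return np.empty(0, dtype=np.uint8)
        return SEQ_CODE_TABLE[np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)]

    def is_primary_mapped(self) -> bool:
        return classify_read(self.flag) is ReadClass.PRIMARY_MAPPED


def read_sam(path) -> tuple[str, Iterator[AlignedRead]]:
    """Read a SAM text file.

    Returns the header verbatim (as one string, possibly empty) and a lazy
    stream of :class:`AlignedRead` in file order. Malformed records raise
    :class:`SamFormatError` naming the offending line.
    """
    fh = open(path, "rt")
    header_lines: list[str] = []
    first: Optional[tuple[int, str]] = None
    lineno = 0
    for line in fh:
        lineno += 1
        if line.startswith("@"):
            header_lines.append(line)
        elif line.strip():
            first = (lineno, line)
            break
    header = "".join(header_lines)
    if first is None:
        fh.close()
        return header, iter(())

    def _records() -> Iterator[AlignedRead]:
        try:
            n, ln = first
            yield AlignedRead.from_line(ln, n)
            for ln in fh:
                n += 1
                if ln.strip():
                    yield AlignedRead.from_line(ln, n)
        finally:
            fh.close()

    return header, _records()


def reference_lengths(header: str) -> dict[str, int]:
    """Extract ``@SQ`` SN -> LN from a SAM header."""
    out: dict[str, int] = {}
    for line in header.splitlines():
        if not line.startswith("@SQ"):
            continue
        sn, ln = None, None
        for tag in line.split("\t")[1:]:
            if tag.startswith("SN:"):
                sn = tag[3:]
            elif tag.startswith("LN:"):
                ln = int(tag[3:])
        if sn is not None and ln is not None:
            out[sn] = ln
    return out


def write_sam(header: str, reads: Iterable[AlignedRead], path,
              command_line: str = "aligndude") -> None:
    """Write a SAM file: the input header verbatim, an appended ``@PG``
    program-group line, then the records in stream order."""
    with open(path, "wt") as out:
        if header:
            out.write(header if header.endswith("\n") else header + "\n")
        out.write(f"@PG\tID:aligndude\tPN:aligndude\tCL:{command_line}\n")
        for read in reads:
            out.write(read.to_line() + "\n")


def walk_alignment(read: AlignedRead) -> list[tuple[Optional[int], Optional[int], str]]:
    """Walk a read's CIGAR, pairing 0-based query indices with 1-based
    reference positions.

    M/=/X emit (query, ref); I and S emit (query, None); D and N emit
    (None, ref) once per deleted/skipped position; H and P emit nothing.
    """
    if read.cigar is None:
        raise SamFormatError(f"read {read.qname!r} has no CIGAR")
    if read.seq is not None:
        qlen = cigar_query_length(read.cigar)
        if qlen != len(read.seq):
            raise SamFormatError(
                f"read {read.qname!r} CIGAR consumes {qlen} query bases "
                f"but SEQ has {len(read.seq)}"
            )
    out: list[tuple[Optional[int], Optional[int], str]] = []
    q, r = 0, read.pos
    for op, length in read.cigar:
        if op in ALIGN_OPS:
            out.extend((q + t, r + t, op) for t in range(length))
            q += length
            r += length
        elif op in ("I", "S"):
            out.extend((q + t, None, op) for t in range(length))
            q += length
        elif op in ("D", "N"):
            out.extend((None, r + t, op) for t in range(length))
            r += length
        # H and P consume nothing
    return out


def aligned_runs(read: AlignedRead) -> list[tuple[int, int, int]]:
    """Maximal runs of reference-aligned query bases as
    (query_start, ref_start_1based, length) triples. Fast path used by the
    pileup; equivalent to grouping :func:`walk_alignment` M/=/X output."""
    runs = []
    q, r = 0, read.pos
    for op, length in read.cigar or ():
        if op in ALIGN_OPS:
            runs.append((q, r, length))
            q += length
            r += length
        elif op in ("I", "S"):
            q += length
        elif op in ("D", "N"):
            r += length
    return runs
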