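"""Double-sided context statistics (first pass, second half).

An *effective read* is the read with soft-clipped bases removed and inserted
bases retained: clipped stretches are low-confidence by construction, while
insertions may be real sequence private to the individual. Reads whose first
(last) effective base is reference-mapped are padded on that side with up to
k consensus bases from the sequence estimate, which recovers context for
windows near the read ends.

The context store maps each (left, right) pair of k-mers over {A,C,G,T} to a
32-long histogram of the central (base, quality-bin) symbols observed with
that context across all reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from .sam_model import AlignedRead, symbol_label
from .estimation import MAX_PHRED, BinningScheme, ILLUMINA8, SequenceEstimate

_BASE_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class EffectiveRead:
    """Clip-free view of a read, optionally padded with consensus bases.

    Parallel arrays, one entry per effective position:

    - ``chars``: base letters as bytes (original character for read bases,
      consensus letter for pads);
    - ``codes``: base codes 0..3, or -1 for non-ACGT;
    - ``bins``: quality bin 1..8 for read-origin entries, 0 for pads;
    - ``quals``: Phred for read-origin entries, -1 for pads;
    - ``read_index``: 0-based index into the original SEQ, -1 for pads;
    - ``ref_pos``: 1-based reference position, -1 for insertions;
    - ``origin_read``: True where the entry came from the read itself.
    """

    chars: bytes
    codes: np.ndarray
    bins: np.ndarray
    quals: np.ndarray
    read_index: np.ndarray
    ref_pos: np.ndarray
    origin_read: np.ndarray

    def __len__(self) -> int:
        return len(self.codes)


def effective_read(read: AlignedRead, scheme: BinningScheme = ILLUMINA8) -> EffectiveRead:
    """Build the unpadded effective read: drop S, keep M/=/X and I in order."""
    raw = read.seq_codes()
    quals_full = np.asarray(read.qual, dtype=np.int16)
    keep_idx: list[np.ndarray] = []
    refpos: list[np.ndarray] = []
    q, r = 0, read.pos
    for op, length in read.cigar or ():
        if op in ("M", "=", "X"):
            keep_idx.append(np.arange(q, q + length))
            refpos.append(np.arange(r, r + length))
            q += length
            r += length
        elif op == "I":
            keep_idx.append(np.arange(q, q + length))
            refpos.append(np.full(length, -1, dtype=np.int64))
            q += length
        elif op == "S":
            q += length
        elif op in ("D", "N"):
            r += length
    if keep_idx:
        idx = np.concatenate(keep_idx)
        rp = np.concatenate(refpos).astype(np.int32)
    else:
        idx = np.empty(0, dtype=np.int64)
        rp = np.empty(0, dtype=np.int32)
    kept_raw = raw[idx]
    codes = np.where(kept_raw == 255, -1, kept_raw.astype(np.int16)).astype(np.int8)
    seq_bytes = np.frombuffer(read.seq.encode("ascii"), dtype=np.uint8)
    chars = seq_bytes[idx].tobytes()
    quals = quals_full[idx]
    bins = scheme.table[np.clip(quals, 0, MAX_PHRED)].astype(np.int8)
    return EffectiveRead(
        chars=chars,
        codes=codes,
        bins=bins,
        quals=quals,
        read_index=idx.astype(np.int32),
        ref_pos=rp,
        origin_read=np.ones(len(idx), dtype=bool),
    )


def pad_read(eff: EffectiveRead, x_hat: SequenceEstimate, rname: str, k: int) -> EffectiveRead:
    """Pad with up to k consensus bases on each side.

    Padding applies only where the first (last) effective entry is
    reference-mapped, and stops at the first position where the consensus is
    undefined, so pads are always contiguous with the read.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(eff)
    if n == 0:
        return eff
    est = x_hat.codes.get(rname)

    def _grab(positions: Iterable[int]) -> list[int]:
        got = []
        for p in positions:  # walk outward; stop at first undefined
            if est is None or not (1 <= p <= len(est)) or est[p - 1] < 0:
                break
            got.append(p)
        return got

    left_pos: list[int] = []
    if eff.ref_pos[0] >= 1:
        j0 = int(eff.ref_pos[0])
        left_pos = _grab(range(j0 - 1, j0 - k - 1, -1))[::-1]
    right_pos: list[int] = []
    if eff.ref_pos[-1] >= 1:
        jn = int(eff.ref_pos[-1])
        right_pos = _grab(range(jn + 1, jn + k + 1))

    if not left_pos and not right_pos:
        return eff

    def _pad_arrays(positions: list[int]):
        codes = np.array([est[p - 1] for p in positions], dtype=np.int8)
        chars = _BASE_ASCII[codes].tobytes() if len(codes) else b""
        m = len(positions)
        return (
            chars,
            codes,
            np.zeros(m, dtype=np.int8),
            np.full(m, -1, dtype=np.int16),
            np.full(m, -1, dtype=np.int32),
            np.array(positions, dtype=np.int32),
            np.zeros(m, dtype=bool),
        )

    lc, lcd, lb, lq, li, lr, lo = _pad_arrays(left_pos)
    rc, rcd, rb, rq, ri, rr, ro = _pad_arrays(right_pos)
    return EffectiveRead(
        chars=lc + eff.chars + rc,
        codes=np.concatenate([lcd, eff.codes, rcd]),
        bins=np.concatenate([lb, eff.bins, rb]),
        quals=np.concatenate([lq, eff.quals, rq]),
        read_index=np.concatenate([li, eff.read_index, ri]),
        ref_pos=np.concatenate([lr, eff.ref_pos, rr]),
        origin_read=np.concatenate([lo, eff.origin_read, ro]),
    )


class ContextStore:
    """Sparse map from 2k-character context strings to 32-long count vectors.

    The key is the left context concatenated with the right context
    (``l^k + r^k`` as ASCII bytes); only observed contexts are stored.
    """

    def __init__(self, k: int):
        self.k = k
        self._map: dict[bytes, list[int]] = {}

    def __len__(self) -> int:
        return len(self._map)

    def add(self, key: bytes, flat_symbol: int, count: int = 1) -> None:
        vec = self._map.get(key)
        if vec is None:
            vec = [0] * 32
            self._map[key] = vec
        vec[flat_symbol] += count

    def get(self, key: bytes) -> Optional[np.ndarray]:
        vec = self._map.get(key)
        if vec is None:
            return None
        return np.asarray(vec, dtype=np.float64)

    def items(self) -> Iterator[tuple[bytes, np.ndarray]]:
        for key, vec in self._map.items():
            yield key, np.asarray(vec, dtype=np.int64)

    def total(self) -> int:
        return sum(sum(vec) for vec in self._map.values())

    def dump_tsv(self, path) -> None:
        with open(path, "wt") as out:
            out.write(
                "left\tright\t" + "\t".join(symbol_label(s) for s in range(32)) + "\n"
            )
            for key in sorted(self._map):
                vec = self._map[key]
                left = key[: self.k].decode()
                right = key[self.k :].decode()
                out.write(left + "\t" + right + "\t" + "\t".join(map(str, vec)) + "\n")


def count_windows(eff: EffectiveRead, k: int, store: ContextStore) -> int:
    """Tally every valid window of one padded effective read; returns the
    number of windows counted.

    A window is valid when its center is a read-origin A/C/G/T base and all
    2k flanking entries (pads allowed) are A/C/G/T.
    """
    n = len(eff)
    w = 2 * k + 1
    if n < w:
        return 0
    valid = eff.codes >= 0
    cs = np.concatenate(([0], np.cumsum(valid)))
    full = (cs[w:] - cs[:-w]) == w  # window starting at s is all-ACGT
    centers = np.nonzero(full & eff.origin_read[k : n - k])[0] + k
    chars = eff.chars
    codes = eff.codes
    bins = eff.bins
    added = 0
    for i in centers:
        key = chars[i - k : i] + chars[i + 1 : i + k + 1]
        store.add(key, (int(codes[i]) << 3) | (int(bins[i]) - 1))
        added += 1
    return added


def count_contexts(
    reads: Iterable[AlignedRead],
    x_hat: SequenceEstimate,
    k: int,
    scheme: BinningScheme = ILLUMINA8,
) -> ContextStore:
    """First-pass context acquisition over primary mapped reads."""
    store = ContextStore(k)
    for read in reads:
        if not read.is_primary_mapped():
            continue
        if read.seq is None or read.qual is None or read.cigar is None:
            continue
        eff = pad_read(effective_read(read, scheme), x_hat, read.rname, k)
        count_windows(eff, k, store)
    return store
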