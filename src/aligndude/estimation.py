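"""First-pass statistics: quality binning, reference pileups, the majority
consensus sequence estimate, and the empirical substitution-noise channel.

The channel is the 4x32 row-stochastic matrix of conditional probabilities
P(observed (base, quality-bin) | true base). It is estimated from pileup
columns whose normalized majority-base count reaches the threshold ``t_m``:
the majority base is taken as truth and every observed symbol in that column
is tallied into the conditional counts matrix N, which is then row-normalized.
Columns without a clear majority (notably heterozygous sites near 50/50)
contribute nothing, so germline polymorphism is not mistaken for noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Optional

import numpy as np

from .sam_model import (
    AlignedRead,
    N_BASES,
    N_BINS,
    N_SYMBOLS,
    aligned_runs,
    symbol_label,
)

MAX_PHRED = 93  # highest Phred encodable in printable Phred+33 ASCII


@dataclass(frozen=True)
class BinningScheme:
    """Partition of the Phred scale into 8 ordered bins.

    ``lower_bounds`` gives the inclusive lower Phred limit of each bin; the
    first must be 0 and the sequence strictly increasing, so the bins are
    disjoint, contiguous and exhaustive. Scores above the top limit fall in
    bin 8.
    """

    lower_bounds: tuple[int, ...]
    name: str = "custom"

    def __post_init__(self):
        if len(self.lower_bounds) != N_BINS:
            raise ValueError(f"need exactly {N_BINS} bin lower bounds")
        if self.lower_bounds[0] != 0:
            raise ValueError("first bin must start at Phred 0")
        if any(a >= b for a, b in zip(self.lower_bounds, self.lower_bounds[1:])):
            raise ValueError("bin lower bounds must be strictly increasing")

    @cached_property
    def table(self) -> np.ndarray:
        """Phred -> bin lookup for q in 0..MAX_PHRED."""
        qs = np.arange(MAX_PHRED + 1)
        return np.searchsorted(np.asarray(self.lower_bounds), qs, side="right").astype(
            np.int8
        )

    def bin_of(self, q: int) -> int:
        if q < 0:
            raise ValueError(f"negative Phred score {q}")
        if q > MAX_PHRED:
            return N_BINS
        return int(self.table[q])


#: Default scheme following Illumina's published 8-level quality binning.
ILLUMINA8 = BinningScheme((0, 2, 10, 20, 25, 30, 35, 40), name="illumina8")


def bin_quality(q: int, scheme: BinningScheme = ILLUMINA8) -> int:
    """Map a Phred score to its quality bin (1..8)."""
    return scheme.bin_of(q)


class _RefPileup:
    """Per-reference counters, indexed by 0-based position."""

    __slots__ = ("base_counts", "symbol_counts")

    def __init__(self, length: int):
        self.base_counts = np.zeros((length, N_BASES), dtype=np.int64)
        self.symbol_counts = np.zeros((length, N_SYMBOLS), dtype=np.int32)

    def grow(self, length: int) -> None:
        if length > len(self.base_counts):
            extra = length - len(self.base_counts)
            self.base_counts = np.vstack(
                [self.base_counts, np.zeros((extra, N_BASES), dtype=np.int64)]
            )
            self.symbol_counts = np.vstack(
                [self.symbol_counts, np.zeros((extra, N_SYMBOLS), dtype=np.int32)]
            )


class PileupStore:
    """Pileup counters for every covered reference position.

    For each position the store keeps both the 4-long base tally (bins
    aggregated) and the 32-long (base, bin) symbol tally; soft-clipped and
    inserted bases never reach the store, and non-ACGT characters are
    ignored.
    """

    def __init__(self, scheme: BinningScheme = ILLUMINA8,
                 ref_lengths: Optional[dict[str, int]] = None):
        self.scheme = scheme
        self._refs: dict[str, _RefPileup] = {}
        self._declared = dict(ref_lengths or {})

    def _ref(self, rname: str, min_length: int) -> _RefPileup:
        ref = self._refs.get(rname)
        if ref is None:
            length = max(self._declared.get(rname, 0), min_length)
            ref = _RefPileup(length)
            self._refs[rname] = ref
        else:
            ref.grow(min_length)
        return ref

    def add_read(self, read: AlignedRead) -> None:
        codes = read.seq_codes()
        bins = self.scheme.table[np.clip(read.qual, 0, MAX_PHRED)]
        runs = aligned_runs(read)
        if not runs:
            return
        end = max(rs + ln - 1 for _, rs, ln in runs)
        ref = self._ref(read.rname, end)
        for qs, rs, length in runs:
            c = codes[qs : qs + length]
            ok = c < N_BASES
            if not ok.any():
                continue
            idx = (rs - 1) + np.nonzero(ok)[0]
            cc = c[ok].astype(np.intp)
            ref.base_counts[idx, cc] += 1
            flat = (cc << 3) | (bins[qs : qs + length][ok].astype(np.intp) - 1)
            ref.symbol_counts[idx, flat] += 1

    def references(self) -> list[str]:
        return list(self._refs)

    def base_counts(self, rname: str) -> np.ndarray:
        return self._refs[rname].base_counts

    def symbol_counts(self, rname: str) -> np.ndarray:
        return self._refs[rname].symbol_counts

    def total_observations(self) -> int:
        return int(sum(r.base_counts.sum() for r in self._refs.values()))


def accumulate_pileup(
    reads: Iterable[AlignedRead],
    scheme: BinningScheme = ILLUMINA8,
    ref_lengths: Optional[dict[str, int]] = None,
) -> PileupStore:
    """Pile up every primary mapped read with bases and qualities present.

    Secondary/supplementary/unmapped reads and reads lacking SEQ, QUAL or
    CIGAR contribute nothing.
    """
    store = PileupStore(scheme, ref_lengths)
    for read in reads:
        if not read.is_primary_mapped():
            continue
        if read.seq is None or read.qual is None or read.cigar is None:
            continue
        store.add_read(read)
    return store


def majority_base(base_counts, t_m: float) -> Optional[int]:
    """The base index whose normalized count reaches ``t_m``, or None.

    None is returned for empty columns and whenever the threshold is met by
    zero or several bases (the latter is possible only for t_m <= 0.5).
    """
    counts = np.asarray(base_counts)
    total = counts.sum()
    if total == 0:
        return None
    qualified = np.nonzero(counts / total >= t_m)[0]
    if len(qualified) != 1:
        return None
    return int(qualified[0])


@dataclass
class SequenceEstimate:
    """Per-reference majority-base consensus; -1 where no base qualified."""

    codes: dict[str, np.ndarray]

    def base_at(self, rname: str, pos: int) -> Optional[int]:
        """Consensus base code at a 1-based reference position, or None."""
        arr = self.codes.get(rname)
        if arr is None or not (1 <= pos <= len(arr)):
            return None
        c = int(arr[pos - 1])
        return c if c >= 0 else None

    def defined_positions(self, rname: str) -> np.ndarray:
        arr = self.codes.get(rname)
        if arr is None:
            return np.empty(0, dtype=np.int64)
        return np.nonzero(arr >= 0)[0] + 1


@dataclass
class ChannelEstimate:
    """Row-stochastic 4x32 channel matrix with its conditional counts N."""

    matrix: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        rs = self.matrix.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-12):
            raise ValueError("channel rows must sum to 1")

    def column(self, flat_symbol: int) -> np.ndarray:
        """pi_b: the length-4 column for one observed (base, bin) symbol."""
        return self.matrix[:, flat_symbol]


def _majority_codes(base_counts: np.ndarray, t_m: float) -> np.ndarray:
    """Vectorized majority call per position; -1 where undefined."""
    totals = base_counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = base_counts / totals[:, None]
    qualified = fracs >= t_m  # NaN rows compare False everywhere
    nq = qualified.sum(axis=1)
    maj = np.where((totals > 0) & (nq == 1), base_counts.argmax(axis=1), -1)
    return maj.astype(np.int8)


def build_channel(
    pileup: PileupStore, t_m: float
) -> tuple[SequenceEstimate, np.ndarray, ChannelEstimate]:
    """Consensus sequence, conditional counts N and channel estimate.

    Every pileup column with a defined majority base j adds its 32-long
    symbol tally to row j of N; N row-normalized gives the channel. A row
    never observed as majority falls back to a uniform distribution over
    that base's own 8 symbols (no evidence of error). Raises ``ValueError``
    if no position anywhere has a defined majority.
    """
    codes: dict[str, np.ndarray] = {}
    N = np.zeros((N_BASES, N_SYMBOLS), dtype=np.int64)
    for rname in pileup.references():
        bc = pileup.base_counts(rname)
        maj = _majority_codes(bc, t_m)
        codes[rname] = maj
        sc = pileup.symbol_counts(rname)
        for j in range(N_BASES):
            sel = maj == j
            if sel.any():
                N[j] += sc[sel].sum(axis=0, dtype=np.int64)
    if N.sum() == 0:
        raise ValueError("cannot estimate channel: no position has a majority base")
    matrix = np.zeros((N_BASES, N_SYMBOLS), dtype=np.float64)
    row_sums = N.sum(axis=1)
    for j in range(N_BASES):
        if row_sums[j] > 0:
            matrix[j] = N[j] / row_sums[j]
        else:
            matrix[j, 8 * j : 8 * j + 8] = 1.0 / N_BINS
    return SequenceEstimate(codes), N, ChannelEstimate(matrix, N)


def dump_channel_tsv(channel: ChannelEstimate, path) -> None:
    """Debug dump of N and the channel matrix as TSV (rows A,C,G,T)."""
    with open(path, "wt") as out:
        out.write("matrix\trow\t" + "\t".join(symbol_label(s) for s in range(N_SYMBOLS)) + "\n")
        for name, mat in (("N", channel.counts), ("Pi_hat", channel.matrix)):
            for j, row in enumerate(mat):
                vals = "\t".join(
                    str(int(v)) if name == "N" else f"{v:.6g}" for v in row
                )
                out.write(f"{name}\t{'ACGT'[j]}\t{vals}\n")
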