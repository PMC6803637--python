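"""Second pass: sliding-window denoising and quality-score updating.

For each eligible read base z_i with quality q_i, the denoiser forms the
double-sided context (l^k, r^k), looks up the context's count vector m, and
estimates the distribution of the clean base as

    q_hat = pi_(z_i, bin_i) * [(Pi Pi^T)^-1 Pi m]

where Pi is the 4x32 channel estimate, pi_b its column for the observed
(base, bin) symbol, and * is element-wise. Negative components of the
channel-inverted vector are clamped to zero and q_hat is normalized so its
maximum is a probability. The base is replaced by the argmax (ties prefer
the original base, then A<C<G<T) and the quality is updated from p_max: the
mean-with-prior rule when the base is kept, a straight back-conversion when
it is changed.

Bases whose own confidence 1 - 10^(-q/10) already reaches the threshold t_p
are never touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .sam_model import (
    AlignedRead,
    BASE_BYTES,
    read_sam,
    reference_lengths,
    write_sam,
)
from .estimation import (
    BinningScheme,
    ChannelEstimate,
    ILLUMINA8,
    MAX_PHRED,
    SequenceEstimate,
    accumulate_pileup,
    build_channel,
)
from .contexts import ContextStore, count_contexts, effective_read, pad_read


def phred_to_prob(q: int) -> float:
    """Confidence probability p = 1 - 10^(-q/10) of a Phred score."""
    if q < 0:
        raise ValueError(f"negative Phred score {q}")
    return 1.0 - 10.0 ** (-q / 10.0)


def prob_to_phred(p: float, q_cap: int = 41) -> int:
    """Back-convert a probability to a Phred score, rounded half away from
    zero and capped at ``q_cap`` (p = 1 maps to the cap)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if p >= 1.0:
        return q_cap
    q = -10.0 * math.log10(1.0 - p)
    return min(int(math.floor(q + 0.5)), q_cap)


def update_quality(q_i: int, p_max: float, base_changed: bool, q_cap: int = 41) -> int:
    """Updated Phred score after a denoising decision.

    Kept base: back-convert the mean of the sequencer's confidence and
    p_max. Changed base: the old quality is unrelated to the new base, so
    back-convert p_max alone.
    """
    if base_changed:
        p = p_max
    else:
        p = (phred_to_prob(q_i) + p_max) / 2.0
    return prob_to_phred(p, q_cap)


@dataclass
class DistributionEstimate:
    """Estimated clean-base distribution; invalid when the evidence is
    degenerate (all-zero after channel inversion and clamping)."""

    q_hat: np.ndarray
    valid: bool


@dataclass
class DenoiserConfig:
    k: int = 7
    t_m: float = 0.9
    t_p: float = 0.9
    q_cap: int = 41
    pinv_rcond: float = 1e-10
    scheme: BinningScheme = field(default_factory=lambda: ILLUMINA8)
    pooled_stats: bool = True

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.5 <= self.t_m <= 1.0:
            raise ValueError("t_m must be in [0.5, 1]")
        if not 0.0 < self.t_p < 1.0:
            raise ValueError("t_p must be in (0, 1)")


class ChannelSolver:
    """Precomputed map m -> u = (Pi Pi^T)^-1 Pi m for one channel estimate.

    The 4x4 Gram matrix is factored once; if it is singular beyond
    ``rcond`` the least-squares pseudo-solution is used instead.
    """

    def __init__(self, channel: ChannelEstimate, rcond: float = 1e-10):
        pi = channel.matrix
        gram = pi @ pi.T
        s = np.linalg.svd(gram, compute_uv=False)
        if s[-1] > rcond * s[0]:
            self.A = np.linalg.solve(gram, pi)
        else:
            self.A = np.linalg.pinv(gram, rcond=rcond) @ pi
        self.pi = pi

    def invert(self, m: np.ndarray) -> np.ndarray:
        """Unclamped channel-inverted count vector u (length 4)."""
        return self.A @ m


def dude_estimate(
    m: np.ndarray,
    channel: ChannelEstimate,
    observed_symbol: int,
    pinv_rcond: float = 1e-10,
    solver: Optional[ChannelSolver] = None,
) -> DistributionEstimate:
    """Clean-base distribution for one context count vector and observed
    symbol. Negative components of the inverted vector are clamped to zero
    before the element-wise product with the observed symbol's channel
    column; an all-zero product yields an invalid estimate."""
    if solver is None:
        solver = ChannelSolver(channel, pinv_rcond)
    u = np.clip(solver.invert(np.asarray(m, dtype=np.float64)), 0.0, None)
    q_raw = channel.column(observed_symbol) * u
    total = q_raw.sum()
    if total <= 0.0 or not np.isfinite(total):
        return DistributionEstimate(np.zeros(4), valid=False)
    return DistributionEstimate(q_raw / total, valid=True)


def _decide(q_hat: np.ndarray, original_base: int) -> tuple[int, float]:
    """Argmax base with tie-break preferring the original, then A<C<G<T."""
    p_max = float(q_hat.max())
    if q_hat[original_base] == p_max:
        return original_base, p_max
    return int(np.argmax(q_hat)), p_max


def denoise_position(
    center: tuple[int, int, int],
    context_key: bytes,
    store: ContextStore,
    channel: ChannelEstimate,
    config: DenoiserConfig,
    solver: Optional[ChannelSolver] = None,
) -> tuple[int, int]:
    """Denoise one read position.

    ``center`` is (base_code, quality_bin, phred); ``context_key`` is the
    2k-byte context string. Returns the (possibly new) base code and Phred.
    High-confidence bases (p >= t_p), unknown contexts and degenerate
    estimates all pass through unchanged.
    """
    base, qbin, q_i = center
    if phred_to_prob(q_i) >= config.t_p:
        return base, q_i
    m = store.get(context_key)
    if m is None:
        return base, q_i
    sym = (base << 3) | (qbin - 1)
    est = dude_estimate(m, channel, sym, config.pinv_rcond, solver)
    if not est.valid:
        return base, q_i
    new_base, p_max = _decide(est.q_hat, base)
    q_new = update_quality(q_i, p_max, new_base != base, config.q_cap)
    return new_base, q_new


@dataclass
class DenoiseReport:
    reads_total: int = 0
    reads_primary: int = 0
    reads_denoised: int = 0
    bases_examined: int = 0
    bases_attempted: int = 0
    bases_changed: int = 0
    quals_updated: int = 0

    def as_dict(self) -> dict:
        return {
            "reads_total": self.reads_total,
            "reads_primary": self.reads_primary,
            "reads_denoised": self.reads_denoised,
            "bases_examined": self.bases_examined,
            "bases_attempted": self.bases_attempted,
            "bases_changed": self.bases_changed,
            "quals_updated": self.quals_updated,
        }


class _ReadDenoiser:
    """Applies the second pass to single reads, caching window decisions.

    The outcome of a window depends only on (context, observed symbol), so
    decisions are memoized across reads; the quality update additionally
    depends on q_i and is computed per base.
    """

    def __init__(self, store: ContextStore, channel: ChannelEstimate,
                 config: DenoiserConfig):
        self.store = store
        self.channel = channel
        self.config = config
        self.solver = ChannelSolver(channel, config.pinv_rcond)
        self._cache: dict[tuple[bytes, int], Optional[tuple[int, float]]] = {}
        # attempt gate per Phred score: p < t_p
        self.attemptable = np.array(
            [phred_to_prob(q) < config.t_p for q in range(MAX_PHRED + 1)], dtype=bool
        )

    def _window_decision(self, key: bytes, sym: int) -> Optional[tuple[int, float]]:
        cache_key = (key, sym)
        try:
            return self._cache[cache_key]
        except KeyError:
            pass
        m = self.store.get(key)
        if m is None:
            result = None
        else:
            est = dude_estimate(m, self.channel, sym, solver=self.solver)
            result = _decide(est.q_hat, sym >> 3) if est.valid else None
        self._cache[cache_key] = result
        return result

    def denoise_read(self, read: AlignedRead, x_hat: SequenceEstimate,
                     report: DenoiseReport) -> None:
        cfg = self.config
        k = cfg.k
        eff = pad_read(effective_read(read, cfg.scheme), x_hat, read.rname, k)
        n = len(eff)
        report.bases_examined += int((eff.origin_read & (eff.codes >= 0)).sum())
        w = 2 * k + 1
        if n < w:
            return
        valid = eff.codes >= 0
        cs = np.concatenate(([0], np.cumsum(valid)))
        full = (cs[w:] - cs[:-w]) == w
        gate = np.zeros(n, dtype=bool)
        ro = eff.origin_read
        gate[ro] = self.attemptable[np.clip(eff.quals[ro], 0, MAX_PHRED)]
        centers = np.nonzero(full & ro[k : n - k] & gate[k : n - k])[0] + k
        if len(centers) == 0:
            return
        chars = eff.chars
        codes = eff.codes
        bins = eff.bins
        quals = eff.quals
        ridx = eff.read_index
        seq_bytes: Optional[bytearray] = None
        changed_any = False
        for i in centers:
            report.bases_attempted += 1
            sym = (int(codes[i]) << 3) | (int(bins[i]) - 1)
            key = chars[i - k : i] + chars[i + 1 : i + k + 1]
            decision = self._window_decision(key, sym)
            if decision is None:
                continue
            new_base, p_max = decision
            q_i = int(quals[i])
            base_changed = new_base != int(codes[i])
            q_new = update_quality(q_i, p_max, base_changed, cfg.q_cap)
            j = int(ridx[i])
            if base_changed:
                if seq_bytes is None:
                    seq_bytes = bytearray(read.seq.encode("ascii"))
                seq_bytes[j] = int(BASE_BYTES[new_base])
                report.bases_changed += 1
                changed_any = True
            if q_new != q_i:
                read.qual[j] = q_new
                report.quals_updated += 1
        if seq_bytes is not None:
            read.seq = seq_bytes.decode("ascii")
        if changed_any:
            report.reads_denoised += 1


def _eligible(read: AlignedRead) -> bool:
    return (
        read.is_primary_mapped()
        and read.seq is not None
        and read.qual is not None
        and read.cigar is not None
    )


def build_statistics(
    in_path, config: DenoiserConfig
) -> tuple[SequenceEstimate, ChannelEstimate, ContextStore]:
    """First pass over a SAM file: consensus, channel and context store
    (pooled across reference sequences)."""
    header, reads = read_sam(in_path)
    pileup = accumulate_pileup(reads, config.scheme, reference_lengths(header))
    x_hat, _, channel = build_channel(pileup, config.t_m)
    _, reads2 = read_sam(in_path)
    store = count_contexts(reads2, x_hat, config.k, config.scheme)
    return x_hat, channel, store


def denoise_file(in_path, out_path, config: Optional[DenoiserConfig] = None,
                 command_line: Optional[str] = None) -> dict:
    """Two-pass denoising of a SAM file.

    Pass one builds the consensus sequence estimate, channel estimate and
    context store from primary mapped reads; pass two rewrites each primary
    read through the sliding-window rule. Non-primary reads and reads
    without SEQ/QUAL/CIGAR are copied through unchanged. Statistics are
    pooled across reference sequences unless ``config.pooled_stats`` is
    False, in which case each reference is processed independently.

    Returns the summary report as a plain dict.
    """
    config = config or DenoiserConfig()
    if not config.pooled_stats:
        return _denoise_file_per_reference(in_path, out_path, config, command_line)
    x_hat, channel, store = build_statistics(in_path, config)
    worker = _ReadDenoiser(store, channel, config)
    report = DenoiseReport()
    header, reads = read_sam(in_path)

    def _stream():
        for read in reads:
            report.reads_total += 1
            if _eligible(read):
                report.reads_primary += 1
                worker.denoise_read(read, x_hat, report)
            yield read

    cl = command_line or (
        f"aligndude denoise -i {in_path} -o {out_path} --k {config.k} "
        f"--tm {config.t_m} --tp {config.t_p}"
    )
    write_sam(header, _stream(), out_path, command_line=cl)
    return report.as_dict()


def _denoise_file_per_reference(in_path, out_path, config: DenoiserConfig,
                                command_line: Optional[str]) -> dict:
    """Per-reference variant: independent statistics for every RNAME.

    References where no channel can be estimated (no majority anywhere)
    pass through undenoised.
    """
    header, reads = read_sam(in_path)
    pileups: dict[str, object] = {}
    per_ref_cfg = replace(config, pooled_stats=True)
    # Build per-reference pileup by filtering; reuse the pooled machinery on
    # per-reference read subsets.
    all_reads = list(reads)
    rnames = []
    for read in all_reads:
        if _eligible(read) and read.rname not in rnames:
            rnames.append(read.rname)
    workers: dict[str, tuple[_ReadDenoiser, SequenceEstimate]] = {}
    ref_lens = reference_lengths(header)
    for rname in rnames:
        subset = [r for r in all_reads if _eligible(r) and r.rname == rname]
        pileup = accumulate_pileup(iter(subset), config.scheme, ref_lens)
        try:
            x_hat, _, channel = build_channel(pileup, config.t_m)
        except ValueError:
            continue
        store = count_contexts(iter(subset), x_hat, config.k, config.scheme)
        workers[rname] = (_ReadDenoiser(store, channel, per_ref_cfg), x_hat)
    report = DenoiseReport()

    def _stream():
        for read in all_reads:
            report.reads_total += 1
            if _eligible(read):
                report.reads_primary += 1
                if read.rname in workers:
                    worker, x_hat = workers[read.rname]
                    worker.denoise_read(read, x_hat, report)
            yield read

    cl = command_line or f"aligndude denoise -i {in_path} -o {out_path} --per-reference"
    write_sam(header, _stream(), out_path, command_line=cl)
    return report.as_dict()
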