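"""Synthetic aligned-read generator with a known substitution channel.

The generator emulates shotgun sequencing of a diploid sample: a uniform
random reference, optional heterozygous SNVs at a 50/50 (configurable)
allele ratio, fixed-length reads sampled uniformly along the reference,
per-base Phred scores drawn from a quality profile, and substitution errors
drawn from a base-and-quality-bin dependent channel. Reads are emitted
pre-aligned (correct POS and CIGAR), so the pipeline can be exercised
without an external aligner; soft-clip and single-base-insertion CIGAR
events can be injected at configurable per-read rates.

Everything is reproducible from the seed: the same configuration always
yields byte-identical SAM output and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .sam_model import AlignedRead, BASES, BASE_BYTES, N_BASES, N_BINS, N_SYMBOLS
from .estimation import BinningScheme, ILLUMINA8, MAX_PHRED

#: Default per-base quality mixture: mostly high-confidence calls with a
#: realistic low-quality tail (the only bases below the denoising gate).
DEFAULT_QUALITY_PROFILE: tuple[tuple[int, float], ...] = (
    (36, 0.70),
    (25, 0.15),
    (15, 0.07),
    (6, 0.08),
)


@dataclass
class SimulationConfig:
    ref_length: int = 50_000
    coverage: float = 30.0
    read_length: int = 100
    #: Per-bin substitution probability (scalar applied to all 8 bins, or a
    #: length-8 sequence); errors are uniform over the three other bases.
    error_rate: float | Sequence[float] = 0.01
    #: Optional full 4x32 row-stochastic channel; overrides ``error_rate``.
    channel_true: Optional[np.ndarray] = None
    quality_profile: tuple[tuple[int, float], ...] = DEFAULT_QUALITY_PROFILE
    het_rate: float = 0.0
    vaf: float = 0.5  # fraction of reads drawn from the variant haplotype
    clip_rate: float = 0.0
    ins_rate: float = 0.0
    clip_length: int = 5
    seed: int = 0
    ref_name: str = "sim_ref"
    scheme: BinningScheme = field(default_factory=lambda: ILLUMINA8)

    def __post_init__(self):
        for name in ("het_rate", "vaf", "clip_rate", "ins_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.clip_rate + self.ins_rate > 1.0:
            raise ValueError("clip_rate + ins_rate must not exceed 1")
        if self.read_length > self.ref_length:
            raise ValueError("read_length exceeds ref_length")
        if self.read_length < max(3, self.clip_length + 2):
            raise ValueError("read_length too small for the configured events")
        w = sum(wt for _, wt in self.quality_profile)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("quality profile weights must sum to 1")
        if any(q < 0 or q > MAX_PHRED for q, _ in self.quality_profile):
            raise ValueError("quality profile Phred values out of range")
        eps = self.eps_by_bin()
        if np.any(eps < 0) or np.any(eps > 1):
            raise ValueError("per-bin error rates must be in [0, 1]")
        if self.channel_true is not None:
            ch = np.asarray(self.channel_true, dtype=np.float64)
            if ch.shape != (N_BASES, N_SYMBOLS):
                raise ValueError("channel_true must be 4x32")
            if not np.allclose(ch.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("channel_true rows must sum to 1")

    def eps_by_bin(self) -> np.ndarray:
        if np.isscalar(self.error_rate):
            return np.full(N_BINS, float(self.error_rate))
        eps = np.asarray(self.error_rate, dtype=np.float64)
        if eps.shape != (N_BINS,):
            raise ValueError("error_rate must be a scalar or length-8 sequence")
        return eps

    def n_reads(self) -> int:
        return int(round(self.ref_length * self.coverage / self.read_length))

    def bin_weights(self) -> np.ndarray:
        """Marginal probability of each quality bin under the profile."""
        w = np.zeros(N_BINS)
        for q, wt in self.quality_profile:
            w[self.scheme.bin_of(q) - 1] += wt
        return w

    def true_channel(self) -> np.ndarray:
        """The implied 4x32 channel P(observed (base, bin) | true base)."""
        if self.channel_true is not None:
            return np.asarray(self.channel_true, dtype=np.float64)
        w = self.bin_weights()
        eps = self.eps_by_bin()
        pi = np.zeros((N_BASES, N_SYMBOLS))
        for j in range(N_BASES):
            for b in range(N_BASES):
                for q in range(N_BINS):
                    p = 1.0 - eps[q] if b == j else eps[q] / 3.0
                    pi[j, (b << 3) | q] = w[q] * p
        return pi


@dataclass
class SimulationTruth:
    """Ground truth for every emitted read base.

    Matrices are (n_reads, read_length); ``ref_pos`` is 1-based and -1 for
    soft-clipped or inserted bases, which never carry planted errors.
    """

    read_names: list[str]
    true_code: np.ndarray
    emitted_code: np.ndarray
    phred: np.ndarray
    ref_pos: np.ndarray
    #: Planted variants: (position_1based, ref_allele_code, alt_allele_code)
    variants: np.ndarray
    ref_codes: np.ndarray

    def n_aligned_bases(self) -> int:
        return int((self.ref_pos >= 1).sum())

    def n_errors(self) -> int:
        aligned = self.ref_pos >= 1
        return int((aligned & (self.true_code != self.emitted_code)).sum())

    def write_tsv(self, path) -> None:
        with open(path, "wt") as out:
            out.write("read_name\tread_index\tref_pos\ttrue_base\temitted_base\tphred\n")
            for r, name in enumerate(self.read_names):
                for i in range(self.true_code.shape[1]):
                    out.write(
                        f"{name}\t{i}\t{int(self.ref_pos[r, i])}\t"
                        f"{BASES[self.true_code[r, i]]}\t"
                        f"{BASES[self.emitted_code[r, i]]}\t{int(self.phred[r, i])}\n"
                    )

    def write_variants_tsv(self, path) -> None:
        with open(path, "wt") as out:
            out.write("ref_pos\tallele_a\tallele_b\n")
            for pos, a, b in self.variants:
                out.write(f"{int(pos)}\t{BASES[int(a)]}\t{BASES[int(b)]}\n")


def load_truth_tsv(path, variants_path=None) -> SimulationTruth:
    """Load a truth table (and optional variants table) written by
    :meth:`SimulationTruth.write_tsv`. Reads must all share one length."""
    names: list[str] = []
    rows: dict[str, list[tuple[int, int, int, int, int]]] = {}
    base_idx = {b: i for i, b in enumerate(BASES)}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            name, ridx, rpos, tb, eb, ph = line.rstrip("\n").split("\t")
            if name not in rows:
                rows[name] = []
                names.append(name)
            rows[name].append(
                (int(ridx), int(rpos), base_idx[tb], base_idx[eb], int(ph))
            )
    rl = len(rows[names[0]]) if names else 0
    n = len(names)
    true_code = np.zeros((n, rl), dtype=np.int8)
    emitted = np.zeros((n, rl), dtype=np.int8)
    phred = np.zeros((n, rl), dtype=np.int16)
    ref_pos = np.zeros((n, rl), dtype=np.int32)
    for r, name in enumerate(names):
        entries = rows[name]
        if len(entries) != rl:
            raise ValueError(f"read {name!r} has {len(entries)} truth rows, expected {rl}")
        for ridx, rpos, tb, eb, ph in entries:
            true_code[r, ridx] = tb
            emitted[r, ridx] = eb
            phred[r, ridx] = ph
            ref_pos[r, ridx] = rpos
    variants = np.empty((0, 3), dtype=np.int64)
    if variants_path is not None:
        recs = []
        with open(variants_path) as fh:
            fh.readline()
            for line in fh:
                pos, a, b = line.rstrip("\n").split("\t")
                recs.append((int(pos), base_idx[a], base_idx[b]))
        if recs:
            variants = np.array(recs, dtype=np.int64)
    return SimulationTruth(
        read_names=names,
        true_code=true_code,
        emitted_code=emitted,
        phred=phred,
        ref_pos=ref_pos,
        variants=variants,
        ref_codes=np.empty(0, dtype=np.int8),
    )


@dataclass
class SimulationResult:
    header: str
    reads: list[AlignedRead]
    truth: SimulationTruth
    config: SimulationConfig

    def write_sam(self, path) -> None:
        with open(path, "wt") as out:
            out.write(self.header)
            for read in self.reads:
                out.write(read.to_line() + "\n")


def _draw_emitted(rng: np.random.Generator, cfg: SimulationConfig,
                  true_code: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """Pass the truth matrix through the substitution channel."""
    if cfg.channel_true is None:
        eps = cfg.eps_by_bin()
        e = eps[bins - 1]
        err = rng.random(true_code.shape) < e
        shift = rng.integers(1, 4, size=true_code.shape, dtype=np.int8)
        return np.where(err, (true_code + shift) % 4, true_code).astype(np.int8)
    # Full-channel mode: per (true base, bin) group, sample the emitted base
    # from the channel row restricted to that bin's four columns.
    pi = np.asarray(cfg.channel_true, dtype=np.float64)
    u = rng.random(true_code.shape)
    emitted = true_code.copy()
    for j in range(N_BASES):
        for q in range(1, N_BINS + 1):
            sel = (true_code == j) & (bins == q)
            if not sel.any():
                continue
            probs = pi[j, [(b << 3) | (q - 1) for b in range(N_BASES)]]
            total = probs.sum()
            if total <= 0:  # bin never emitted for this base: keep truth
                continue
            cdf = np.cumsum(probs / total)
            emitted[sel] = np.searchsorted(cdf, u[sel], side="right").clip(0, 3)
    return emitted.astype(np.int8)


def simulate_dataset(config: SimulationConfig) -> SimulationResult:
    """Generate an aligned synthetic data set with ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L, rl = cfg.ref_length, cfg.read_length
    ref = rng.integers(0, 4, L, dtype=np.int8)

    # Heterozygous SNVs, planted away from the reference ends where
    # coverage collapses and a 50/50 site cannot be observed as such.
    margin = rl
    var_mask = rng.random(L) < cfg.het_rate
    var_mask[:margin] = False
    var_mask[L - margin:] = False
    var_pos0 = np.nonzero(var_mask)[0]
    alt = ((ref[var_pos0] + rng.integers(1, 4, len(var_pos0), dtype=np.int8)) % 4).astype(np.int8)
    hap_alt = ref.copy()
    hap_alt[var_pos0] = alt
    variants = np.column_stack([var_pos0 + 1, ref[var_pos0], alt]) if len(var_pos0) else np.empty((0, 3), dtype=np.int64)

    n = cfg.n_reads()
    starts = np.sort(rng.integers(0, L - rl + 1, n))
    from_alt = rng.random(n) < cfg.vaf
    u_event = rng.random(n)
    is_clip = u_event < cfg.clip_rate
    is_ins = (~is_clip) & (u_event < cfg.clip_rate + cfg.ins_rate)
    clip_side = rng.integers(0, 2, n)
    ins_off = rng.integers(1, rl - 1, n)

    phreds = np.array([q for q, _ in cfg.quality_profile])
    weights = np.array([w for _, w in cfg.quality_profile])
    quals = rng.choice(phreds, size=(n, rl), p=weights).astype(np.int16)
    bins = cfg.scheme.table[quals].astype(np.int8)

    idx = starts[:, None] + np.arange(rl)[None, :]
    true_code = np.where(from_alt[:, None], hap_alt[idx], ref[idx]).astype(np.int8)
    emitted = _draw_emitted(rng, cfg, true_code, bins)
    ref_pos = (idx + 1).astype(np.int32)

    cigars = [f"{rl}M"] * n
    cl = cfg.clip_length
    for r in np.nonzero(is_clip | is_ins)[0]:
        if is_clip[r]:
            garbage = rng.integers(0, 4, cl, dtype=np.int8)
            if clip_side[r] == 0:  # left clip
                true_code[r] = np.concatenate([garbage, true_code[r, : rl - cl]])
                emitted[r] = np.concatenate([garbage, emitted[r, : rl - cl]])
                ref_pos[r] = np.concatenate(
                    [np.full(cl, -1, dtype=np.int32),
                     np.arange(starts[r] + 1, starts[r] + 1 + rl - cl, dtype=np.int32)]
                )
                cigars[r] = f"{cl}S{rl - cl}M"
            else:  # right clip
                true_code[r] = np.concatenate([true_code[r, : rl - cl], garbage])
                emitted[r] = np.concatenate([emitted[r, : rl - cl], garbage])
                ref_pos[r] = np.concatenate(
                    [np.arange(starts[r] + 1, starts[r] + 1 + rl - cl, dtype=np.int32),
                     np.full(cl, -1, dtype=np.int32)]
                )
                cigars[r] = f"{rl - cl}M{cl}S"
        else:
            t = int(ins_off[r])
            ins_base = np.int8(rng.integers(0, 4))
            true_code[r] = np.concatenate([true_code[r, :t], [ins_base], true_code[r, t : rl - 1]])
            emitted[r] = np.concatenate([emitted[r, :t], [ins_base], emitted[r, t : rl - 1]])
            ref_pos[r] = np.concatenate(
                [np.arange(starts[r] + 1, starts[r] + 1 + t, dtype=np.int32),
                 [-1],
                 np.arange(starts[r] + 1 + t, starts[r] + rl, dtype=np.int32)]
            )
            cigars[r] = f"{t}M1I{rl - 1 - t}M"

    header = (
        "@HD\tVN:1.6\tSO:coordinate\n"
        f"@SQ\tSN:{cfg.ref_name}\tLN:{L}\n"
    )
    names = [f"read{r:06d}" for r in range(n)]
    reads = []
    for r in range(n):
        seq = BASE_BYTES[emitted[r]].tobytes().decode("ascii")
        qual = (quals[r].astype(np.uint8) + 33).tobytes().decode("ascii")
        line = "\t".join(
            [names[r], "0", cfg.ref_name, str(int(starts[r]) + 1), "60",
             cigars[r], "*", "0", "0", seq, qual]
        )
        reads.append(AlignedRead.from_line(line))

    truth = SimulationTruth(
        read_names=names,
        true_code=true_code,
        emitted_code=emitted,
        phred=quals,
        ref_pos=ref_pos,
        variants=variants,
        ref_codes=ref,
    )
    return SimulationResult(header=header, reads=reads, truth=truth, config=cfg)
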