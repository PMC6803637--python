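"""Scoring of denoised output against simulation ground truth.

Accounting is restricted to reference-aligned (M/=/X) read-origin bases;
soft-clipped and inserted bases are never denoised and are excluded. For an
aligned base with truth t, noisy value z and denoised value y:

- corrected:  z != t and y == t
- introduced: z == t and y != t
- missed:     z != t and y != t

so that noisy errors = corrected + missed on every input.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .sam_model import SEQ_CODE_TABLE, read_sam
from .simulate import SimulationTruth


@dataclass
class DenoisingReport:
    errors_corrected: int
    errors_missed: int
    errors_introduced: int
    net_error_reduction: float
    noisy_error_rate: float
    denoised_error_rate: float
    aligned_bases: int
    variant_bases_retained: Optional[float] = None
    channel_max_abs_dev: Optional[float] = None

    def as_dict(self) -> dict:
        return asdict(self)


def _denoised_codes(truth: SimulationTruth, denoised_sam_path) -> np.ndarray:
    """Denoised SEQ matrix aligned row-for-row with the truth matrices."""
    by_name: dict[str, np.ndarray] = {}
    _, reads = read_sam(denoised_sam_path)
    for read in reads:
        if read.seq is None:
            continue
        codes = SEQ_CODE_TABLE[np.frombuffer(read.seq.encode("ascii"), dtype=np.uint8)]
        by_name[read.qname] = codes
    n, rl = truth.true_code.shape
    out = np.empty((n, rl), dtype=np.int16)
    for r, name in enumerate(truth.read_names):
        codes = by_name.get(name)
        if codes is None:
            raise ValueError(f"read {name!r} missing from denoised SAM")
        if len(codes) != rl:
            raise ValueError(
                f"read {name!r} has length {len(codes)} in denoised SAM, "
                f"expected {rl}"
            )
        out[r] = codes
    return out


def error_accounting(truth: SimulationTruth, denoised_sam_path) -> DenoisingReport:
    """Score a denoised SAM file base-for-base against simulation truth."""
    den = _denoised_codes(truth, denoised_sam_path)
    aligned = truth.ref_pos >= 1
    t = truth.true_code
    z = truth.emitted_code
    noisy_err = aligned & (z != t)
    corrected = int((noisy_err & (den == t)).sum())
    missed = int((noisy_err & (den != t)).sum())
    introduced = int((aligned & (z == t) & (den != t)).sum())
    n_aligned = int(aligned.sum())
    n_noisy = int(noisy_err.sum())
    n_denoised_err = int((aligned & (den != t)).sum())
    return DenoisingReport(
        errors_corrected=corrected,
        errors_missed=missed,
        errors_introduced=introduced,
        net_error_reduction=(corrected - introduced) / n_noisy if n_noisy else 0.0,
        noisy_error_rate=n_noisy / n_aligned if n_aligned else 0.0,
        denoised_error_rate=n_denoised_err / n_aligned if n_aligned else 0.0,
        aligned_bases=n_aligned,
    )


def channel_deviation(
    pi_true: np.ndarray,
    pi_hat: np.ndarray,
    counts: Optional[np.ndarray] = None,
    min_support: int = 0,
) -> float:
    """Max absolute entry-wise deviation between two 4x32 channel matrices,
    restricted to entries with at least ``min_support`` observations in
    ``counts`` (the conditional counts matrix N) when given."""
    pi_true = np.asarray(pi_true, dtype=np.float64)
    pi_hat = np.asarray(pi_hat, dtype=np.float64)
    if pi_true.shape != pi_hat.shape:
        raise ValueError("channel matrices must have the same shape")
    dev = np.abs(pi_hat - pi_true)
    if counts is not None:
        mask = np.asarray(counts) >= min_support
        if not mask.any():
            return 0.0
        dev = dev[mask]
    return float(dev.max())


def variant_retention(truth: SimulationTruth, denoised_sam_path) -> float:
    """Fraction of noisy read bases that carry a planted non-reference
    allele (truly and as emitted) and still carry it after denoising.

    Returns 1.0 when no such bases exist.
    """
    if len(truth.variants) == 0:
        return 1.0
    den = _denoised_codes(truth, denoised_sam_path)
    max_pos = int(truth.ref_pos.max())
    alt_of = np.full(max_pos + 2, -2, dtype=np.int16)
    for pos, _a, b in truth.variants:
        alt_of[int(pos)] = int(b)
    aligned = truth.ref_pos >= 1
    pos_clipped = np.where(aligned, truth.ref_pos, 0)
    carrier = (
        aligned
        & (alt_of[pos_clipped] == truth.true_code)
        & (truth.emitted_code == truth.true_code)
    )
    n_carrier = int(carrier.sum())
    if n_carrier == 0:
        return 1.0
    retained = int((carrier & (den == truth.true_code)).sum())
    return retained / n_carrier
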