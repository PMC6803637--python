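# Methods

## Setting and model

`aligndude` removes substitution errors from aligned short sequencing reads
and updates the accompanying quality scores. The model: an unknown clean
genomic sequence x^n over the alphabet A = {A, C, G, T} is sampled by
shotgun sequencing into many short overlapping reads; the sequencer acts as
a memoryless substitution channel whose output symbols are pairs
(called base, quality score). INDEL errors are assumed negligible, which is
a good approximation for sequencing-by-synthesis platforms; the method
therefore never changes read lengths, only base identities and qualities.

To keep the output alphabet tractable the ~42-value Phred scale is reduced
to 8 bins (default limits below), giving the 32-symbol output alphabet
B = A x Q. Coupling the base with its quality bin lets one channel matrix
absorb position-within-read and cycle effects without modelling them
explicitly: systematically low-quality cycles simply populate low-quality
bins with their own error rates.

The denoiser is a two-pass, DUDE-style scheme. Because the channel of a
specific machine is rarely known, both the channel and the clean-sequence
statistics are estimated from the input file itself.

### First pass: channel, consensus and contexts

1. **Pileup and consensus.** All primary mapped reads are piled up per
   reference position (soft-clipped and inserted bases excluded; non-ACGT
   characters ignored). A position's *majority base* is the base whose
   normalized count is >= t_m (default 0.9, inclusive). Majority bases form
   the sequence estimate x̂; positions without a clear majority stay
   undefined. With t_m = 0.9 a 50/50 heterozygous site essentially never
   produces a majority, so germline variation is kept out of the noise
   statistics.
2. **Channel estimate.** At every majority position j, each observed
   (base, bin) symbol increments N[j, symbol], a 4x32 conditional counts
   matrix. Row-normalizing N gives the channel estimate Π̂. A base never
   seen as a majority would leave an all-zero row; such a row falls back to
   a uniform distribution over that base's own 8 symbols — "no evidence of
   error" — keeping Π̂Π̂ᵀ well-conditioned without inventing cross-base
   error rates.
3. **Context counts.** For each read an *effective read* is built: clips
   removed, insertions retained (they may be real private sequence), and,
   when the read starts/ends with a mapped base, up to k consensus bases
   from x̂ prepended/appended (stopping at the first undefined consensus
   position). Every window of 2k+1 effective entries whose center is a
   read-origin ACGT base and whose 2k flanks are all ACGT increments the
   32-long histogram m(l^k, r^k) at the center's (base, bin) symbol.
   Contexts are restricted to the plain ACGT alphabet so each context is
   observed often enough to be informative. Padding recovers up to 2k
   windows per read.

### Second pass: denoising and quality updating

For each read-origin base z_i with quality q_i in each primary read
(windows built exactly as in pass one):

- **Gate.** If the sequencer's own confidence p_i = 1 - 10^(-q_i/10)
  already reaches t_p (default 0.9, i.e. Phred >= 10), the base and quality
  are left untouched. The comparison is `p_i >= t_p -> skip`, so the
  boundary is conservative.
- **Distribution estimate.** Otherwise look up m for the window's context
  and compute

      q̂ = π_(z_i, bin_i) ⊙ [ (Π̂ Π̂ᵀ)⁻¹ Π̂ m ]

  where π_b is the channel column of the observed symbol and ⊙ is
  element-wise. The bracketed term deconvolves the observed symbol counts
  into estimated clean-base counts; its negative components (sampling
  noise) are clamped to zero before the product. q̂ is normalized to sum
  to 1 so its maximum is a probability; if it is identically zero (context
  unseen in the observed bin, degenerate channel), the base passes through
  unchanged, quality included.
- **Replacement.** The base becomes argmax q̂, with ties preferring the
  original base and then the fixed A<C<G<T order.
- **Quality update.** With p_max = max q̂: if the base was kept, the new
  quality is the back-conversion of (p_i + p_max)/2 — the sequencer's
  confidence and the denoiser's estimate are averaged because both refer to
  the same call. If the base was changed the old quality refers to a
  different base and is discarded: the new quality is the back-conversion
  of p_max alone. Back-conversion uses -10·log10(1-p), rounded half away
  from zero, capped at q_cap (default 41, the top of the standard
  Phred+33 printable range; the cap also bounds -log(0) for p_max = 1).

Denoising decisions depend only on first-pass statistics, so the output is
invariant to read order. Statistics are pooled across reference sequences
by default (`--per-reference` switches to independent per-reference
estimation, matching per-chromosome processing).

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 7 | single-sided context length (14-base double-sided context). Large enough to make contexts specific, small enough that each is seen repeatedly at ~30x. |
| t_m | 0.9 | majority threshold (inclusive) for consensus and channel estimation; high enough to exclude heterozygous sites. |
| t_p | 0.9 | confidence gate; bases at Phred >= 10 are never touched. |
| q_cap | 41 | maximum output Phred. |
| pinv_rcond | 1e-10 | relative condition tolerance for the 4x4 Gram solve; beyond it a least-squares pseudo-solution is used. |
| bins | 0-1, 2-9, 10-19, 20-24, 25-29, 30-34, 35-39, >=40 | 8-level quality binning following Illumina's published scheme; configurable because bin limits vary between pipelines. |

The threshold comparison in the majority rule is computed as
`count/total >= t_m` in double precision so the inclusive boundary (e.g.
9/10 at t_m = 0.9) holds exactly.

## Synthetic data generator

The simulator emulates the assumed sequencing process: a uniform random
reference, optional heterozygous SNVs (50/50 allele ratio by default; a
`vaf` parameter exposes unbalanced somatic-like mixtures), fixed-length
reads with uniform start positions, per-base Phred scores drawn i.i.d. from
a quality profile, and substitution errors drawn per quality bin (uniform
over the three other bases, or from a full 4x32 channel). Reads are
emitted pre-aligned with correct POS/CIGAR, so no external aligner is
needed; soft-clip and one-base-insertion events can be injected at
per-read rates to exercise the CIGAR handling.

Default conditions mirror the intended use case: 30x coverage, 100 bp
reads, 1% per-bin substitution error. The default quality profile is a
mixture of 70% Q36, 15% Q25, 7% Q15 and 8% Q6 — predominantly confident
calls with a realistic low-quality tail; the tail matters because only
bases below the t_p gate (Phred < 10) are ever candidates for denoising.
Heterozygous variants are planted at least one read length away from the
reference ends: coverage decays to ~1 read there, and a 50/50 site covered
by one or two reads degenerates into a spurious unanimous column that no
majority rule could recognize as heterozygous.

What the simulator does **not** model: INDEL sequencing errors (outside the
substitution-only model), platform-specific motif-dependent error hotspots,
GC bias and coverage waviness, correlated errors within a read, and
alignment errors (reads are placed at their true positions). Passing tests
on simulated data therefore demonstrate correctness of the estimation and
denoising machinery under the model's own assumptions, not performance on
real data, where mapping artifacts and context-dependent errors add noise
the channel model does not capture.

## Numerical and design choices

- **Three streaming sweeps, two logical passes.** Context acquisition pads
  reads with the finished consensus, so the file is streamed once for the
  pileup, once for context counting and once for rewriting. This keeps
  memory at O(reference length + distinct contexts) instead of buffering
  reads.
- **Window cache.** A window's decision depends only on (context, observed
  symbol); decisions are memoized across reads.
- **Counting own windows.** The count vector m includes each read's own
  window; no leave-one-out correction is applied (immaterial beyond trivial
  coverage, and the classic sliding-window formulation counts itself too).
- **Context orientation.** Contexts are taken exactly as stored in the SAM
  record; no reverse-complement canonicalization. Forward- and
  reverse-strand reads of one locus therefore feed different context keys —
  a deliberate fidelity choice; collapsing strands would roughly double
  counts at the cost of assuming strand-symmetric errors.
- **Ties and degenerate cases.** Argmax ties keep the original base;
  windows whose context was never stored (edge effects), or whose estimate
  is invalid, change nothing — not even the quality. Reads with `*`
  quality strings are passed through and excluded from all statistics. A
  single-base record whose quality encodes to the ASCII character `*` is
  indistinguishable from an absent quality string under the SAM grammar
  and is treated as absent.
- **Pileup memory.** Per-reference counter arrays are sized from the `@SQ`
  header and grown on demand; 32 int32 counters per position ≈ 128 B/base.

## Problem sizes used in tests

The test-suite and the acceptance script exercise the pipeline at 30x
coverage of 50 kb (clean-identity and diploid runs) and 100 kb (error
reduction and channel recovery) references — 1.5-3 M read bases per run,
the package's standard desk-scale validation conditions. Channel-recovery
assertions consider entries of N with >= 1000 observations, where the
binomial standard error of an estimated probability is well below the 0.01
tolerance.

## Known limitations

- Substitution-only: INDEL errors are neither modelled nor corrected.
- Paired-end mate information is not used.
- Somatic variants with allele fractions near the machine error rate can be
  "corrected" away; the method is intended for germline (healthy-tissue)
  data, and the t_m mechanism protects only balanced heterozygotes.
- The channel estimate conditions on majority positions; error bursts that
  destroy the majority locally are excluded from N, slightly biasing error
  rates downward at extreme error densities.
- BAM/CRAM are out of scope; input and output are SAM text (Phred+33).
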