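"""Quality conversions, the channel-inversion rule and file-level denoising."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import bruteforce as bf
from aligndude.contexts import ContextStore
from aligndude.denoiser import (
    ChannelSolver,
    DenoiserConfig,
    denoise_file,
    denoise_position,
    dude_estimate,
    phred_to_prob,
    prob_to_phred,
    update_quality,
)
from aligndude.estimation import ChannelEstimate
from aligndude.sam_model import read_sam, symbol_index

from conftest import sam_record


def identity_channel():
    """Noiseless channel: each base emits (base, bin8) with probability 1."""
    pi = np.zeros((4, 32))
    for j in range(4):
        pi[j, symbol_index(j, 8)] = 1.0
    return ChannelEstimate(pi, (pi * 100).astype(np.int64))


class TestConversions:
    @pytest.mark.parametrize("q,p", [(30, 0.999), (10, 0.9), (0, 0.0),
                                     (20, 0.99)])
    def test_phred_to_prob(self, q, p):
        assert phred_to_prob(q) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("p,q", [(0.99, 20), (1.0, 41), (0.0, 0),
                                     (0.999, 30)])
    def test_prob_to_phred(self, p, q):
        assert prob_to_phred(p) == q

    def test_cap_applies(self):
        assert prob_to_phred(1 - 1e-9, q_cap=41) == 41
        assert prob_to_phred(1.0, q_cap=30) == 30

    @given(st.integers(0, 60))
    def test_round_trip_is_identity_below_cap(self, q):
        assert prob_to_phred(phred_to_prob(q), q_cap=93) == q


class TestUpdateQuality:
    def test_unchanged_base_fixed_point(self):
        assert update_quality(20, 0.99, base_changed=False) == 20

    def test_unchanged_base_mean_rule(self):
        # mean of 0.9 and 1.0 is 0.95 -> -10*log10(0.05) = 13.0103 -> 13
        assert update_quality(10, 1.0, base_changed=False) == 13

    def test_changed_base_discards_old_quality(self):
        assert update_quality(40, 0.9, base_changed=True) == 10


class TestDudeEstimate:
    def test_identity_channel(self):
        channel = identity_channel()
        m = np.zeros(32)
        m[symbol_index(0, 8)] = 10
        m[symbol_index(1, 8)] = 2
        est = dude_estimate(m, channel, symbol_index(1, 8))
        assert est.valid
        assert np.allclose(est.q_hat, [0, 1, 0, 0])

    def test_all_zero_counts_invalid(self):
        est = dude_estimate(np.zeros(32), identity_channel(), 0)
        assert not est.valid

    def test_matches_dense_pseudoinverse_oracle(self, rng):
        """Channel inversion agrees with an independent SVD pinv route."""
        for _ in range(200):
            pi = rng.dirichlet(np.ones(32) * 0.3, size=4)
            channel = ChannelEstimate(pi, np.zeros((4, 32), dtype=np.int64))
            m = rng.integers(0, 50, 32).astype(float)
            solver = ChannelSolver(channel)
            u = solver.invert(m)
            u_oracle = np.linalg.pinv(pi @ pi.T) @ pi @ m
            assert np.allclose(u, u_oracle, atol=1e-9)


class TestDenoisePosition:
    def _setup(self):
        channel = identity_channel()
        store = ContextStore(1)
        store.add(b"AG", symbol_index(0, 8), 10)
        store.add(b"AG", symbol_index(1, 8), 2)
        cfg = DenoiserConfig(k=1)
        return channel, store, cfg

    def test_high_confidence_gate(self):
        channel, store, cfg = self._setup()
        # q=40: p = 0.9999 >= t_p = 0.9 -> untouched
        assert denoise_position((1, 8, 40), b"AG", store, channel, cfg) == (1, 40)

    def test_kept_base_quality_updated_by_mean_rule(self):
        _, _, cfg = self._setup()
        # noiseless channel concentrated on bin 2 keeps C with p_max = 1
        pi = np.zeros((4, 32))
        for j in range(4):
            pi[j, symbol_index(j, 2)] = 1.0
        channel = ChannelEstimate(pi, (pi * 10).astype(np.int64))
        store2 = ContextStore(1)
        store2.add(b"AG", symbol_index(1, 2), 2)
        base, q = denoise_position((1, 2, 2), b"AG", store2, channel, cfg)
        assert base == 1
        p = (phred_to_prob(2) + 1.0) / 2
        assert q == prob_to_phred(p)

    def test_missing_context_unchanged(self):
        channel, store, cfg = self._setup()
        assert denoise_position((0, 2, 2), b"TT", store, channel, cfg) == (0, 2)

    def test_boundary_p_equal_tp_not_denoised(self):
        channel, store, cfg = self._setup()
        # q=10 -> p = 0.9 exactly = t_p -> conservative: no attempt
        assert denoise_position((1, 3, 10), b"AG", store, channel, cfg) == (1, 10)


def _toy_sam(make_sam, rng, n_reads=8, read_len=20, err=0.15, seed_cigars=True):
    """Overlapping toy reads over a short reference with planted errors."""
    ref = rng.choice(list("ACGT"), 60)
    recs = []
    for i in range(n_reads):
        pos = int(rng.integers(1, 60 - read_len))
        seq = list(ref[pos - 1 : pos - 1 + read_len])
        qual = [int(q) for q in rng.choice([6, 25, 40], read_len, p=[0.4, 0.3, 0.3])]
        for j in range(read_len):
            if rng.random() < err:
                seq[j] = rng.choice([b for b in "ACGT" if b != seq[j]])
        cigar = f"{read_len}M"
        if seed_cigars and i == 0:
            cigar = f"3S{read_len - 3}M"
        elif seed_cigars and i == 1:
            cigar = f"8M1I{read_len - 9}M"
        recs.append(sam_record(f"r{i}", pos=pos, seq="".join(seq), qual=qual,
                               cigar=cigar))
    recs.append(sam_record("sec", flag=256, pos=5, seq="A" * 10, cigar="10M"))
    return make_sam(recs)


class TestDenoiseFile:
    @pytest.mark.parametrize("k", [1, 2])
    def test_matches_bruteforce_pipeline(self, make_sam, rng, k, tmp_path):
        """Full two-pass output equals the straight-line oracle base-for-base."""
        path = _toy_sam(make_sam, rng)
        out = tmp_path / f"out{k}.sam"
        denoise_file(path, out, DenoiserConfig(k=k))
        expected = bf.denoise(path, k=k, t_m=0.9, t_p=0.9)
        _, reads = read_sam(out)
        checked = 0
        for read in reads:
            if read.qname in expected:
                seq, qual = expected[read.qname]
                assert read.seq == seq, read.qname
                assert list(read.qual) == qual, read.qname
                checked += 1
        assert checked == len(expected) > 0

    def test_read_order_permutation_does_not_change_output(self, make_sam, rng,
                                                           tmp_path):
        path = _toy_sam(make_sam, rng, seed_cigars=False)
        lines = open(path).read().splitlines()
        header = [l for l in lines if l.startswith("@")]
        body = [l for l in lines if not l.startswith("@")]
        shuffled = tmp_path / "shuffled.sam"
        perm = list(rng.permutation(len(body)))
        with open(shuffled, "w") as fh:
            fh.write("\n".join(header + [body[i] for i in perm]) + "\n")
        out1, out2 = tmp_path / "o1.sam", tmp_path / "o2.sam"
        denoise_file(path, out1, DenoiserConfig(k=1))
        denoise_file(shuffled, out2, DenoiserConfig(k=1))

        def by_name(p):
            _, reads = read_sam(p)
            return {r.qname: (r.seq, None if r.qual is None else list(r.qual))
                    for r in reads}

        assert by_name(out1) == by_name(out2)

    def test_gate_invariant(self, make_sam, rng, tmp_path):
        """Bases whose confidence meets t_p are byte-identical in output."""
        path = _toy_sam(make_sam, rng)
        out = tmp_path / "out.sam"
        denoise_file(path, out, DenoiserConfig(k=1))
        _, orig = read_sam(path)
        _, den = read_sam(out)
        for o, d in zip(orig, den):
            if o.qual is None:
                continue
            for j, q in enumerate(o.qual):
                if phred_to_prob(int(q)) >= 0.9:
                    assert d.seq[j] == o.seq[j]
                    assert d.qual[j] == o.qual[j]

    def test_lengths_and_non_seq_fields_preserved(self, make_sam, rng, tmp_path):
        path = _toy_sam(make_sam, rng)
        out = tmp_path / "out.sam"
        denoise_file(path, out, DenoiserConfig(k=1))
        in_recs = [l for l in open(path).read().splitlines() if not l.startswith("@")]
        out_recs = [l for l in open(out).read().splitlines() if not l.startswith("@")]
        assert len(in_recs) == len(out_recs)
        for a, b in zip(in_recs, out_recs):
            fa, fb = a.split("\t"), b.split("\t")
            assert fa[:9] == fb[:9]
            assert len(fa[9]) == len(fb[9])
            assert fa[11:] == fb[11:]

    def test_empty_sam_raises_without_output(self, make_sam, tmp_path):
        path = make_sam([])
        out = tmp_path / "never.sam"
        with pytest.raises(ValueError):
            denoise_file(path, out, DenoiserConfig(k=1))
        assert not out.exists()

    def test_secondary_reads_copied_unchanged(self, make_sam, rng, tmp_path):
        path = _toy_sam(make_sam, rng)
        out = tmp_path / "out.sam"
        denoise_file(path, out, DenoiserConfig(k=1))
        orig = {l.split("\t")[0]: l for l in open(path) if l.startswith("sec")}
        den = {l.split("\t")[0]: l for l in open(out) if l.startswith("sec")}
        assert orig == den
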