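import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:ref1\tLN:1000\n"


def sam_record(qname="r1", flag=0, rname="ref1", pos=1, mapq=60, cigar="*",
               seq="*", qual=None, tags=()):
    """One SAM line; qual given as Phred ints (defaults to Q30 per base)."""
    if seq != "*" and qual is None:
        qual = [30] * len(seq)
    qstr = "*" if qual is None else "".join(chr(q + 33) for q in qual)
    fields = [qname, str(flag), rname, str(pos), str(mapq), cigar, "*", "0",
              "0", seq, qstr, *tags]
    return "\t".join(fields)


@pytest.fixture
def make_sam(tmp_path):
    """Write a SAM file from record lines; returns the path."""
    counter = [0]

    def _make(records, header=HEADER):
        counter[0] += 1
        path = tmp_path / f"input{counter[0]}.sam"
        with open(path, "w") as fh:
            fh.write(header)
            for rec in records:
                fh.write(rec + "\n")
        return path

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
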