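"""Independent straight-line reference implementations used as oracles.

Deliberately naive: plain dicts and per-position loops, its own SAM text
parsing, and a dense SVD pseudo-inverse for the channel inversion. Shares
no code with the package under test.
"""

import math
import re

import numpy as np

BASES = "ACGT"
BIDX = {b: i for i, b in enumerate(BASES)}
DEFAULT_BOUNDS = (0, 2, 10, 20, 25, 30, 35, 40)


def bin_of(q, bounds=DEFAULT_BOUNDS):
    b = 1
    for i, lo in enumerate(bounds):
        if q >= lo:
            b = i + 1
    return b


def parse_sam(path):
    header, reads = [], []
    for line in open(path):
        if line.startswith("@"):
            header.append(line)
            continue
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        qual = None if f[10] == "*" else [ord(c) - 33 for c in f[10]]
        reads.append(
            dict(qname=f[0], flag=int(f[1]), rname=f[2], pos=int(f[3]),
                 cigar=f[5], seq=f[9], qual=qual, fields=f)
        )
    return "".join(header), reads


def cigar_ops(c):
    return [(int(n), op) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", c)]


def is_primary(flag):
    return not (flag & 0x4 or flag & 0x100 or flag & 0x800)


def effective(read):
    """Entries (char, qual, ref_pos or None, read_index); clips dropped."""
    out = []
    q, r = 0, read["pos"]
    for n, op in cigar_ops(read["cigar"]):
        if op in "M=X":
            for t in range(n):
                out.append((read["seq"][q + t], read["qual"][q + t], r + t, q + t))
            q += n
            r += n
        elif op == "I":
            for t in range(n):
                out.append((read["seq"][q + t], read["qual"][q + t], None, q + t))
            q += n
        elif op == "S":
            q += n
        elif op in "DN":
            r += n
    return out


def padded(eff, xhat, rname, k):
    est = xhat.get(rname, {})
    left = []
    if eff and eff[0][2] is not None:
        j0 = eff[0][2]
        p = j0 - 1
        while p >= j0 - k and p in est:
            left.append((est[p], None, p, None))
            p -= 1
        left.reverse()
    right = []
    if eff and eff[-1][2] is not None:
        jn = eff[-1][2]
        p = jn + 1
        while p <= jn + k and p in est:
            right.append((est[p], None, p, None))
            p += 1
    return left + eff + right


def window_count(eff_padded, k):
    """Number of valid windows in one padded effective read."""
    n = 0
    for i in range(k, len(eff_padded) - k):
        if eff_padded[i][3] is None:
            continue
        if all(e[0] in BASES for e in eff_padded[i - k : i + k + 1]):
            n += 1
    return n


def usable(read):
    return (
        is_primary(read["flag"])
        and read["seq"] != "*"
        and read["qual"] is not None
        and read["cigar"] != "*"
    )


def first_pass(path, k, t_m, bounds=DEFAULT_BOUNDS):
    """Pileup -> majority consensus -> N -> channel -> context histograms."""
    _, reads = parse_sam(path)
    prim = [r for r in reads if usable(r)]
    pile = {}
    for r in prim:
        for ch, q, rp, qi in effective(r):
            if rp is not None and ch in BASES:
                pile.setdefault((r["rname"], rp), []).append((ch, q))
    xhat, N = {}, np.zeros((4, 32))
    for (rn, pos), col in pile.items():
        counts = {b: 0 for b in BASES}
        for ch, _ in col:
            counts[ch] += 1
        total = sum(counts.values())
        winners = [b for b in BASES if counts[b] / total >= t_m]
        if len(winners) == 1:
            j = winners[0]
            xhat.setdefault(rn, {})[pos] = j
            for ch, q in col:
                N[BIDX[j], 8 * BIDX[ch] + bin_of(q, bounds) - 1] += 1
    Pi = np.zeros((4, 32))
    for j in range(4):
        s = N[j].sum()
        if s > 0:
            Pi[j] = N[j] / s
        else:
            Pi[j, 8 * j : 8 * j + 8] = 1.0 / 8
    m = {}
    for r in prim:
        pe = padded(effective(r), xhat, r["rname"], k)
        for i in range(k, len(pe) - k):
            if pe[i][3] is None:
                continue
            if any(e[0] not in BASES for e in pe[i - k : i + k + 1]):
                continue
            key = "".join(e[0] for e in pe[i - k : i]) + "".join(
                e[0] for e in pe[i + 1 : i + k + 1]
            )
            vec = m.setdefault(key, np.zeros(32))
            vec[8 * BIDX[pe[i][0]] + bin_of(pe[i][1], bounds) - 1] += 1
    return xhat, N, Pi, m


def denoise(path, k, t_m, t_p, q_cap=41, bounds=DEFAULT_BOUNDS):
    """Full pipeline; returns {qname: (seq, qual_list)} for usable reads."""
    xhat, N, Pi, m = first_pass(path, k, t_m, bounds)
    _, reads = parse_sam(path)
    prim = [r for r in reads if usable(r)]
    inv = np.linalg.pinv(Pi @ Pi.T)
    out = {}
    for r in prim:
        seq, qual = list(r["seq"]), list(r["qual"])
        pe = padded(effective(r), xhat, r["rname"], k)
        for i in range(k, len(pe) - k):
            ch, q, rp, qi = pe[i]
            if qi is None:
                continue
            if any(e[0] not in BASES for e in pe[i - k : i + k + 1]):
                continue
            p_i = 1 - 10 ** (-q / 10)
            if p_i >= t_p:
                continue
            key = "".join(e[0] for e in pe[i - k : i]) + "".join(
                e[0] for e in pe[i + 1 : i + k + 1]
            )
            if key not in m:
                continue
            u = np.clip(inv @ Pi @ m[key], 0, None)
            sym = 8 * BIDX[ch] + bin_of(q, bounds) - 1
            qraw = Pi[:, sym] * u
            s = qraw.sum()
            if s <= 0:
                continue
            qh = qraw / s
            pmax = qh.max()
            nb = BIDX[ch] if qh[BIDX[ch]] == pmax else int(np.argmax(qh))
            p_new = pmax if nb != BIDX[ch] else (p_i + pmax) / 2
            if p_new >= 1:
                qn = q_cap
            else:
                qn = min(int(math.floor(-10 * math.log10(1 - p_new) + 0.5)), q_cap)
            seq[qi] = BASES[nb]
            qual[qi] = qn
        out[r["qname"]] = ("".join(seq), qual)
    return out
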