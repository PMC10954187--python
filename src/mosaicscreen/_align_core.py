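"""Affine-gap dynamic-programming kernels (numba-jitted).

One alignment flavour backs the package: semi-global ("glocal") —
the query is consumed end to end, reference overhangs are free. This is
the right shape both for full-length amplicon reads against a short
reference and for scanning short mutant determinants within whole reads
(query = determinant, reference = read). Gap of length L costs
open + L * extend.

An optional band restricts the DP to |j - i*m/n| <= band around the
scaled diagonal; band <= 0 means full DP. Scores use int64; bases are
int8 codes (A=0..T=3, N=4; N never matches).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(2**40))

# Pointer codes for the H matrix: 0 = diagonal, 1 = from D (ref gap),
# 2 = from I (read gap). For D/I: 0 = opened from H, 1 = extended.


@njit(cache=True)
def _sg_fill(read, ref, ma, mm, go, ge, band, want_ptr):
    n = read.shape[0]
    m = ref.shape[0]
    h_prev = np.empty(m + 1, np.int64)
    h_cur = np.empty(m + 1, np.int64)
    i_prev = np.empty(m + 1, np.int64)
    i_cur = np.empty(m + 1, np.int64)

    # pointer matrices are stored band-compressed: row i's columns
    # jlo(i)..jhi(i) live at [i, j - row_lo[i]]; column j=0 needs no
    # pointers (it is always a read-prefix insertion chain)
    width = (2 * band + 1) if band > 0 else m
    row_lo = np.ones(n + 1, np.int64)
    if want_ptr:
        p_h = np.empty((n + 1, width), np.uint8)
        p_d = np.empty((n + 1, width), np.uint8)
        p_i = np.empty((n + 1, width), np.uint8)
    else:
        p_h = np.empty((1, 1), np.uint8)
        p_d = np.empty((1, 1), np.uint8)
        p_i = np.empty((1, 1), np.uint8)

    for j in range(m + 1):
        h_prev[j] = 0  # free reference prefix
        i_prev[j] = NEG
        h_cur[j] = NEG
        i_cur[j] = NEG

    best_last = NEG
    best_j = 0

    for i in range(1, n + 1):
        if band > 0:
            c = (i * m) // n
            jlo = c - band
            if jlo < 1:
                jlo = 1
            jhi = c + band
            if jhi > m:
                jhi = m
            # clear a margin around the band; the band centre drifts by at
            # most ceil(m/n) columns per row
            drift = m // n + 2
            lo = jlo - drift
            if lo < 0:
                lo = 0
            hi = jhi + drift
            if hi > m:
                hi = m
            for j in range(lo, hi + 1):
                h_cur[j] = NEG
                i_cur[j] = NEG
        else:
            jlo = 1
            jhi = m
            for j in range(m + 1):
                h_cur[j] = NEG
                i_cur[j] = NEG

        row_lo[i] = jlo
        # read prefix before the reference start: penalized insertions
        i_cur[0] = -(go + i * ge)
        h_cur[0] = i_cur[0]

        d_left = NEG  # D[i, j-1]
        h_left = h_cur[jlo - 1]
        for j in range(jlo, jhi + 1):
            col = j - jlo
            # D: gap in the read (consumes reference)
            open_d = h_left - go - ge
            ext_d = d_left - ge
            if open_d >= ext_d:
                d_val = open_d
                if want_ptr:
                    p_d[i, col] = 0
            else:
                d_val = ext_d
                if want_ptr:
                    p_d[i, col] = 1
            # I: gap in the reference (consumes read)
            open_i = h_prev[j] - go - ge
            ext_i = i_prev[j] - ge
            if open_i >= ext_i:
                i_val = open_i
                if want_ptr:
                    p_i[i, col] = 0
            else:
                i_val = ext_i
                if want_ptr:
                    p_i[i, col] = 1
            rb = read[i - 1]
            fb = ref[j - 1]
            if rb == fb and rb < 4:
                s = ma
            else:
                s = -mm
            diag = h_prev[j - 1] + s
            best = diag
            p = 0
            if d_val > best:
                best = d_val
                p = 1
            if i_val > best:
                best = i_val
                p = 2
            h_cur[j] = best
            i_cur[j] = i_val
            if want_ptr:
                p_h[i, col] = p
            d_left = d_val
            h_left = best
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
        tmp = i_prev
        i_prev = i_cur
        i_cur = tmp

    for j in range(m + 1):
        if h_prev[j] > best_last:
            best_last = h_prev[j]
            best_j = j
    return best_last, best_j, p_h, p_d, p_i, row_lo


def semiglobal_score(read_codes, ref_codes, ma, mm, go, ge, band=0):
    score, _, _, _, _, _ = _sg_fill(
        read_codes, ref_codes, np.int64(ma), np.int64(mm), np.int64(go), np.int64(ge),
        np.int64(band), False,
    )
    return int(score)


def semiglobal_align(read_codes, ref_codes, ma, mm, go, ge, band=0):
    """Returns (score, ref_start, cigar) with cigar as [(op, length)]."""
    n = read_codes.shape[0]
    score, bj, p_h, p_d, p_i, row_lo = _sg_fill(
        read_codes, ref_codes, np.int64(ma), np.int64(mm), np.int64(go), np.int64(ge),
        np.int64(band), True,
    )
    ops: list[str] = []
    i, j = n, int(bj)
    state = 0  # 0=H, 1=D, 2=I
    while i > 0:
        if j == 0:
            # column 0 is always a read-prefix insertion chain
            ops.append("I")
            i -= 1
            continue
        col = j - int(row_lo[i])
        if state == 0:
            state = p_h[i, col]
            if state == 0:
                ops.append("M")
                i -= 1
                j -= 1
        elif state == 1:
            ops.append("D")
            opened = p_d[i, col] == 0
            j -= 1
            if opened:
                state = 0
        else:
            ops.append("I")
            opened = p_i[i, col] == 0
            i -= 1
            if opened:
                state = 0
    ref_start = j
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return int(score), ref_start, cigar
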