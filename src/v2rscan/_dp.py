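"""Numba dynamic-programming kernels.

Three kernels live here: affine-gap Needleman-Wunsch on a precomputed
column-score matrix (used pairwise and profile-profile by the progressive
aligner), X-drop ungapped extension for the translated seeded search, and
the spliced protein-to-genome aligner that models introns and frameshifts.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def nw_affine(S, gap_open, gap_ext):
    """Global affine alignment over score matrix S (n1 x n2).

    Returns (score, pa, pb, L): aligned columns pa[k]/pb[k] are row/col
    indices into S or -1 for a gap, listed 5'->3'.
    """
    n1, n2 = S.shape
    M = np.full((n1 + 1, n2 + 1), NEG)
    X = np.full((n1 + 1, n2 + 1), NEG)
    Y = np.full((n1 + 1, n2 + 1), NEG)
    pM = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    pX = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    pY = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_ext
        pX[i, 0] = 1
    for j in range(1, n2 + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_ext
        pY[0, j] = 1
    pX[1, 0] = 0
    pY[0, 1] = 0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            # match
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = ptr
            # gap in B (consume A row i)
            a = M[i - 1, j] - gap_open
            b = X[i - 1, j] - gap_ext
            c = Y[i - 1, j] - gap_open
            if a >= b and a >= c:
                X[i, j] = a
                pX[i, j] = 0
            elif b >= c:
                X[i, j] = b
                pX[i, j] = 1
            else:
                X[i, j] = c
                pX[i, j] = 2
            # gap in A (consume B col j)
            a = M[i, j - 1] - gap_open
            b = Y[i, j - 1] - gap_ext
            c = X[i, j - 1] - gap_open
            if a >= b and a >= c:
                Y[i, j] = a
                pY[i, j] = 0
            elif b >= c:
                Y[i, j] = b
                pY[i, j] = 1
            else:
                Y[i, j] = c
                pY[i, j] = 2
    # traceback
    i, j = n1, n2
    state = 0
    score = M[i, j]
    if X[i, j] > score:
        score = X[i, j]
        state = 1
    if Y[i, j] > score:
        score = Y[i, j]
        state = 2
    pa = np.empty(n1 + n2, dtype=np.int32)
    pb = np.empty(n1 + n2, dtype=np.int32)
    L = 0
    while i > 0 or j > 0:
        if state == 0:
            pa[L] = i - 1
            pb[L] = j - 1
            nstate = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            pa[L] = i - 1
            pb[L] = -1
            nstate = pX[i, j]
            if nstate == 1:
                nstate = 1
            elif nstate == 2:
                nstate = 2
            i -= 1
        else:
            pa[L] = -1
            pb[L] = j - 1
            nstate = pY[i, j]
            if nstate == 2:
                nstate = 1
            elif nstate == 1:
                nstate = 2
            j -= 1
        L += 1
        state = nstate
    return score, pa[:L][::-1].copy(), pb[:L][::-1].copy(), L


@njit(cache=True)
def ungapped_extend(q, f, qpos, fpos, k, B, xdrop):
    """X-drop ungapped extension of a k-word seed.

    q, f: aa-index arrays (query, translated frame). Returns
    (qstart, qend, score) in query coordinates; the frame interval is
    qstart+d .. qend+d with d = fpos - qpos.
    """
    d = fpos - qpos
    score = 0
    for t in range(k):
        score += B[q[qpos + t], f[fpos + t]]
    # extend right
    best = score
    cur = score
    qe = qpos + k
    i = qpos + k
    while i < len(q) and i + d < len(f):
        cur += B[q[i], f[i + d]]
        if cur > best:
            best = cur
            qe = i + 1
        if best - cur > xdrop:
            break
        i += 1
    # extend left
    cur = best
    qs = qpos
    i = qpos - 1
    while i >= 0 and i + d >= 0:
        cur += B[q[i], f[i + d]]
        if cur > best:
            best = cur
            qs = i
        if best - cur > xdrop:
            break
        i -= 1
    return qs, qe, best


@njit(cache=True)
def spliced_dp(dna, q, B, codon_aa, gap_open, gap_ext, fs_pen, intron_pen,
               min_intron, intron_len_cost):
    """Local alignment of protein q against DNA with introns/frameshifts.

    States per (j aa consumed, i nt consumed): E = in-exon (after a match,
    an inserted codon, or an intron acceptor), Dq = query-gap chain.
    Matches consume 3 nt (or 2/4 with a frameshift penalty); introns jump
    i by >= min_intron between GT..AG and leave j unchanged, at a cost of
    intron_pen + intron_len_cost per nt (the length term keeps the
    aligner from leaping between neighboring paralogs).

    Returns (score, end_j, end_i, ptrA, ptrE, ptrDn, ptrDq, donor).
    """
    n = len(dna)
    J = len(q)
    A = np.full((J + 1, n + 1), NEG)
    E = np.full((J + 1, n + 1), NEG)
    Dn = np.full((J + 1, n + 1), NEG)
    Dq = np.full((J + 1, n + 1), NEG)
    ptrA = np.zeros((J + 1, n + 1), dtype=np.int8)
    ptrE = np.zeros((J + 1, n + 1), dtype=np.int8)
    ptrDn = np.zeros((J + 1, n + 1), dtype=np.int8)
    ptrDq = np.zeros((J + 1, n + 1), dtype=np.int8)
    donor = np.full((J + 1, n + 1), -1, dtype=np.int32)
    for i in range(n + 1):
        E[0, i] = 0.0  # free leading DNA: local in genome
    best = NEG
    bj = 0
    bi = 0
    for j in range(1, J + 1):
        qa = q[j - 1]
        bd_val = NEG  # best donor so far on this row
        bd_pos = -1
        for i in range(n + 1):
            # update donor candidates: position p = i - min_intron becomes
            # eligible (intron length >= min_intron)
            p = i - min_intron
            if p >= 0 and p + 1 < n and dna[p] == 2 and dna[p + 1] == 3:
                v = E[j, p] + intron_len_cost * p
                if v > bd_val:
                    bd_val = v
                    bd_pos = p
            # A: aa j matched to a codon ending at i
            aval = NEG
            aptr = 0
            if i >= 3:
                c0 = dna[i - 3]
                c1 = dna[i - 2]
                c2 = dna[i - 1]
                s = B[qa, codon_aa[c0 * 25 + c1 * 5 + c2]]
                prev = E[j - 1, i - 3]
                ptr = 1
                if Dq[j - 1, i - 3] > prev:
                    prev = Dq[j - 1, i - 3]
                    ptr = 2
                if 0.0 > prev:
                    prev = 0.0
                    ptr = 0
                aval = prev + s
                aptr = ptr
            if i >= 2:  # frameshift: codon of 2 nt, scored as ambiguous
                prev = E[j - 1, i - 2]
                v = prev - fs_pen
                if v > aval:
                    aval = v
                    aptr = 3
            if i >= 4:  # frameshift: 4 nt consumed, last 3 read as codon
                c0 = dna[i - 3]
                c1 = dna[i - 2]
                c2 = dna[i - 1]
                s = B[qa, codon_aa[c0 * 25 + c1 * 5 + c2]]
                v = E[j - 1, i - 4] + s - fs_pen
                if v > aval:
                    aval = v
                    aptr = 4
            A[j, i] = aval
            ptrA[j, i] = aptr
            # Dn: extra codon in DNA (consume 3 nt, no aa)
            if i >= 3:
                a = E[j, i - 3] - gap_open
                b = Dn[j, i - 3] - gap_ext
                if a >= b:
                    Dn[j, i] = a
                    ptrDn[j, i] = 1
                else:
                    Dn[j, i] = b
                    ptrDn[j, i] = 0
            # Dq: query aa unmatched (consume 1 aa, no nt)
            a = E[j - 1, i] - gap_open
            b = Dq[j - 1, i] - gap_ext
            if a >= b:
                Dq[j, i] = a
                ptrDq[j, i] = 1
            else:
                Dq[j, i] = b
                ptrDq[j, i] = 0
            # E: best exon state at (j, i)
            e = A[j, i]
            eptr = 0
            if Dn[j, i] > e:
                e = Dn[j, i]
                eptr = 1
            if i >= 2 and dna[i - 2] == 0 and dna[i - 1] == 2 and bd_pos >= 0:
                v = bd_val - intron_pen - intron_len_cost * i
                if v > e:
                    e = v
                    eptr = 2
                    donor[j, i] = bd_pos
            E[j, i] = e
            ptrE[j, i] = eptr
            if e > best:
                best = e
                bj = j
                bi = i
    return best, bj, bi, ptrA, ptrE, ptrDn, ptrDq, donor
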