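"""Translated homology search and spliced gene-model reconstruction.

This is the gene-mining stage: a tBLASTn-style seeded search (k-mer
neighborhood seeds, two-hit diagonal trigger, X-drop ungapped extension,
Karlin-Altschul E-values) followed by a GeneWise-style dynamic program
that aligns the best query protein to a genomic window with explicit
intron (GT..AG) and frameshift states.  Candidate receptor loci come out
as :class:`GeneModel` objects with an intact/pseudogene status call; the
status rule encodes the repertoire definition used throughout: a gene is
*intact* iff it has no internal stop, no frameshift, and a coding length
of at least 600 nt ("shorter than 600" is discarded as too_short).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ._dp import spliced_dp, ungapped_extend
from ._seq import (
    AA_ALPHABET,
    AA_BACKGROUND,
    BLOSUM62,
    CODON_AA_TABLE,
    encode_aa,
    encode_dna,
    revcomp,
)

MIN_CDS_NT = 600


def karlin_altschul_lambda(
    matrix: np.ndarray = BLOSUM62, background: np.ndarray = AA_BACKGROUND
) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0."""
    S = matrix[:20, :20].astype(float)
    P = np.outer(background, background)

    def f(lam: float) -> float:
        return float((P * np.exp(lam * S)).sum() - 1.0)

    return float(brentq(f, 1e-4, 2.0))


_LAMBDA = karlin_altschul_lambda()


@dataclass
class TMQuery:
    query_id: str
    sequence: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty query sequence")
        bad = set(self.sequence) - set(AA_ALPHABET[:21])  # 20 aa + X
        if bad:
            raise ValueError(f"invalid query symbols: {sorted(bad)}")


@dataclass
class SearchParams:
    """Tunable parameters of the translated search and gene modelling."""

    k: int = 3
    T: int = 11  # neighborhood word score threshold
    xdrop: float = 20.0
    gap_open: float = 11.0
    gap_ext: float = 1.0
    matrix_name: str = "BLOSUM62"
    ka_lambda: float = _LAMBDA
    ka_K: float = 0.13
    evalue_cutoff: float = 1e-5
    min_cds_len: int = MIN_CDS_NT
    min_intron: int = 40
    frameshift_penalty: float = 15.0
    intron_penalty: float = 20.0
    intron_len_cost: float = 0.01  # per intron nt; penalises paralog jumps
    max_query_gap: int = 30  # aa; longer skips indicate chance re-anchoring
    min_terminal_avg: float = 1.0  # per-codon score floor for model ends
    two_hit_window: int = 40
    window_pad: int = 2_000  # > max intron length, < intergenic spacing
    locus_join_dist: int = 3_000

    def validate(self) -> None:
        if self.k < 2:
            raise ValueError("word size k must be >= 2")
        if self.ka_lambda <= 0 or self.ka_K <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be > 0")
        if min(self.gap_open, self.gap_ext, self.frameshift_penalty,
               self.intron_penalty) <= 0:
            raise ValueError("penalties must be > 0")


@dataclass
class HSP:
    scaffold: str
    strand: str
    g_start: int  # forward genomic nt, 0-based half-open
    g_end: int
    q_start: int
    q_end: int
    score: float
    evalue: float
    query_id: str = ""


@dataclass
class GeneModel:
    model_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]  # forward coords, sorted, disjoint
    cds_len: int
    protein: str
    query_id: str
    score: float
    status: str = ""
    has_stop: bool = False
    has_frameshift: bool = False
    at_scaffold_edge: bool = False

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


# ---------------------------------------------------------------------------
# six-frame translation


@dataclass
class Frame:
    strand: str
    offset: int
    dna_len: int
    aa: np.ndarray  # aa indices incl X(20)/*(21)

    def aa_to_nt(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Map an aa interval of this frame to a forward nt interval."""
        s = self.offset + 3 * aa_start
        e = self.offset + 3 * aa_end
        if self.strand == "+":
            return s, e
        return self.dna_len - e, self.dna_len - s

    def nt_to_aa(self, nt_start: int, nt_end: int) -> tuple[int, int]:
        if self.strand == "-":
            nt_start, nt_end = self.dna_len - nt_end, self.dna_len - nt_start
        return (nt_start - self.offset) // 3, (nt_end - self.offset) // 3


def six_frame_translate(dna: str) -> list[Frame]:
    """All six translation frames with coordinate maps (N codons -> X)."""
    out = []
    L = len(dna)
    for strand, seq in (("+", dna), ("-", revcomp(dna))):
        codes = encode_dna(seq).astype(np.int32)
        for off in range(3):
            n = (L - off) // 3
            if n <= 0:
                aa = np.empty(0, dtype=np.int8)
            else:
                c = codes[off : off + 3 * n].reshape(n, 3)
                aa = CODON_AA_TABLE[c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]]
            out.append(Frame(strand=strand, offset=off, dna_len=L, aa=aa))
    return out


# ---------------------------------------------------------------------------
# seeded search

_CODES3 = np.stack(
    np.meshgrid(np.arange(20), np.arange(20), np.arange(20), indexing="ij"), -1
).reshape(-1, 3)


def _query_neighborhood(q: np.ndarray, k: int, T: int):
    """(codes, qpos) of all words scoring >= T against some query word."""
    B = BLOSUM62
    codes_list = []
    qpos_list = []
    for qp in range(len(q) - k + 1):
        sc = np.zeros(len(_CODES3))
        for t in range(k):
            sc += B[q[qp + t], _CODES3[:, t]]
        sel = np.nonzero(sc >= T)[0]
        codes_list.append(sel)  # _CODES3 row index == base-20 code
        qpos_list.append(np.full(len(sel), qp, dtype=np.int64))
    codes = np.concatenate(codes_list) if codes_list else np.empty(0, np.int64)
    qpos = np.concatenate(qpos_list) if qpos_list else np.empty(0, np.int64)
    order = np.argsort(codes, kind="stable")
    return codes[order], qpos[order]


def _frame_codes(aa: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-20 k-word codes and their positions (words with X/* skipped)."""
    n = len(aa) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    a = aa.astype(np.int64)
    code = a[:n] * 400 + a[1 : n + 1] * 20 + a[2 : n + 2]
    valid = (a[:n] < 20) & (a[1 : n + 1] < 20) & (a[2 : n + 2] < 20)
    pos = np.nonzero(valid)[0]
    return code[pos], pos


def seeded_search(
    query: TMQuery,
    genome: dict[str, str],
    params: SearchParams | None = None,
    frames_by_scaffold: dict[str, list[Frame]] | None = None,
    search_space_aa: int | None = None,
) -> list[HSP]:
    """k-mer seeded, two-hit triggered, X-drop extended translated search.

    E = K * m * n * exp(-lambda * S) with m the query length and n the
    total translated length searched; HSPs with E <= cutoff are returned
    sorted by E.
    """
    params = params or SearchParams()
    params.validate()
    q = encode_aa(query.sequence)
    if len(q) < params.k:
        raise ValueError(
            f"query {query.query_id} shorter than word size k={params.k}"
        )
    neigh_codes, neigh_qpos = _query_neighborhood(q, params.k, params.T)
    if frames_by_scaffold is None:
        frames_by_scaffold = {name: six_frame_translate(s) for name, s in genome.items()}
    if search_space_aa is None:
        search_space_aa = sum(
            len(fr.aa) for frames in frames_by_scaffold.values() for fr in frames
        )
    m = len(q)
    lam, K = params.ka_lambda, params.ka_K
    # minimal raw score that can reach the E-value cutoff
    s_min = np.log(K * m * max(search_space_aa, 1) / params.evalue_cutoff) / lam

    hsps: list[HSP] = []
    for scaffold, frames in frames_by_scaffold.items():
        for fr in frames:
            codes, pos = _frame_codes(fr.aa, params.k)
            if len(codes) == 0 or len(neigh_codes) == 0:
                continue
            lo = np.searchsorted(neigh_codes, codes, "left")
            hi = np.searchsorted(neigh_codes, codes, "right")
            cnt = hi - lo
            tot = int(cnt.sum())
            if tot == 0:
                continue
            csum = np.concatenate([[0], np.cumsum(cnt)])
            within = np.arange(tot) - np.repeat(csum[:-1], cnt)
            qp = neigh_qpos[np.repeat(lo, cnt) + within]
            fp = np.repeat(pos, cnt)
            diag = fp - qp
            order = np.lexsort((fp, diag))
            diag, fp, qp = diag[order], fp[order], qp[order]
            same = diag[1:] == diag[:-1]
            close = (fp[1:] - fp[:-1] > 0) & (fp[1:] - fp[:-1] <= params.two_hit_window)
            cand = np.nonzero(same & close)[0]  # index of first hit of the pair
            covered: dict[int, int] = {}
            for ci in cand:
                d = int(diag[ci])
                if covered.get(d, -1) >= fp[ci]:
                    continue
                qs, qe, score = ungapped_extend(
                    q, fr.aa, int(qp[ci]), int(fp[ci]), params.k,
                    BLOSUM62, params.xdrop,
                )
                covered[d] = int(qe + d)
                if score < s_min:
                    continue
                evalue = K * m * search_space_aa * float(np.exp(-lam * score))
                if evalue > params.evalue_cutoff:
                    continue
                g_start, g_end = fr.aa_to_nt(qs + d, qe + d)
                hsps.append(
                    HSP(
                        scaffold=scaffold,
                        strand=fr.strand,
                        g_start=g_start,
                        g_end=g_end,
                        q_start=int(qs),
                        q_end=int(qe),
                        score=float(score),
                        evalue=evalue,
                        query_id=query.query_id,
                    )
                )
    hsps.sort(key=lambda h: (h.evalue, h.scaffold, h.g_start))
    return hsps


@dataclass
class Locus:
    scaffold: str
    strand: str
    start: int
    end: int
    score: float  # summed HSP score of the best query
    query_id: str


def merge_hsps_to_loci(hsps: list[HSP], join_dist: int = 5_000) -> list[Locus]:
    """Merge same-strand HSPs within ``join_dist`` into candidate loci.

    Each locus keeps the query with the highest summed HSP score.
    """
    loci: list[Locus] = []
    by_key: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        by_key.setdefault((h.scaffold, h.strand), []).append(h)
    for (scaffold, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.g_start)
        cur: list[HSP] = []
        for h in group:
            if cur and h.g_start > max(x.g_end for x in cur) + join_dist:
                loci.append(_locus_from(cur, scaffold, strand))
                cur = []
            cur.append(h)
        if cur:
            loci.append(_locus_from(cur, scaffold, strand))
    return loci


def _locus_from(group: list[HSP], scaffold: str, strand: str) -> Locus:
    scores: dict[str, float] = {}
    for h in group:
        scores[h.query_id] = scores.get(h.query_id, 0.0) + h.score
    best_q = max(sorted(scores), key=lambda k: scores[k])
    return Locus(
        scaffold=scaffold,
        strand=strand,
        start=min(h.g_start for h in group),
        end=max(h.g_end for h in group),
        score=scores[best_q],
        query_id=best_q,
    )


# ---------------------------------------------------------------------------
# spliced gene modelling


def _trim_ends(chunks, min_avg: float, min_run: int = 5):
    """Drop terminal path segments averaging below ``min_avg`` per chunk.

    Random-DNA continuations average below zero per codon while genuine
    homology sits well above 1, so a long terminal run with a low mean
    marks chance extension past the real gene boundary.
    """
    for _ in range(2):  # once per orientation
        scores = [c[3] for c in chunks]
        cut = 0
        acc = 0.0
        for t in range(1, len(scores) + 1):
            acc += scores[-t]
            if t >= min_run and acc < min_avg * t:
                cut = t
        chunks = chunks[: len(chunks) - cut] if cut else chunks
        chunks = chunks[::-1]
    # strip non-codon chunks left dangling at the ends
    while chunks and chunks[0][2] != "codon":
        chunks = chunks[1:]
    while chunks and chunks[-1][2] != "codon":
        chunks = chunks[:-1]
    return chunks


def spliced_gene_model(
    query_protein: str,
    genomic_window: str,
    params: SearchParams | None = None,
    *,
    scaffold: str = "window",
    strand: str = "+",
    window_start: int = 0,
    scaffold_len: int | None = None,
    query_id: str = "",
) -> GeneModel:
    """Best spliced alignment of a protein to a genomic window.

    The DP is local in the genome and in the protein, with match states
    consuming 3 nt (2 or 4 with a frameshift penalty), affine codon gaps
    and GT..AG introns of at least ``min_intron`` nt.  The genomic window
    is given in forward orientation; with ``strand='-'`` it is reverse
    complemented internally and exon coordinates are reported forward.
    """
    params = params or SearchParams()
    if len(genomic_window) < 3:
        raise ValueError("genomic window shorter than one codon")
    work = genomic_window if strand == "+" else revcomp(genomic_window)
    dna = encode_dna(work)
    q = encode_aa(query_protein)
    B = BLOSUM62.astype(np.float64)
    score, bj, bi, ptrA, ptrE, ptrDn, ptrDq, donor = spliced_dp(
        dna, q, B, CODON_AA_TABLE,
        params.gap_open, params.gap_ext, params.frameshift_penalty,
        params.intron_penalty, params.min_intron, params.intron_len_cost,
    )
    def codon_score(end: int, qj: int) -> float:
        c = dna[end - 3 : end]
        if (c >= 4).any():
            return 0.0
        return float(B[q[qj - 1], CODON_AA_TABLE[c[0] * 25 + c[1] * 5 + c[2]]])

    # (start, end, kind, score) in window coords, collected 3'->5'
    chunks: list[tuple[int, int, str, float]] = []
    j, i = int(bj), int(bi)
    state = "E"
    while True:
        if state == "E":
            if j == 0:
                break
            c = ptrE[j, i]
            if c == 0:
                state = "A"
            elif c == 1:
                state = "Dn"
            else:
                p = int(donor[j, i])
                i = p
                # stay in E, same j (intron consumed)
        elif state == "A":
            c = ptrA[j, i]
            if c in (1, 2, 0):
                chunks.append((i - 3, i, "codon", codon_score(i, j)))
                j -= 1
                i -= 3
                if c == 0:
                    break
                state = "E" if c == 1 else "Dq"
            elif c == 3:
                chunks.append((i - 2, i, "fs2", -params.frameshift_penalty))
                j -= 1
                i -= 2
                state = "E"
            else:  # c == 4
                chunks.append(
                    (i - 4, i, "fs4", codon_score(i, j) - params.frameshift_penalty)
                )
                j -= 1
                i -= 4
                state = "E"
        elif state == "Dn":
            c = ptrDn[j, i]
            pen = params.gap_open if c == 1 else params.gap_ext
            chunks.append((i - 3, i, "ins", -pen))
            i -= 3
            state = "E" if c == 1 else "Dn"
        else:  # Dq
            c = ptrDq[j, i]
            pen = params.gap_open if c == 1 else params.gap_ext
            chunks.append((i, i, "qgap", -pen))
            j -= 1
            state = "E" if c == 1 else "Dq"
    chunks.reverse()
    # a model may not skip long stretches of the query between anchors:
    # runs of >= max_query_gap unmatched aa mark chance re-anchoring in
    # flanking DNA, so only the dominant segment is kept
    segments: list[list[tuple[int, int, str, float]]] = [[]]
    run = 0
    for ch in chunks:
        if ch[2] == "qgap":
            run += 1
            if run == params.max_query_gap:
                segments.append([])
            continue
        run = 0
        segments[-1].append(ch)
    chunks = max(segments, key=lambda seg: sum(e - s for s, e, _, _ in seg))
    chunks = _trim_ends(chunks, params.min_terminal_avg)
    has_fs = any(kind in ("fs2", "fs4") for _, _, kind, _ in chunks)
    if not chunks:
        raise ValueError("no alignment found in window")
    # merge contiguous chunks into exons (window coords)
    exons_w: list[list[int]] = []
    for s, e, _, _ in chunks:
        if e == s:
            continue
        if exons_w and s == exons_w[-1][1]:
            exons_w[-1][1] = e
        else:
            exons_w.append([s, e])
    protein_parts = []
    for s, e, kind, _ in chunks:
        if kind in ("codon", "ins", "fs4"):
            cod = work[max(e - 3, s) : e]
            aa = CODON_AA_TABLE[
                encode_dna(cod)[0] * 25 + encode_dna(cod)[1] * 5 + encode_dna(cod)[2]
            ]
            protein_parts.append(AA_ALPHABET[aa])
        elif kind == "fs2":
            protein_parts.append("X")
    protein = "".join(protein_parts)
    cds_len = sum(e - s for s, e in exons_w)
    W = len(genomic_window)
    if strand == "+":
        exons = [(window_start + s, window_start + e) for s, e in exons_w]
    else:
        exons = sorted((window_start + W - e, window_start + W - s) for s, e in exons_w)
    at_edge = False
    if scaffold_len is not None:
        at_edge = exons[0][0] <= 2 or exons[-1][1] >= scaffold_len - 2
    model = GeneModel(
        model_id="",
        scaffold=scaffold,
        strand=strand,
        exons=exons,
        cds_len=cds_len,
        protein=protein,
        query_id=query_id,
        score=float(score),
        has_stop="*" in protein,
        has_frameshift=has_fs,
        at_scaffold_edge=at_edge,
    )
    model.status = call_status(model, params)
    return model


def call_status(model: GeneModel, params: SearchParams | None = None) -> str:
    """Intact/pseudogene call.

    too_short iff CDS < 600 nt (strict); otherwise pseudo_frameshift /
    pseudo_stop if flagged (a detected indel takes precedence, since
    frameshifts routinely create premature stops downstream); partial
    for scaffold-edge truncations; else intact.
    """
    params = params or SearchParams()
    if model.cds_len < params.min_cds_len:
        return "too_short"
    if model.has_frameshift:
        return "pseudo_frameshift"
    if model.has_stop:
        return "pseudo_stop"
    if model.at_scaffold_edge:
        return "partial"
    return "intact"


def merge_models(models: list[GeneModel]) -> list[GeneModel]:
    """Collapse models overlapping reciprocally >= 50% of their extents.

    The survivor is the highest score, ties broken by longest CDS then
    smallest start.
    """
    ranked = sorted(
        models, key=lambda m: (-m.score, -m.cds_len, m.scaffold, m.start)
    )
    kept: list[GeneModel] = []
    for m in ranked:
        clash = False
        for k in kept:
            if k.scaffold != m.scaffold:
                continue
            ov = min(k.end, m.end) - max(k.start, m.start)
            if ov <= 0:
                continue
            if ov >= 0.5 * (k.end - k.start) and ov >= 0.5 * (m.end - m.start):
                clash = True
                break
        if not clash:
            kept.append(m)
    kept.sort(key=lambda m: (m.scaffold, m.start))
    return kept


def mine_genome(
    genome: dict[str, str],
    queries: list[TMQuery],
    params: SearchParams | None = None,
) -> list[GeneModel]:
    """Full mining pass: search all queries, model each locus, deduplicate."""
    params = params or SearchParams()
    frames = {name: six_frame_translate(s) for name, s in genome.items()}
    n_aa = sum(len(fr.aa) for fs in frames.values() for fr in fs)
    all_hsps: list[HSP] = []
    for query in queries:
        all_hsps.extend(
            seeded_search(query, genome, params, frames_by_scaffold=frames,
                          search_space_aa=n_aa)
        )
    loci = merge_hsps_to_loci(all_hsps, params.locus_join_dist)
    qmap = {q.query_id: q.sequence for q in queries}
    models = []
    for locus in loci:
        seq = genome[locus.scaffold]
        ws = max(locus.start - params.window_pad, 0)
        we = min(locus.end + params.window_pad, len(seq))
        try:
            model = spliced_gene_model(
                qmap[locus.query_id],
                seq[ws:we],
                params,
                scaffold=locus.scaffold,
                strand=locus.strand,
                window_start=ws,
                scaffold_len=len(seq),
                query_id=locus.query_id,
            )
        except ValueError:
            continue
        models.append(model)
    models = merge_models(models)
    for i, m in enumerate(models):
        m.model_id = f"m{i:04d}"
    return models


def models_to_gff3(models: list[GeneModel]) -> str:
    lines = ["##gff-version 3"]
    for m in models:
        attrs = f"ID={m.model_id};status={m.status};query={m.query_id}"
        lines.append(
            "\t".join(
                [m.scaffold, "v2rscan", "gene", str(m.start + 1), str(m.end),
                 f"{m.score:.1f}", m.strand, ".", attrs]
            )
        )
        for k, (s, e) in enumerate(m.exons):
            lines.append(
                "\t".join(
                    [m.scaffold, "v2rscan", "CDS", str(s + 1), str(e), ".",
                     m.strand, ".", f"ID={m.model_id}.cds{k};Parent={m.model_id}"]
                )
            )
    return "\n".join(lines) + "\n"
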