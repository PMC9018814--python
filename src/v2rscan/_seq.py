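"""Low-level sequence utilities shared across modules.

Encodings are fixed once here: amino acids 0-19 in alphabetical order,
``X`` = 20, ``*`` (stop) = 21; nucleotides A,C,G,T = 0-3, N = 4.  The
scoring matrix is BLOSUM62 re-indexed into this alphabet.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = AA20 + "X*"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
X_IDX = 20
STOP_IDX = 21

NT_ALPHABET = "ACGTN"
NT_INDEX = {c: i for i, c in enumerate(NT_ALPHABET)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def _build_blosum62() -> np.ndarray:
    src = substitution_matrices.load("BLOSUM62")
    m = np.zeros((22, 22), dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            m[i, j] = int(src[a, b])
    return m


BLOSUM62 = _build_blosum62()

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon string -> amino-acid letter (stops map to '*')
CODON_TO_AA = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: fixed deterministic back-translation: lexicographically smallest codon
BACKTRANSLATE = {}
for _codon in sorted(CODON_TO_AA):
    _aa = CODON_TO_AA[_codon]
    if _aa != "*" and _aa not in BACKTRANSLATE:
        BACKTRANSLATE[_aa] = _codon
STOP_CODON = "TAA"


def _build_codon_aa_table() -> np.ndarray:
    """Map codon code (base-5 over ACGTN, 125 entries) -> aa index.

    Codons containing N translate to X.
    """
    tab = np.full(125, X_IDX, dtype=np.int8)
    for c0 in range(4):
        for c1 in range(4):
            for c2 in range(4):
                codon = NT_ALPHABET[c0] + NT_ALPHABET[c1] + NT_ALPHABET[c2]
                tab[c0 * 25 + c1 * 5 + c2] = AA_INDEX[CODON_TO_AA[codon]]
    return tab


CODON_AA_TABLE = _build_codon_aa_table()

#: background amino-acid frequencies implied by uniform-ACGT DNA read in
#: frame (61 sense codons + stops; stops excluded, rest renormalised)
_counts = np.zeros(20)
for _codon, _aa in CODON_TO_AA.items():
    if _aa != "*":
        _counts[AA_INDEX[_aa]] += 1.0
AA_BACKGROUND = _counts / _counts.sum()


def encode_aa(seq: str) -> np.ndarray:
    try:
        return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"non-amino-acid symbol {exc} in sequence") from exc


def encode_dna(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for ch, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[arr == ord(ch)] = code
    return out


def translate_codes(dna_codes: np.ndarray) -> np.ndarray:
    """Translate an encoded in-frame DNA array to aa indices (len//3)."""
    n = len(dna_codes) // 3
    trimmed = dna_codes[: n * 3].reshape(n, 3).astype(np.int32)
    codes = trimmed[:, 0] * 25 + trimmed[:, 1] * 5 + trimmed[:, 2]
    return CODON_AA_TABLE[codes]


def translate(dna: str) -> str:
    aa = translate_codes(encode_dna(dna))
    return "".join(AA_ALPHABET[i] for i in aa)


def backtranslate(protein: str) -> str:
    return "".join(BACKTRANSLATE[a] for a in protein)


def decode_aa(codes: np.ndarray) -> str:
    return "".join(AA_ALPHABET[i] for i in codes)
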