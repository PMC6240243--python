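"""Codon state space and the MG94-style codon substitution model.

The model crosses a general-reversible nucleotide exchangeability pattern
in which A<->C, A<->G and C<->G are fixed to 1 while A<->T, C<->T and G<->T
carry free parameters (R_AT, R_CT, R_GT) with a synonymous/nonsynonymous
rate decomposition: a single-nucleotide codon change a -> b at position p
has rate

    q_ab = R[nt_a, nt_b] * f_p(nt_b) * (dS if synonymous else dN),

where ``f_p`` are position-specific nucleotide frequencies (F3x4).  Stop
codons are excluded from the state space; multi-nucleotide changes have
rate 0.  The matrix is reversible with stationary distribution
proportional to the product of position frequencies, which permits a
symmetric eigendecomposition.  Rate matrices are normalized so that the
neutral model (dS = dN = 1) has one expected substitution per codon per
unit branch length; dS/dN class values therefore act as relative rates.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

from .alignments import GAP, CodonAlignment

__all__ = [
    "SENSE_CODONS",
    "codon_index",
    "f3x4_frequencies",
    "mg94_rate_matrix",
    "codon_stationary",
    "encode_codon_alignment",
]

NUCLEOTIDES = "ACGT"
NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

_table = CodonTable.unambiguous_dna_by_id[1]  # universal code
STOPS = set(_table.stop_codons)
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3) if "".join(c) not in STOPS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_OF = {c: _table.forward_table[c] for c in SENSE_CODONS}
N_CODONS = len(SENSE_CODONS)  # 61


def codon_index(codon: str) -> int:
    return CODON_INDEX[codon]


def _nt_exchangeability(r_at: float, r_ct: float, r_gt: float) -> np.ndarray:
    R = np.ones((4, 4))
    np.fill_diagonal(R, 0.0)
    for a, b, val in (("A", "T", r_at), ("C", "T", r_ct), ("G", "T", r_gt)):
        R[NT_INDEX[a], NT_INDEX[b]] = R[NT_INDEX[b], NT_INDEX[a]] = val
    return R


def f3x4_frequencies(alignment: CodonAlignment, pseudocount: float = 1.0) -> np.ndarray:
    """Position-specific nucleotide frequencies (3, 4) from an alignment."""
    counts = np.full((3, 4), pseudocount)
    mat = alignment.matrix
    for p in range(3):
        cols = mat[:, p::3]
        for k, nt in enumerate(NUCLEOTIDES):
            counts[p, k] += (cols == nt).sum()
    return counts / counts.sum(axis=1, keepdims=True)


def codon_stationary(pos_freqs: np.ndarray) -> np.ndarray:
    """Stationary codon distribution: product of position frequencies."""
    pi = np.array(
        [
            pos_freqs[0, NT_INDEX[c[0]]]
            * pos_freqs[1, NT_INDEX[c[1]]]
            * pos_freqs[2, NT_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def _single_change_structure():
    """Index arrays over single-nucleotide codon changes (vectorized Q build)."""
    rows = []
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if a[p] != b[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            rows.append((i, j, p, NT_INDEX[a[p]], NT_INDEX[b[p]], AA_OF[a] == AA_OF[b]))
    arr = np.array(rows, dtype=int)
    return {
        "i": arr[:, 0],
        "j": arr[:, 1],
        "pos": arr[:, 2],
        "nt_from": arr[:, 3],
        "nt_to": arr[:, 4],
        "syn": arr[:, 5].astype(bool),
    }

_STRUCTURE = _single_change_structure()


def mg94_rate_matrix(
    r_at: float,
    r_ct: float,
    r_gt: float,
    pos_freqs: np.ndarray,
    ds: float = 1.0,
    dn: float = 1.0,
    normalization: float | None = None,
) -> tuple[np.ndarray, float]:
    """(Q, norm): codon rate matrix for one (dS, dN) class.

    ``normalization`` is the neutral-model mean rate used to scale Q; pass
    the value returned for the (1, 1) class so all grid cells share one
    time scale, or None to compute it here.
    """
    if min(r_at, r_ct, r_gt) <= 0:
        raise ValueError("exchangeability parameters must be positive")
    if ds < 0 or dn < 0:
        raise ValueError("class rates must be non-negative")
    R = _nt_exchangeability(r_at, r_ct, r_gt)
    st = _STRUCTURE
    base = R[st["nt_from"], st["nt_to"]] * pos_freqs[st["pos"], st["nt_to"]]
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[st["i"], st["j"]] = base * np.where(st["syn"], ds, dn)
    pi = codon_stationary(pos_freqs)
    if normalization is None:
        normalization = float((pi[st["i"]] * base).sum())
    Q /= normalization
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, normalization


def encode_codon_alignment(alignment: CodonAlignment) -> np.ndarray:
    """(n_seq, n_sites) codon state indices; -1 marks gap/ambiguous codons."""
    n_seq = alignment.n_sequences
    n_sites = alignment.n_codons
    out = np.full((n_seq, n_sites), -1, dtype=int)
    for i in range(n_seq):
        row = "".join(alignment.matrix[i])
        for s in range(n_sites):
            codon = row[3 * s : 3 * s + 3]
            if GAP in codon or codon not in CODON_INDEX:
                continue
            out[i, s] = CODON_INDEX[codon]
    return out
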