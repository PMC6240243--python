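"""Reverse conservation analysis (RCA).

RCA locates poorly conserved stretches of a protein alignment and, when
two paralog groups are profiled side by side, regions of putative
functional divergence.  The per-column statistic is an empirical-Bayes
posterior mean evolutionary rate (the S score: *high = poorly conserved*),
computed under a fixed amino-acid substitution model with a discretized
gamma prior over site rates:

    S_c = sum_k r_k P(column c | r_k) p_k  /  sum_k P(column c | r_k) p_k.

Scores are z-normalized over the included columns (population mean 0,
sd 1), averaged in a centred sliding window of width ``n = 7`` (the W
mean), and maximal runs of W >= I (default intensity threshold I = 0.5)
become variable regions.  Columns gapped in more than half of the
sequences are excluded before any scoring.  The two-group classifier
labels a region *divergent in A* when the region-mean W is >= I in group A
but < I in group B (and symmetrically), *variable in both* or *conserved
in both* otherwise.

Usage follows the Model / Results idiom::

    profile = ReverseConservation(aln, tree=guide, reference_id="ref").fit()
    profile.variable_regions()               # list of VariableRegion
    call_divergent_regions(profile_a, profile_b)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _phylo
from .aamodel import AA_INDEX, ReversibleMatrix, aa_rate_matrix, discrete_gamma_rates
from .alignments import (
    AMINO_ACIDS,
    GAP,
    Alignment,
    ReferenceCoordinateMap,
    map_to_reference,
)
from .trees import BaseTree, GeneTree

__all__ = [
    "mask_gappy_columns",
    "site_rates",
    "normalize_and_window",
    "nj_guide_tree",
    "ReverseConservation",
    "ConservationProfile",
    "VariableRegion",
    "DivergenceCall",
    "call_variable_regions",
    "call_divergent_regions",
]

ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
]


def _roman(k: int) -> str:
    return ROMAN[k] if k < len(ROMAN) else f"R{k + 1}"


def mask_gappy_columns(alignment: Alignment, max_gap_fraction: float = 0.5) -> np.ndarray:
    """Boolean inclusion mask: True where gap fraction <= threshold."""
    if alignment.n_sequences == 0:
        raise ValueError("empty alignment")
    return alignment.gap_fraction() <= max_gap_fraction


def nj_guide_tree(alignment: Alignment) -> GeneTree:
    """Neighbor-joining guide tree from pairwise identity-fraction distances.

    Declared plumbing for when no tree is supplied: p-distances over
    mutually ungapped columns, NJ via scikit-bio, negative branch lengths
    clamped to zero, arbitrarily rooted at the NJ root.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    mat = alignment.matrix
    n = alignment.n_sequences
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] != GAP) & (mat[j] != GAP)
            if ok.sum() == 0:
                d = 1.0
            else:
                d = float((mat[i][ok] != mat[j][ok]).mean())
            D[i, j] = D[j, i] = d
    tree = nj(DistanceMatrix(D, ids=alignment.ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    newick = str(tree).strip()
    return GeneTree.from_newick(newick, species_map={i: i for i in alignment.ids})


def _encode_protein(alignment: Alignment, included: np.ndarray) -> dict[str, np.ndarray]:
    cols = np.nonzero(included)[0]
    out = {}
    for i, sid in enumerate(alignment.ids):
        row = alignment.matrix[i, cols]
        codes = np.array([AA_INDEX.get(ch, -1) for ch in row], dtype=int)
        out[sid] = codes
    return out


def site_rates(
    alignment: Alignment,
    tree: BaseTree,
    included: np.ndarray | None = None,
    alpha: float = 1.0,
    n_rate_categories: int = 16,
    freqs: str | np.ndarray = "empirical",
) -> np.ndarray:
    """Raw S scores (posterior mean relative rates) for included columns.

    ``freqs`` may be "empirical" (alignment amino-acid composition),
    "uniform", or an explicit 20-vector.
    """
    if set(tree.tip_labels) != set(alignment.ids):
        raise ValueError("tree tips and alignment ids must match")
    if included is None:
        included = np.ones(alignment.n_columns, dtype=bool)
    if isinstance(freqs, str):
        if freqs == "empirical":
            counts = np.array([(alignment.matrix == aa).sum() for aa in AMINO_ACIDS], float)
            pi0 = counts / counts.sum() if counts.sum() else None
        elif freqs == "uniform":
            pi0 = None
        else:
            raise ValueError(f"unknown freqs option {freqs!r}")
    else:
        pi0 = np.asarray(freqs, float)
    Q, pi = aa_rate_matrix(pi0)
    rev = ReversibleMatrix(Q, pi)
    rates = discrete_gamma_rates(alpha, n_rate_categories)
    codes = _encode_protein(alignment, included)
    n_sites = int(included.sum())
    log_lik = np.empty((n_rate_categories, n_sites))
    for k, r in enumerate(rates):
        log_lik[k] = _phylo.site_log_likelihoods(
            tree, codes, lambda t, r=r: rev.transition_matrix(r * t), pi
        )
    # posterior mean rate with uniform category prior
    m = log_lik.max(axis=0)
    w = np.exp(log_lik - m[None, :])
    return (rates[:, None] * w).sum(axis=0) / w.sum(axis=0)


@dataclass(frozen=True)
class VariableRegion:
    """Maximal run of W mean >= I, in 1-based inclusive reference coords."""

    start: int
    end: int
    peak_w: float
    label: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start must be <= end")


@dataclass(frozen=True)
class DivergenceCall:
    """Two-group classification of one region."""

    start: int
    end: int
    category: str  # divergent-in-A | divergent-in-B | variable-in-both | conserved-in-both
    mean_w_a: float
    mean_w_b: float


@dataclass
class ConservationProfile:
    """Per-column conservation scores of one alignment/group.

    ``raw_s``, ``normalized`` and ``w_mean`` are full-alignment-length
    arrays with NaN at excluded columns; ``included`` is the column mask.
    """

    raw_s: np.ndarray
    normalized: np.ndarray
    w_mean: np.ndarray
    included: np.ndarray
    reference: ReferenceCoordinateMap | None = None
    degenerate: bool = False
    window: int = 7

    @property
    def n_columns(self) -> int:
        return len(self.included)

    def reference_position(self, column: int) -> int | None:
        """1-based reference residue of a 1-based column (None if unmapped)."""
        if self.reference is None:
            return column
        return self.reference.residue_of(column)

    def w_by_reference(self) -> dict[int, float]:
        """W mean per mapped reference residue over included columns."""
        out = {}
        for col in np.nonzero(self.included)[0]:
            pos = self.reference_position(col + 1)
            if pos is not None:
                out[pos] = float(self.w_mean[col])
        return out

    def variable_regions(self, intensity: float = 0.5, min_gap: int = 3) -> list[VariableRegion]:
        return call_variable_regions(self, intensity=intensity, min_gap=min_gap)

    def to_frame(self) -> pd.DataFrame:
        cols = np.arange(1, self.n_columns + 1)
        refpos = [self.reference_position(c) or 0 for c in cols]
        return pd.DataFrame(
            {
                "alignment_col": cols,
                "reference_pos": refpos,
                "raw_S": self.raw_s,
                "normalized": self.normalized,
                "W_mean": self.w_mean,
                "included": self.included.astype(int),
            }
        )


def normalize_and_window(
    raw_s: np.ndarray,
    included: np.ndarray,
    window: int = 7,
    reference: ReferenceCoordinateMap | None = None,
) -> ConservationProfile:
    """Z-normalize raw scores and apply the centred sliding-window mean.

    Normalization uses the population standard deviation over included
    columns.  The window runs over included columns in alignment order and
    shrinks symmetrically at the edges (at most ``window // 2`` neighbours
    each side).  Zero-variance input yields all-zero scores and a
    degenerate flag.
    """
    included = np.asarray(included, bool)
    n_cols = len(included)
    idx = np.nonzero(included)[0]
    if idx.size == 0:
        raise ValueError("no included columns")
    raw_s = np.asarray(raw_s, float)
    if raw_s.shape[0] == n_cols:
        vals = raw_s[idx]
        full_raw = np.where(included, raw_s, np.nan)
    elif raw_s.shape[0] == idx.size:
        vals = raw_s
        full_raw = np.full(n_cols, np.nan)
        full_raw[idx] = vals
    else:
        raise ValueError("raw_s length matches neither alignment nor included columns")
    sd = float(vals.std())  # population sd
    degenerate = sd < 1e-12
    z = np.zeros_like(vals) if degenerate else (vals - vals.mean()) / sd
    half = window // 2
    w = np.empty_like(z)
    for i in range(len(z)):
        lo = max(0, i - half)
        hi = min(len(z), i + half + 1)
        w[i] = z[lo:hi].mean()
    normalized = np.full(n_cols, np.nan)
    w_mean = np.full(n_cols, np.nan)
    normalized[idx] = z
    w_mean[idx] = w
    return ConservationProfile(
        raw_s=full_raw,
        normalized=normalized,
        w_mean=w_mean,
        included=included,
        reference=reference,
        degenerate=degenerate,
        window=window,
    )


def call_variable_regions(
    profile: ConservationProfile, intensity: float = 0.5, min_gap: int = 3
) -> list[VariableRegion]:
    """Maximal runs of included columns with W mean >= intensity.

    Runs separated by fewer than ``min_gap`` included sub-threshold columns
    are merged.  Coordinates are 1-based inclusive reference residues; a
    run none of whose columns maps to the reference is dropped.
    """
    if profile.degenerate:
        return []
    idx = np.nonzero(profile.included)[0]
    above = profile.w_mean[idx] >= intensity
    runs: list[list[int]] = []  # positions into idx
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(above) - 1])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < min_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    regions = []
    for run in merged:
        cols = idx[run[0] : run[1] + 1] + 1  # 1-based columns
        positions = [p for c in cols if (p := profile.reference_position(int(c))) is not None]
        if not positions:
            continue
        peak = float(np.nanmax(profile.w_mean[cols - 1]))
        regions.append(
            VariableRegion(
                start=min(positions), end=max(positions), peak_w=peak, label=_roman(len(regions))
            )
        )
    return regions


def call_divergent_regions(
    profile_a: ConservationProfile,
    profile_b: ConservationProfile,
    intensity: float = 0.5,
    min_gap: int = 3,
) -> list[DivergenceCall]:
    """Classify regions variable in either group by the two-group I rule.

    Both profiles must be mapped to the same reference sequence (each
    group may be aligned separately).  For every variable region found in
    either group, the region-mean W of each group over its covered
    reference positions decides the class.
    """
    w_a = profile_a.w_by_reference()
    w_b = profile_b.w_by_reference()
    if not (set(w_a) & set(w_b)):
        raise ValueError("profiles share no reference positions")
    intervals = [
        (r.start, r.end)
        for r in (
            profile_a.variable_regions(intensity, min_gap)
            + profile_b.variable_regions(intensity, min_gap)
        )
    ]
    intervals.sort()
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    calls = []
    for s, e in merged:
        in_a = [w_a[p] for p in range(s, e + 1) if p in w_a]
        in_b = [w_b[p] for p in range(s, e + 1) if p in w_b]
        mean_a = float(np.mean(in_a)) if in_a else np.nan
        mean_b = float(np.mean(in_b)) if in_b else np.nan
        hi_a = bool(mean_a >= intensity) if in_a else False
        hi_b = bool(mean_b >= intensity) if in_b else False
        if hi_a and not hi_b:
            cat = "divergent-in-A"
        elif hi_b and not hi_a:
            cat = "divergent-in-B"
        elif hi_a and hi_b:
            cat = "variable-in-both"
        else:
            cat = "conserved-in-both"
        calls.append(DivergenceCall(start=s, end=e, category=cat, mean_w_a=mean_a, mean_w_b=mean_b))
    return calls


class ReverseConservation:
    """RCA model for one alignment (one paralog group).

    Parameters
    ----------
    alignment : protein :class:`Alignment`.
    tree : guide tree with branch lengths; an identity-fraction NJ tree is
        built when omitted.
    reference_id : sequence whose residue numbering anchors region
        coordinates (defaults to alignment-column coordinates).
    alpha : gamma shape of the site-rate prior (default 1.0).
    n_rate_categories : discretization resolution (default 16).
    max_gap_fraction : columns with a larger gap share are excluded (0.5).
    window : sliding-window width for the W mean (7).
    """

    def __init__(
        self,
        alignment: Alignment,
        tree: BaseTree | None = None,
        reference_id: str | None = None,
        alpha: float = 1.0,
        n_rate_categories: int = 16,
        max_gap_fraction: float = 0.5,
        window: int = 7,
        freqs: str | np.ndarray = "empirical",
    ):
        self.alignment = alignment
        self.tree = tree if tree is not None else nj_guide_tree(alignment)
        self.reference_id = reference_id
        self.alpha = alpha
        self.n_rate_categories = n_rate_categories
        self.max_gap_fraction = max_gap_fraction
        self.window = window
        self.freqs = freqs

    def fit(self) -> ConservationProfile:
        included = mask_gappy_columns(self.alignment, self.max_gap_fraction)
        raw = site_rates(
            self.alignment,
            self.tree,
            included=included,
            alpha=self.alpha,
            n_rate_categories=self.n_rate_categories,
            freqs=self.freqs,
        )
        ref = (
            map_to_reference(self.alignment, self.reference_id)
            if self.reference_id is not None
            else None
        )
        return normalize_and_window(raw, included, window=self.window, reference=ref)
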