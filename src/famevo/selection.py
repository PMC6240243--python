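"""Random-effects-likelihood (REL) scan for site-wise selection.

Sites of an in-frame codon alignment are modelled as draws from a discrete
grid of (dS, dN) rate classes: independent class-value/weight vectors for
dS and dN are crossed into a K_s x K_n grid, and the likelihood of site
``s`` is sum_g w_g P(site_s | dS_g, dN_g, theta) with theta the nucleotide
exchangeabilities (R_AT, R_CT, R_GT; A<->C = A<->G = C<->G = 1), a global
branch-length scale on the fixed input topology, and F3x4 codon
frequencies.  Fitting alternates EM updates of the grid weights with
bounded quasi-Newton updates of the continuous parameters; the
log-likelihood is non-decreasing across iterations.

Per-site empirical-Bayes posteriors over the grid give the posterior
probability of positive selection PP = P(dN > dS | site) and the Bayes
factor

    BF+ = [PP / (1 - PP)] / [pi+ / (1 - pi+)],    pi+ = prior mass of dN > dS,

with the symmetric BF- for negative selection (dN < dS).  Sites are
classified strong positive (BF+ >= 50), weak positive (10 <= BF+ < 50),
negative (BF- >= 50 and not positive), else neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _phylo
from .aamodel import ReversibleMatrix
from .alignments import GAP, CodonAlignment
from .codon import (
    codon_stationary,
    encode_codon_alignment,
    f3x4_frequencies,
    mg94_rate_matrix,
)
from .trees import BaseTree

__all__ = [
    "RelCodonModel",
    "RelSiteSelection",
    "RelResults",
    "fit_rel_model",
    "site_bayes_factors",
    "classify_sites",
]


@dataclass
class RelCodonModel:
    """Parameters of the fitted REL codon model."""

    r_at: float
    r_ct: float
    r_gt: float
    branch_scale: float
    ds_values: np.ndarray
    ds_weights: np.ndarray
    dn_values: np.ndarray
    dn_weights: np.ndarray
    pos_freqs: np.ndarray
    llf: float = np.nan
    converged: bool = False
    n_iter: int = 0
    loglike_path: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("ds_weights", "dn_weights"):
            w = np.asarray(getattr(self, name), float)
            if not np.isclose(w.sum(), 1.0):
                raise ValueError(f"{name} must sum to 1")
            setattr(self, name, w)
        if min(self.r_at, self.r_ct, self.r_gt) <= 0:
            raise ValueError("exchangeability parameters must be positive")
        self.ds_values = np.asarray(self.ds_values, float)
        self.dn_values = np.asarray(self.dn_values, float)
        if (self.ds_values < 0).any() or (self.dn_values < 0).any():
            raise ValueError("class values must be non-negative")

    # -- grid geometry ------------------------------------------------
    def grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ds_g, dn_g, w_g) flattened over the K_s x K_n grid."""
        ds = np.repeat(self.ds_values, len(self.dn_values))
        dn = np.tile(self.dn_values, len(self.ds_values))
        w = np.outer(self.ds_weights, self.dn_weights).ravel()
        return ds, dn, w

    def positive_mask(self) -> np.ndarray:
        ds, dn, _ = self.grid()
        return dn > ds

    def negative_mask(self) -> np.ndarray:
        ds, dn, _ = self.grid()
        return dn < ds

    @property
    def prior_positive(self) -> float:
        _, _, w = self.grid()
        return float(w[self.positive_mask()].sum())

    @property
    def prior_negative(self) -> float:
        _, _, w = self.grid()
        return float(w[self.negative_mask()].sum())

    def to_dict(self) -> dict:
        return {
            "R_AT": self.r_at,
            "R_CT": self.r_ct,
            "R_GT": self.r_gt,
            "branch_scale": self.branch_scale,
            "dS_values": self.ds_values.tolist(),
            "dS_weights": self.ds_weights.tolist(),
            "dN_values": self.dn_values.tolist(),
            "dN_weights": self.dn_weights.tolist(),
            "logL": self.llf,
            "converged": self.converged,
        }


def _grid_site_loglikes(
    tree: BaseTree,
    tip_codes: dict[str, np.ndarray],
    model: RelCodonModel,
) -> np.ndarray:
    """(n_cells, n_sites) per-cell site log-likelihoods."""
    pi = codon_stationary(model.pos_freqs)
    _, norm = mg94_rate_matrix(model.r_at, model.r_ct, model.r_gt, model.pos_freqs, 1.0, 1.0)
    ds_g, dn_g, _ = model.grid()
    revs = []
    for ds, dn in zip(ds_g, dn_g):
        Q, _ = mg94_rate_matrix(
            model.r_at, model.r_ct, model.r_gt, model.pos_freqs, ds, dn, normalization=norm
        )
        revs.append(ReversibleMatrix(Q, pi))
    mats = {
        node.index: np.stack(
            [rev.transition_matrix(model.branch_scale * (node.length or 0.0)) for rev in revs]
        )
        for node in tree.postorder()
        if node is not tree.root
    }
    return _phylo.site_log_likelihoods_batched(tree, tip_codes, mats, pi)


def _mixture_loglike(cell_ll: np.ndarray, weights: np.ndarray, pattern_weights: np.ndarray) -> float:
    m = cell_ll.max(axis=0)
    mix = np.log((weights[:, None] * np.exp(cell_ll - m[None, :])).sum(axis=0)) + m
    return float((mix * pattern_weights).sum())


class RelSiteSelection:
    """REL site-selection model for one codon alignment on a fixed tree.

    Parameters
    ----------
    alignment : :class:`CodonAlignment` (in frame, no internal stops).
    tree : rooted tree with branch lengths whose tips match the alignment
        ids; only a global scale of its branch lengths is re-estimated.
    n_ds_classes, n_dn_classes : grid resolution (default 3 x 3).
    reference_id : optional sequence anchoring reported site positions.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: BaseTree,
        n_ds_classes: int = 3,
        n_dn_classes: int = 3,
        reference_id: str | None = None,
    ):
        if alignment.n_sequences < 3:
            raise ValueError("at least 3 sequences are required")
        if set(tree.tip_labels) != set(alignment.ids):
            raise ValueError("tree tips and alignment ids must match")
        self.alignment = alignment
        self.tree = tree
        self.n_ds = n_ds_classes
        self.n_dn = n_dn_classes
        self.reference_id = reference_id
        self.pos_freqs = f3x4_frequencies(alignment)
        codes = encode_codon_alignment(alignment)
        # compress to unique site patterns
        patterns, inverse, counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self._pattern_codes = {
            sid: patterns[:, i] for i, sid in enumerate(alignment.ids)
        }
        self._pattern_inverse = inverse
        self._pattern_weights = counts.astype(float)

    # -- likelihood ---------------------------------------------------
    def _cell_loglikes(self, model: RelCodonModel) -> np.ndarray:
        return _grid_site_loglikes(self.tree, self._pattern_codes, model)

    def loglike(self, model: RelCodonModel) -> float:
        _, _, w = model.grid()
        return _mixture_loglike(self._cell_loglikes(model), w, self._pattern_weights)

    # -- fitting ------------------------------------------------------
    def _initial(self, rng: np.random.Generator | None) -> RelCodonModel:
        ds = np.linspace(0.5, 1.5, self.n_ds)
        dn = np.geomspace(0.1, 3.0, self.n_dn) if self.n_dn > 1 else np.array([1.0])
        if rng is not None:
            ds = ds * np.exp(rng.normal(0, 0.25, self.n_ds))
            dn = dn * np.exp(rng.normal(0, 0.25, self.n_dn))
        return RelCodonModel(
            r_at=1.0,
            r_ct=1.0,
            r_gt=1.0,
            branch_scale=1.0,
            ds_values=np.sort(ds),
            ds_weights=np.full(self.n_ds, 1.0 / self.n_ds),
            dn_values=np.sort(dn),
            dn_weights=np.full(self.n_dn, 1.0 / self.n_dn),
            pos_freqs=self.pos_freqs,
        )

    def _normalize(self, model: RelCodonModel) -> RelCodonModel:
        """Fix the scale degeneracy: weighted-mean dS = 1."""
        m = float((model.ds_weights * model.ds_values).sum())
        if m <= 0:
            return model
        model.ds_values = model.ds_values / m
        model.dn_values = model.dn_values / m
        model.branch_scale = model.branch_scale * m
        return model

    def _em_weights(self, model: RelCodonModel, cell_ll: np.ndarray, n_steps: int = 30):
        """Closed-form EM on the two weight simplices; returns new weights."""
        ws, wn = model.ds_weights.copy(), model.dn_weights.copy()
        lik = np.exp(cell_ll - cell_ll.max(axis=0, keepdims=True))  # (cells, sites)
        pw = self._pattern_weights
        for _ in range(n_steps):
            w = np.outer(ws, wn).ravel()
            post = w[:, None] * lik
            post /= post.sum(axis=0, keepdims=True)
            resp = (post * pw[None, :]).sum(axis=1).reshape(self.n_ds, self.n_dn)
            ws = resp.sum(axis=1) / resp.sum()
            wn = resp.sum(axis=0) / resp.sum()
        return ws, wn

    def fit(
        self,
        n_restarts: int = 3,
        max_outer: int = 8,
        tol: float = 1e-6,
        seed: int = 0,
        inner_maxiter: int = 12,
    ) -> "RelResults":
        """Alternating maximization; best of ``n_restarts`` seeded starts."""
        rng = np.random.default_rng(seed)
        best = None
        for restart in range(max(1, n_restarts)):
            model = self._initial(None if restart == 0 else rng)
            model = self._fit_one(model, max_outer, tol, inner_maxiter)
            if best is None or model.llf > best.llf:
                best = model
        return RelResults(self, best)

    def _fit_one(self, model, max_outer, tol, inner_maxiter) -> RelCodonModel:
        model = self._normalize(model)
        ll = self.loglike(model)
        path = [ll]
        n_iter = 0
        converged = False
        for it in range(max_outer):
            # (a) EM on weights: guaranteed non-decreasing given fixed cell_ll
            cell_ll = self._cell_loglikes(model)
            ws, wn = self._em_weights(model, cell_ll)
            model.ds_weights, model.dn_weights = ws, wn
            # (b) continuous parameters; revert if no improvement
            model = self._optimize_continuous(model, inner_maxiter)
            model = self._normalize(model)
            new_ll = self.loglike(model)
            if new_ll < path[-1] - 1e-7:
                raise RuntimeError("log-likelihood decreased during fitting")
            path.append(new_ll)
            n_iter = it + 1
            if abs(new_ll - ll) < tol:
                converged = True
                ll = new_ll
                break
            ll = new_ll
        model.llf = ll
        model.loglike_path = path
        model.n_iter = n_iter
        model.converged = converged
        return model

    def _optimize_continuous(self, model: RelCodonModel, maxiter: int) -> RelCodonModel:
        kd, kn = self.n_ds, self.n_dn
        x0 = np.log(
            np.concatenate(
                [
                    [model.r_at, model.r_ct, model.r_gt, model.branch_scale],
                    np.maximum(model.ds_values, 1e-4),
                    np.maximum(model.dn_values, 1e-4),
                ]
            )
        )

        def unpack(x):
            v = np.exp(x)
            m = RelCodonModel(
                r_at=v[0],
                r_ct=v[1],
                r_gt=v[2],
                branch_scale=v[3],
                ds_values=v[4 : 4 + kd],
                ds_weights=model.ds_weights,
                dn_values=v[4 + kd : 4 + kd + kn],
                dn_weights=model.dn_weights,
                pos_freqs=self.pos_freqs,
            )
            return m

        def objective(x):
            return -self.loglike(unpack(x))

        f0 = objective(x0)
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(-5, 5)] * len(x0),
            options={"maxiter": maxiter, "maxfun": 40},
        )
        if res.fun < f0:
            return unpack(res.x)
        return unpack(x0)


class RelResults:
    """Fitted REL scan: per-site posteriors, Bayes factors, categories."""

    def __init__(self, spec: RelSiteSelection, model: RelCodonModel):
        self.spec = spec
        self.model = model
        self._site_table: pd.DataFrame | None = None

    @property
    def llf(self) -> float:
        return self.model.llf

    @property
    def params(self) -> dict:
        return self.model.to_dict()

    # -- posteriors ---------------------------------------------------
    def site_posteriors(self) -> np.ndarray:
        """(n_sites, n_cells) posterior grid weights per codon site."""
        cell_ll = self.spec._cell_loglikes(self.model)  # (cells, patterns)
        _, _, w = self.model.grid()
        lik = np.exp(cell_ll - cell_ll.max(axis=0, keepdims=True))
        post = w[:, None] * lik
        post /= post.sum(axis=0, keepdims=True)
        return post.T[self.spec._pattern_inverse]

    def _reference_positions(self) -> list[int]:
        aln = self.spec.alignment
        ref = self.spec.reference_id
        n_sites = aln.n_codons
        if ref is None:
            return list(range(1, n_sites + 1))
        row = aln.row(ref)
        positions, pos = [], 0
        for s in range(n_sites):
            codon = row[3 * s : 3 * s + 3]
            if GAP in codon:
                positions.append(0)
            else:
                pos += 1
                positions.append(pos)
        return positions

    def site_table(self) -> pd.DataFrame:
        """Per-site PP and Bayes factors for both selection hypotheses."""
        if self._site_table is not None:
            return self._site_table
        post = self.site_posteriors()
        pos_mask = self.model.positive_mask()
        neg_mask = self.model.negative_mask()
        pp_pos = post[:, pos_mask].sum(axis=1)
        pp_neg = post[:, neg_mask].sum(axis=1)
        bf_pos = _bayes_factor(pp_pos, self.model.prior_positive)
        bf_neg = _bayes_factor(pp_neg, self.model.prior_negative)
        self._site_table = pd.DataFrame(
            {
                "site": np.arange(1, len(pp_pos) + 1),
                "reference_pos": self._reference_positions(),
                "PP_positive": pp_pos,
                "BF_positive": bf_pos,
                "BF_negative": bf_neg,
            }
        )
        return self._site_table

    def classify(
        self, strong: float = 50.0, weak_low: float = 10.0, weak_high: float = 49.0
    ) -> pd.DataFrame:
        return classify_sites(self, strong=strong, weak_low=weak_low, weak_high=weak_high)

    def category_counts(self, **kwargs) -> pd.Series:
        cats = self.classify(**kwargs)["category"]
        order = ["strong_positive", "weak_positive", "negative", "neutral"]
        return cats.value_counts().reindex(order, fill_value=0)

    def summary(self) -> str:
        p = self.model
        counts = self.category_counts()
        lines = [
            "REL site-selection scan",
            "=" * 40,
            f"sites (codons):      {self.spec.alignment.n_codons}",
            f"sequences:           {self.spec.alignment.n_sequences}",
            f"R_AT, R_CT, R_GT:    {p.r_at:.4f}, {p.r_ct:.4f}, {p.r_gt:.4f}",
            f"branch scale:        {p.branch_scale:.4f}",
            f"dS classes:          {np.round(p.ds_values, 4).tolist()} w={np.round(p.ds_weights, 4).tolist()}",
            f"dN classes:          {np.round(p.dn_values, 4).tolist()} w={np.round(p.dn_weights, 4).tolist()}",
            f"prior P(dN>dS):      {p.prior_positive:.4f}",
            f"log-likelihood:      {p.llf:.4f} ({'converged' if p.converged else 'max iterations'})",
            f"strong positive:     {counts['strong_positive']}",
            f"weak positive:       {counts['weak_positive']}",
            f"negative:            {counts['negative']}",
            f"neutral:             {counts['neutral']}",
        ]
        return "\n".join(lines)


def _bayes_factor(pp: np.ndarray, prior: float) -> np.ndarray:
    """Posterior-odds / prior-odds; 0 when the prior mass is 0."""
    pp = np.asarray(pp, float)
    if prior <= 0:
        return np.zeros_like(pp)
    if prior >= 1:
        return np.where(pp >= 1.0, 1.0, 0.0)
    prior_odds = prior / (1.0 - prior)
    with np.errstate(divide="ignore"):
        post_odds = np.where(pp >= 1.0, np.inf, pp / np.maximum(1.0 - pp, 1e-300))
    return post_odds / prior_odds


def classify_sites(
    result: RelResults, strong: float = 50.0, weak_low: float = 10.0, weak_high: float = 49.0
) -> pd.DataFrame:
    """Attach selection categories to the per-site table.

    strong positive: BF+ >= strong; weak positive: weak_low <= BF+ < strong;
    negative: BF- >= strong and not positive; otherwise neutral.
    """
    if not (0 < weak_low <= weak_high < strong):
        raise ValueError("thresholds must satisfy 0 < weak_low <= weak_high < strong")
    table = result.site_table().copy()
    bf_pos = table["BF_positive"].to_numpy()
    bf_neg = table["BF_negative"].to_numpy()
    cats = np.full(len(table), "neutral", dtype=object)
    cats[bf_neg >= strong] = "negative"
    cats[(bf_pos >= weak_low) & (bf_pos < strong)] = "weak_positive"
    cats[bf_pos >= strong] = "strong_positive"
    table["category"] = cats
    return table


def fit_rel_model(
    alignment: CodonAlignment, tree: BaseTree, reference_id: str | None = None, **fit_kwargs
) -> RelResults:
    """Convenience wrapper: build the model and fit it."""
    return RelSiteSelection(alignment, tree, reference_id=reference_id).fit(**fit_kwargs)


def site_bayes_factors(result: RelResults) -> pd.DataFrame:
    """Per-site PP and Bayes factors of a fitted REL scan."""
    return result.site_table()
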