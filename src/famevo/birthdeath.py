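"""Single-rate birth-death model of gene-family size on a dated species tree.

The family-size process is a linear birth-death chain: each gene copy is
independently duplicated or lost at the same rate ``lambda`` (per gene per
Myr), so a family of size *s* gains at total rate ``lambda * s`` and loses at
total rate ``lambda * s``; size 0 is absorbing.  For equal birth and death
rates the transition probability has the classical closed form

    P(s -> c | t) = sum_j  C(s, j) C(c-1, j-1) a^(s-j) a^(c-j) (1-a)^(2j),

with ``a = lambda * t / (1 + lambda * t)`` and ``P(s -> 0) = a^s``.  Family
likelihoods are computed by postorder pruning over a truncated state space,
``lambda`` is estimated by bounded maximum likelihood over all families
jointly, family-wise p-values come from a Monte Carlo likelihood-ranking
null, and ancestral family sizes are max-posterior states from the standard
inside-outside recursion.

The modelling interface follows the Model / Results idiom:

>>> model = GeneFamilyEvolution(table, tree)        # doctest: +SKIP
>>> res = model.fit()                                # doctest: +SKIP
>>> res.lambda_, res.llf                             # doctest: +SKIP
>>> res.family_tests(n_null=1000, seed=7)            # doctest: +SKIP
>>> res.branch_calls("S8A")                          # doctest: +SKIP
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .tables import FamilyCountTable
from .trees import DatedSpeciesTree

__all__ = [
    "BirthDeathModel",
    "bd_transition_prob",
    "bd_transition_matrix",
    "family_log_likelihood",
    "estimate_lambda",
    "family_p_value",
    "GeneFamilyEvolution",
    "GeneFamilyEvolutionResults",
]


# ---------------------------------------------------------------------------
# transition kernel
# ---------------------------------------------------------------------------

def bd_transition_matrix(lam: float, t: float, cap: int) -> np.ndarray:
    """Transition matrix P[s, c] of the equal-rate birth-death chain.

    Rows index the parent count ``s`` (0..cap), columns the child count
    ``c`` (0..cap) after time ``t``.  Probability mass escaping beyond the
    cap is simply truncated, so rows sum to <= 1 with a deficit that
    vanishes as ``cap`` grows.
    """
    if lam < 0 or t < 0:
        raise ValueError("lambda and t must be non-negative")
    n = cap + 1
    if lam * t == 0.0:
        return np.eye(n)
    a = lam * t / (1.0 + lam * t)
    log_a = np.log(a)
    log_1ma = np.log1p(-a)
    s = np.arange(n)
    # survivor-count expansion: j ancestral lineages leave >=1 descendant
    j = np.arange(1, n + 1)
    # log C(s, j) for s >= j else -inf
    with np.errstate(invalid="ignore"):
        log_comb_sj = (
            gammaln(s[:, None] + 1) - gammaln(j[None, :] + 1) - gammaln(s[:, None] - j[None, :] + 1)
        )
    log_comb_sj[s[:, None] < j[None, :]] = -np.inf
    c = np.arange(n)
    with np.errstate(invalid="ignore"):
        log_comb_cj = (
            gammaln(c[:, None]) - gammaln(j[None, :]) - gammaln(c[:, None] - j[None, :] + 1)
        )
    log_comb_cj[c[:, None] < j[None, :]] = -np.inf
    # term(s, j, c) = C(s,j) a^(s-j) (1-a)^j  *  C(c-1,j-1) a^(c-j) (1-a)^j
    # P = U V as a scaled matmul; each factor's row/column max is <= 0 in
    # log space (both marginals sum to <= 1), so no overflow is possible.
    log_u = log_comb_sj + (s[:, None] - j[None, :]) * log_a + j[None, :] * log_1ma
    log_v = log_comb_cj + (c[:, None] - j[None, :]) * log_a + j[None, :] * log_1ma
    log_v = log_v.T  # (j, c)
    m_u = np.max(log_u, axis=1, initial=-np.inf)
    m_v = np.max(log_v, axis=0, initial=-np.inf)
    A = np.exp(log_u - np.where(np.isfinite(m_u), m_u, 0.0)[:, None])
    B = np.exp(log_v - np.where(np.isfinite(m_v), m_v, 0.0)[None, :])
    with np.errstate(invalid="ignore"):
        P = (A @ B) * np.exp(
            np.where(np.isfinite(m_u), m_u, -np.inf)[:, None]
            + np.where(np.isfinite(m_v), m_v, -np.inf)[None, :]
        )
    P = np.nan_to_num(P, nan=0.0, posinf=0.0)
    P[:, 0] = a ** s
    P[0, :] = 0.0
    P[0, 0] = 1.0
    return np.clip(P, 0.0, 1.0)


def bd_transition_prob(s: int, c: int, lam: float, t: float, cap: int | None = None) -> float:
    """P(child count = c | parent count = s) after time t at rate lambda."""
    if s < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    if lam < 0 or t < 0:
        raise ValueError("lambda and t must be non-negative")
    cap = max(s, c) if cap is None else cap
    return float(bd_transition_matrix(lam, t, cap)[s, c])


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class BirthDeathModel:
    """Fitted (or fixed) parameters of the family-size process.

    Parameters
    ----------
    lambda_rate : gene gain/loss rate per gene per Myr (birth = death).
    count_cap : truncation bound of the state space; must exceed the
        largest observed count with margin.
    root_prior : probability vector over root counts 0..cap.  The default
        is uniform over 1..cap, i.e. conditioned on a non-extinct root.
    """

    lambda_rate: float
    count_cap: int
    root_prior: np.ndarray | None = None
    at_boundary: bool = False

    def __post_init__(self):
        if self.lambda_rate < 0:
            raise ValueError("lambda_rate must be >= 0")
        if self.count_cap < 1:
            raise ValueError("count_cap must be >= 1")
        if self.root_prior is None:
            prior = np.zeros(self.count_cap + 1)
            prior[1:] = 1.0 / self.count_cap
            self.root_prior = prior
        else:
            self.root_prior = np.asarray(self.root_prior, dtype=float)
            if self.root_prior.shape != (self.count_cap + 1,):
                raise ValueError("root_prior must have length count_cap + 1")
            if not np.isclose(self.root_prior.sum(), 1.0):
                raise ValueError("root_prior must sum to 1")

    def transition_matrix(self, t: float) -> np.ndarray:
        return bd_transition_matrix(self.lambda_rate, t, self.count_cap)


def default_count_cap(max_observed: int) -> int:
    return 2 * int(max_observed) + 10


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

def _edge_matrices(tree: DatedSpeciesTree, model: BirthDeathModel) -> dict[int, np.ndarray]:
    out = {}
    for node in tree.postorder():
        if node is not tree.root:
            out[node.index] = model.transition_matrix(node.length or 0.0)
    return out


def _pruning_loglike(
    tree: DatedSpeciesTree,
    counts: np.ndarray,
    model: BirthDeathModel,
    mats: dict[int, np.ndarray] | None = None,
    species_order: list[str] | None = None,
    return_partials: bool = False,
):
    """Vectorized family log-likelihoods.

    ``counts`` is (n_families, n_tips) in ``species_order`` (defaults to the
    tree's tip order).  Partial likelihoods are rescaled per node to avoid
    underflow.  Returns an (n_families,) array of log-likelihoods; with
    ``return_partials`` also the per-node inside arrays (unscaled in log
    space is not needed downstream -- posteriors are scale-invariant).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=int))
    tips = tree.leaves
    order = species_order or [t.label for t in tips]
    col = {sp: k for k, sp in enumerate(order)}
    if counts.shape[1] != len(tips):
        raise ValueError("one count per tip is required")
    if counts.max(initial=0) > model.count_cap:
        raise ValueError("observed count exceeds count_cap")
    mats = mats or _edge_matrices(tree, model)
    n = counts.shape[0]
    cap1 = model.count_cap + 1
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n)
    keep = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in col:
                raise ValueError(f"no counts supplied for tip {node.label!r}")
            part = np.zeros((n, cap1))
            part[np.arange(n), counts[:, col[node.label]]] = 1.0
        else:
            part = np.ones((n, cap1))
            for child in node.children:
                msg = partials.pop(child.index) @ mats[child.index].T
                part = part * msg
            scale = part.max(axis=1)
            nz = scale > 0
            part[nz] /= scale[nz, None]
            with np.errstate(divide="ignore"):
                log_scale += np.where(nz, np.log(np.where(nz, scale, 1.0)), -np.inf)
        partials[node.index] = part
        if return_partials:
            keep[node.index] = part
    root_part = partials[tree.root.index]
    with np.errstate(divide="ignore"):
        ll = np.log(root_part @ model.root_prior) + log_scale
    if return_partials:
        return ll, keep
    return ll


def family_log_likelihood(
    tree: DatedSpeciesTree,
    counts: dict[str, int] | np.ndarray,
    model: BirthDeathModel,
    root_prior: np.ndarray | None = None,
) -> float:
    """Log-likelihood of one family's tip counts under the model.

    ``counts`` maps tip label -> count (or is an array in tip order).
    An explicit ``root_prior`` overrides the model's.
    """
    if root_prior is not None:
        model = BirthDeathModel(model.lambda_rate, model.count_cap, root_prior)
    if isinstance(counts, dict):
        missing = [t for t in tree.tip_labels if t not in counts]
        if missing:
            raise ValueError(f"tips missing a count: {missing}")
        counts = np.array([counts[t] for t in tree.tip_labels])
    return float(_pruning_loglike(tree, counts, model)[0])


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class GeneFamilyEvolution:
    """Gene-family size evolution under the single-rate birth-death process.

    Parameters
    ----------
    table : :class:`FamilyCountTable` (typically pre-filtered with
        :func:`famevo.tables.filter_families`).
    tree : calibrated :class:`DatedSpeciesTree` in Myr.
    count_cap : truncation bound; default ``2 * max(count) + 10``.
    root_prior : prior over root counts; default uniform over 1..cap.
    """

    def __init__(
        self,
        table: FamilyCountTable,
        tree: DatedSpeciesTree,
        count_cap: int | None = None,
        root_prior: np.ndarray | None = None,
    ):
        table.validate_against(tree)
        self.table = table
        self.tree = tree
        self.count_cap = count_cap or default_count_cap(table.max_count())
        self.root_prior = root_prior
        self._tip_order = tree.tip_labels
        self._counts = table.counts(order=self._tip_order)

    def _model(self, lam: float) -> BirthDeathModel:
        return BirthDeathModel(lam, self.count_cap, self.root_prior)

    def loglike_per_family(self, lam: float) -> np.ndarray:
        return _pruning_loglike(self.tree, self._counts, self._model(lam))

    def loglike(self, lam: float) -> float:
        return float(self.loglike_per_family(lam).sum())

    def fit(self, bounds: tuple[float, float] = (1e-8, 1.0)) -> "GeneFamilyEvolutionResults":
        """Estimate lambda by bounded scalar maximum likelihood."""
        counts = self._counts
        at_boundary = False
        if counts.size == 0 or np.all(counts == counts[:, :1]):
            # every family constant across species: no change observed
            lam_hat = 0.0
            at_boundary = True
        else:
            opt = minimize_scalar(
                lambda lam: -self.loglike(lam),
                bounds=bounds,
                method="bounded",
                options={"xatol": 1e-6},
            )
            lam_hat = float(opt.x)
            if lam_hat <= bounds[0] * 2:
                at_boundary = True
                warnings.warn("lambda estimate at lower boundary", RuntimeWarning)
        model = self._model(lam_hat)
        model.at_boundary = at_boundary
        fam_ll = _pruning_loglike(self.tree, counts, model)
        return GeneFamilyEvolutionResults(self, model, fam_ll)


@dataclass
class FamilyBranchCall:
    """One branch of the species tree in one family's history."""

    family_id: str
    parent_node: str
    child_node: str
    parent_count: int
    child_count: int
    branch_p: float
    direction: str  # expansion | contraction | none
    significant: bool


class GeneFamilyEvolutionResults:
    """Fitted birth-death analysis: rate, likelihoods, tests, ancestral sizes."""

    def __init__(self, model_spec: GeneFamilyEvolution, model: BirthDeathModel, family_llf: np.ndarray):
        self.spec = model_spec
        self.model = model
        self.family_llf = family_llf
        self._p_values: pd.Series | None = None

    @property
    def lambda_(self) -> float:
        return self.model.lambda_rate

    @property
    def llf(self) -> float:
        return float(self.family_llf.sum())

    @property
    def at_boundary(self) -> bool:
        return self.model.at_boundary

    # -- Monte Carlo family tests -------------------------------------
    def simulate_null_loglikes(self, n_null: int, seed: int) -> np.ndarray:
        """Log-likelihoods of families simulated from the fitted model."""
        counts = _simulate_from_kernel(self.spec.tree, self.model, n_null, seed)
        return _pruning_loglike(self.spec.tree, counts, self.model)

    def family_tests(self, n_null: int = 1000, seed: int = 0) -> pd.Series:
        """Monte Carlo p-value per family (likelihood-ranking null).

        For each family an independent batch of ``n_null`` families is
        simulated under the fitted model (root drawn from the root prior)
        and the p-value is the fraction with log-likelihood at or below the
        observed family's, with +1 on numerator and denominator so p > 0.
        """
        if n_null < 100:
            raise ValueError("n_null must be at least 100")
        rng = np.random.default_rng(seed)
        n_fam = len(self.family_llf)
        pvals = np.empty(n_fam)
        block = max(1, int(2e5) // max(n_null, 1))
        for start in range(0, n_fam, block):
            stop = min(start + block, n_fam)
            m = stop - start
            sub_seed = int(rng.integers(2**31 - 1))
            counts = _simulate_from_kernel(
                self.spec.tree, self.model, n_null * m, sub_seed
            )
            ll = _pruning_loglike(self.spec.tree, counts, self.model).reshape(m, n_null)
            obs = self.family_llf[start:stop, None]
            pvals[start:stop] = (1.0 + (ll <= obs).sum(axis=1)) / (n_null + 1.0)
        self._p_values = pd.Series(pvals, index=self.spec.table.family_ids, name="p_value")
        return self._p_values

    def family_p_values(self) -> pd.Series:
        if self._p_values is None:
            raise ValueError("run family_tests() first")
        return self._p_values

    # -- ancestral states and branch calls ----------------------------
    def ancestral_counts(self, family_id: str) -> dict[str, tuple[int, bool]]:
        """Max-posterior count per internal node: {node_key: (count, tied)}.

        Posterior ties are broken toward the smaller count and flagged.
        Internal nodes are keyed by the sorted tuple of descendant tips.
        """
        post = self._node_posteriors(family_id)
        out = {}
        for key, dist in post.items():
            best = float(dist.max())
            ties = np.nonzero(dist >= best - 1e-12)[0]
            out[key] = (int(ties[0]), len(ties) > 1)
        return out

    def _family_row(self, family_id: str) -> np.ndarray:
        idx = self.spec.table.family_ids.index(family_id)
        return self.spec._counts[idx]

    def _node_posteriors(self, family_id: str) -> dict[str, np.ndarray]:
        tree = self.spec.tree
        model = self.model
        row = self._family_row(family_id)[None, :]
        mats = _edge_matrices(tree, model)
        _, inside = _pruning_loglike(tree, row, model, mats=mats, return_partials=True)
        inside = {k: v[0] for k, v in inside.items()}
        outside = {tree.root.index: model.root_prior.copy()}
        for node in tree.preorder():
            if node.is_leaf:
                continue
            for child in node.children:
                above = outside[node.index].copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    above = above * (mats[sib.index] @ inside[sib.index])
                outside[child.index] = above @ mats[child.index]
        post = {}
        for node in tree.postorder():
            if node.is_leaf:
                continue
            dist = inside[node.index] * outside[node.index]
            total = dist.sum()
            if total > 0:
                dist = dist / total
            post[_node_key(node)] = dist
        return post

    def branch_calls(self, family_id: str, family_p: float | None = None, alpha: float = 0.05) -> list[FamilyBranchCall]:
        """Per-branch change calls for one family.

        Each species-tree branch is tested with the two-sided exact tail of
        the parent->child birth-death transition given the max-posterior
        parent count.  Branches are flagged significant only when the
        family-wise p-value is itself <= alpha.
        """
        if family_p is None:
            family_p = float(self.family_p_values()[family_id])
        tree = self.spec.tree
        model = self.model
        row = self._family_row(family_id)
        tip_count = {lab: int(c) for lab, c in zip(self.spec._tip_order, row)}
        anc = self.ancestral_counts(family_id)
        calls = []
        for node in tree.preorder():
            if node is tree.root:
                continue
            parent = node.parent
            s = anc[_node_key(parent)][0]
            c = tip_count[node.label] if node.is_leaf else anc[_node_key(node)][0]
            P = model.transition_matrix(node.length or 0.0)
            p_branch = _two_sided_tail(P[s], s, c)
            delta = c - s
            direction = "expansion" if delta > 0 else ("contraction" if delta < 0 else "none")
            significant = bool(family_p <= alpha and p_branch <= alpha and delta != 0)
            calls.append(
                FamilyBranchCall(
                    family_id=family_id,
                    parent_node=_node_key(parent),
                    child_node=node.label if node.is_leaf else _node_key(node),
                    parent_count=int(s),
                    child_count=int(c),
                    branch_p=float(p_branch),
                    direction=direction,
                    significant=significant,
                )
            )
        return calls

    def branch_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Branch calls for every family, as one tidy frame."""
        pvals = self.family_p_values()
        rows = []
        for fam in self.spec.table.family_ids:
            for call in self.branch_calls(fam, family_p=float(pvals[fam]), alpha=alpha):
                rows.append(vars(call))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Gene family birth-death analysis",
            "=" * 40,
            f"families:            {self.spec.table.n_families}",
            f"species:             {len(self.spec._tip_order)}",
            f"count cap:           {self.model.count_cap}",
            f"lambda (per gene/Myr): {self.lambda_:.6g}"
            + ("  [boundary]" if self.at_boundary else ""),
            f"log-likelihood:      {self.llf:.4f}",
        ]
        if self._p_values is not None:
            sig = int((self._p_values <= 0.05).sum())
            lines.append(f"families with p <= 0.05: {sig}")
        return "\n".join(lines)


def _node_key(node) -> str:
    if node.is_leaf:
        return node.label
    tips = sorted(_leaf_labels(node))
    return "|".join(tips)


def _leaf_labels(node) -> list[str]:
    if node.is_leaf:
        return [node.label]
    out = []
    for c in node.children:
        out.extend(_leaf_labels(c))
    return out


def _two_sided_tail(row: np.ndarray, s: int, c: int) -> float:
    """P(|C - s| >= |c - s|) under the transition distribution ``row``."""
    d = abs(c - s)
    if d == 0:
        return 1.0
    lo = max(0, s - d + 1)
    hi = min(len(row) - 1, s + d - 1)
    inner = row[lo : hi + 1].sum()
    return float(max(0.0, min(1.0, 1.0 - inner)))


def _simulate_from_kernel(
    tree: DatedSpeciesTree, model: BirthDeathModel, n: int, seed: int
) -> np.ndarray:
    """Simulate family tip-count vectors by sampling the transition kernel.

    Root counts are drawn from the model's root prior; each branch then
    draws the child count from the exact transition row of its parent
    count.  Used for Monte Carlo null distributions; the event-driven
    simulator in :mod:`famevo.simulate` is the generative counterpart.
    """
    rng = np.random.default_rng(seed)
    cap1 = model.count_cap + 1
    root = rng.choice(cap1, size=n, p=model.root_prior)
    cdfs = {}
    state = {tree.root.index: root}
    tips = tree.leaves
    out = np.zeros((n, len(tips)), dtype=int)
    tip_col = {t.index: k for k, t in enumerate(tips)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.index not in cdfs:
            P = model.transition_matrix(node.length or 0.0)
            # renormalize rows (truncation deficit) for sampling
            rows = P / P.sum(axis=1, keepdims=True)
            cdfs[node.index] = np.cumsum(rows, axis=1)
        cdf = cdfs[node.index]
        parent = state[node.parent.index]
        u = rng.random(n)
        child = (cdf[parent] > u[:, None]).argmax(axis=1)
        if node.is_leaf:
            out[:, tip_col[node.index]] = child
        else:
            state[node.index] = child
    return out


# ---------------------------------------------------------------------------
# functional wrappers (one call per analysis step)
# ---------------------------------------------------------------------------

def estimate_lambda(
    table: FamilyCountTable,
    tree: DatedSpeciesTree,
    count_cap: int | None = None,
    root_prior: np.ndarray | None = None,
) -> GeneFamilyEvolutionResults:
    """Fit the single-rate model; returns the Results object."""
    return GeneFamilyEvolution(table, tree, count_cap=count_cap, root_prior=root_prior).fit()


def family_p_value(
    counts: dict[str, int],
    model: BirthDeathModel,
    tree: DatedSpeciesTree,
    n_null: int = 1000,
    seed: int = 0,
) -> float:
    """Monte Carlo p-value for one family under a fixed fitted model."""
    if n_null < 100:
        raise ValueError("n_null must be at least 100")
    obs = family_log_likelihood(tree, counts, model)
    null_counts = _simulate_from_kernel(tree, model, n_null, seed)
    ll = _pruning_loglike(tree, null_counts, model)
    return float((1.0 + (ll <= obs).sum()) / (n_null + 1.0))
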