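"""Shared Felsenstein-pruning and state-simulation helpers.

These operate on the lightweight tree classes in :mod:`famevo.trees` and
on integer-coded character matrices where ``-1`` marks missing data (gaps
or ambiguity), which contributes a flat partial likelihood.
"""

from __future__ import annotations

import numpy as np

__all__ = ["site_log_likelihoods", "site_likelihood_given_matrices", "simulate_states"]


def site_likelihood_given_matrices(
    tree,
    tip_codes: dict[str, np.ndarray],
    mats: dict[int, np.ndarray],
    root_pi: np.ndarray,
) -> np.ndarray:
    """Per-site log-likelihoods by postorder pruning.

    ``tip_codes[label]`` is an (n_sites,) int array of states (-1 missing);
    ``mats[node.index]`` is the transition matrix on the edge above a node.
    """
    n_states = len(root_pi)
    some = next(iter(tip_codes.values()))
    n_sites = len(some)
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_sites)
    for node in tree.postorder():
        if node.is_leaf:
            codes = tip_codes[node.label]
            part = np.ones((n_sites, n_states))
            obs = codes >= 0
            part[obs] = 0.0
            part[np.nonzero(obs)[0], codes[obs]] = 1.0
        else:
            part = np.ones((n_sites, n_states))
            for child in node.children:
                part = part * (partials.pop(child.index) @ mats[child.index].T)
            scale = part.max(axis=1)
            pos = scale > 0
            part[pos] /= scale[pos, None]
            with np.errstate(divide="ignore"):
                log_scale += np.where(pos, np.log(np.where(pos, scale, 1.0)), -np.inf)
        partials[node.index] = part
    with np.errstate(divide="ignore"):
        return np.log(partials[tree.root.index] @ root_pi) + log_scale


def site_log_likelihoods(tree, tip_codes, matrix_factory, root_pi) -> np.ndarray:
    """Like :func:`site_likelihood_given_matrices` with on-the-fly matrices.

    ``matrix_factory(branch_length)`` returns the edge transition matrix.
    """
    mats = {
        node.index: matrix_factory(node.length or 0.0)
        for node in tree.postorder()
        if node is not tree.root
    }
    return site_likelihood_given_matrices(tree, tip_codes, mats, root_pi)


def site_log_likelihoods_batched(
    tree,
    tip_codes: dict[str, np.ndarray],
    mats: dict[int, np.ndarray],
    root_pi: np.ndarray,
) -> np.ndarray:
    """(n_models, n_sites) pruning log-likelihoods for a stack of models.

    ``mats[node.index]`` is (n_models, S, S): one transition matrix per
    model (e.g. one per grid cell of a rate-class mixture) on the edge
    above a node.  All models share the tree and root distribution.
    """
    n_states = len(root_pi)
    some_mat = next(iter(mats.values()))
    n_models = some_mat.shape[0]
    n_sites = len(next(iter(tip_codes.values())))
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros((n_models, n_sites))
    for node in tree.postorder():
        if node.is_leaf:
            codes = tip_codes[node.label]
            tip = np.ones((n_sites, n_states))
            obs = codes >= 0
            tip[obs] = 0.0
            tip[np.nonzero(obs)[0], codes[obs]] = 1.0
            part = np.broadcast_to(tip, (n_models, n_sites, n_states)).copy()
        else:
            part = np.ones((n_models, n_sites, n_states))
            for child in node.children:
                msg = np.matmul(partials.pop(child.index), mats[child.index].transpose(0, 2, 1))
                part = part * msg
            scale = part.max(axis=2)
            pos = scale > 0
            part = part / np.where(pos, scale, 1.0)[:, :, None]
            with np.errstate(divide="ignore"):
                log_scale += np.where(pos, np.log(np.where(pos, scale, 1.0)), -np.inf)
        partials[node.index] = part
    with np.errstate(divide="ignore"):
        return np.log(partials[tree.root.index] @ root_pi) + log_scale


def simulate_states(tree, root_states: np.ndarray, matrix_factory, rng) -> dict[str, np.ndarray]:
    """Evolve integer states down the tree; returns tip label -> states.

    ``matrix_factory(node)`` supplies the transition matrix of the edge
    above ``node`` (so per-edge rate scaling is the caller's business).
    """
    n_sites = len(root_states)
    states = {tree.root.index: np.asarray(root_states)}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        P = matrix_factory(node)
        cdf = np.cumsum(P, axis=1)
        cdf[:, -1] = 1.0
        parent = states[node.parent.index]
        u = rng.random(n_sites)
        child = (cdf[parent] > u[:, None]).argmax(axis=1)
        if node.is_leaf:
            out[node.label] = child
        else:
            states[node.index] = child
    return out
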