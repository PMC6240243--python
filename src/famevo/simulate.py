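"""Seeded generators for every input the analysis stages consume.

Each generator is a pure function of its parameters and seed, returns its
output together with a :class:`SimulationManifest` carrying the complete
parameterization and the ground truth needed to score the downstream
stage, and writes the same plain-text formats the analysis modules read.

The bundled 11-taxon species tree mirrors the shape of a Hypocreales
phylogeny (three *Hirsutella* species, *Metarhizium robertsii*, three
*Trichoderma* species, two *Fusarium* species, *Clonostachys rosea*, and
the outgroup *Neurospora crassa*) in its two published alternative
placements of *C. rosea*; its branch lengths are synthetic plausible ages
in Myr, anchored on a 29-Myr *H. minnesotensis* / *H. sinensis* split.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _phylo
from .aamodel import ReversibleMatrix, aa_rate_matrix
from .alignments import AMINO_ACIDS, Alignment, CodonAlignment
from .codon import SENSE_CODONS, codon_stationary, mg94_rate_matrix
from .tables import FamilyCountTable
from .trees import BaseTree, DatedSpeciesTree, GeneTree, _Node

__all__ = [
    "SimulationManifest",
    "hypocreales_tree",
    "SPECIES_CODES",
    "simulate_family_counts",
    "simulate_gene_tree",
    "simulate_region_alignment",
    "simulate_codon_alignment",
    "simulate_ct_table",
]

# Short species codes (no underscores: gene-tree tips use CODE_gN labels).
SPECIES_CODES = {
    "HMI": "Hirsutella minnesotensis",
    "HSI": "Hirsutella sinensis",
    "HTH": "Hirsutella thompsonii",
    "MRO": "Metarhizium robertsii",
    "TAT": "Trichoderma atroviride",
    "TVI": "Trichoderma virens",
    "TRE": "Trichoderma reesei",
    "FGR": "Fusarium graminearum",
    "FSO": "Fusarium solani",
    "CRO": "Clonostachys rosea",
    "NCR": "Neurospora crassa",
}

# synthetic node ages in Myr (H. minnesotensis/H. sinensis split = 29)
_NEWICK_A = (
    "(NCR:200,"
    "(((HTH:70,(HMI:29,HSI:29):41):50,MRO:120):30,"
    "((TRE:60,(TAT:25,TVI:25):35):70,"
    "(CRO:110,(FGR:50,FSO:50):60):20):20):50);"
)
_NEWICK_B = (
    "(NCR:200,"
    "(CRO:160,"
    "(((HTH:70,(HMI:29,HSI:29):41):50,MRO:120):30,"
    "((TRE:60,(TAT:25,TVI:25):35):70,(FGR:50,FSO:50):80):20):10):40);"
)


def hypocreales_tree(topology: str = "A") -> DatedSpeciesTree:
    """The 11-taxon fixture species tree (synthetic Myr branch lengths).

    ``topology="A"`` places *C. rosea* sister to the *Fusaria*;
    ``topology="B"`` places it as the basal Hypocreales lineage.
    """
    if topology == "A":
        return DatedSpeciesTree.from_newick(_NEWICK_A)
    if topology == "B":
        return DatedSpeciesTree.from_newick(_NEWICK_B)
    raise ValueError("topology must be 'A' or 'B'")


@dataclass
class SimulationManifest:
    """Full record of one simulation: parameters plus ground truth."""

    generator: str
    seed: int
    parameters: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# family counts under the birth-death process
# ---------------------------------------------------------------------------

def _gillespie_branch(n0: int, lam: float, t: float, rng) -> int:
    """Exact event-driven simulation of the equal-rate BD chain."""
    n, time = n0, 0.0
    while n > 0:
        rate = 2.0 * lam * n
        if rate <= 0:
            break
        time += rng.exponential(1.0 / rate)
        if time >= t:
            break
        n += 1 if rng.random() < 0.5 else -1
    return n


def simulate_family_counts(
    tree: DatedSpeciesTree,
    lam: float,
    n_families: int,
    root_prior: np.ndarray | None = None,
    seed: int = 0,
    root_max: int = 10,
) -> tuple[FamilyCountTable, SimulationManifest]:
    """Families evolving under the single-rate birth-death process.

    The root count is drawn from ``root_prior`` (default uniform over
    1..root_max); each branch then runs an exact event-driven birth-death
    simulation at rate ``lam`` per gene per Myr.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    rng = np.random.default_rng(seed)
    if root_prior is None:
        root_prior = np.zeros(root_max + 1)
        root_prior[1:] = 1.0 / root_max
    root_prior = np.asarray(root_prior, float)
    states = rng.choice(len(root_prior), size=n_families, p=root_prior)
    tips = tree.leaves
    counts = np.zeros((n_families, len(tips)), dtype=int)
    tip_col = {t.index: k for k, t in enumerate(tips)}
    node_states = {tree.root.index: states}
    root_counts = states.copy()
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent = node_states[node.parent.index]
        t = node.length or 0.0
        child = np.array([_gillespie_branch(int(s), lam, t, rng) for s in parent])
        if node.is_leaf:
            counts[:, tip_col[node.index]] = child
        else:
            node_states[node.index] = child
    fam_ids = [f"FAM{i:04d}" for i in range(n_families)]
    table = FamilyCountTable.from_counts(fam_ids, [t.label for t in tips], counts)
    manifest = SimulationManifest(
        generator="simulate_family_counts",
        seed=seed,
        parameters={
            "lambda": lam,
            "n_families": n_families,
            "root_prior": root_prior,
            "tree": tree.to_newick(),
        },
        ground_truth={"root_counts": root_counts},
    )
    return table, manifest


# ---------------------------------------------------------------------------
# gene trees by duplication-loss inside the species tree
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("node",)

    def __init__(self, node: _Node):
        self.node = node


def simulate_gene_tree(
    species_tree: DatedSpeciesTree,
    dup_rate: float,
    loss_rate: float,
    seed: int = 0,
    support_noise: float = 0.0,
    max_retries: int = 100,
) -> tuple[GeneTree, SimulationManifest]:
    """One gene family evolving by duplication and loss in the species tree.

    A single ancestral gene lineage enters the root; along every species
    branch each lineage duplicates at ``dup_rate`` and dies at
    ``loss_rate`` (per lineage per Myr); at speciations every lineage
    splits into both daughter branches.  Lineages without surviving
    descendants are pruned and unifurcations suppressed.  Supports are 100
    by default, degraded by subtracting |N(0, support_noise)| per edge.

    The manifest records every event as placed (``raw``) and the counts
    visible in the pruned tree (``surviving``), with per-species-branch
    placements for surviving duplications.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        out = _simulate_gene_tree_once(species_tree, dup_rate, loss_rate, rng, support_noise)
        if out is not None:
            tree, truth = out
            manifest = SimulationManifest(
                generator="simulate_gene_tree",
                seed=seed,
                parameters={
                    "dup_rate": dup_rate,
                    "loss_rate": loss_rate,
                    "support_noise": support_noise,
                    "tree": species_tree.to_newick(),
                    "attempt": attempt,
                },
                ground_truth=truth,
            )
            return tree, manifest
    raise RuntimeError(f"all gene lineages went extinct in {max_retries} attempts")


def _simulate_gene_tree_once(species_tree, dup_rate, loss_rate, rng, support_noise):
    events = {"duplications_raw": 0, "losses_raw": 0}
    dup_nodes: list[tuple[_Node, str]] = []  # (gene node, species branch key)
    tip_counter: dict[str, int] = {}

    def species_key(snode):
        if snode.is_leaf:
            return snode.label
        return "|".join(sorted(l.label for l in _leaves_of(snode)))

    def evolve_branch(gnode: _Node, snode) -> list[_Node]:
        """Evolve one lineage along the branch above ``snode``; returns the
        lineage tips alive at the bottom of the branch (possibly many after
        duplications, or none)."""
        t = snode.length or 0.0
        alive = [gnode]
        time = 0.0
        total = dup_rate + loss_rate
        while alive and total > 0:
            rate = total * len(alive)
            time += rng.exponential(1.0 / rate)
            if time >= t:
                break
            k = rng.integers(len(alive))
            lineage = alive.pop(k)
            if rng.random() < dup_rate / total:
                events["duplications_raw"] += 1
                left, right = _Node(), _Node()
                lineage.add(left)
                lineage.add(right)
                dup_nodes.append((lineage, species_key(snode)))
                alive.extend([left, right])
            else:
                events["losses_raw"] += 1
                lineage.label = "__dead__"
        return alive

    def at_species_node(lineages: list[_Node], snode) -> None:
        if snode.is_leaf:
            for lin in lineages:
                k = tip_counter.get(snode.label, 0) + 1
                tip_counter[snode.label] = k
                lin.label = f"{snode.label}_g{k}"
            return
        for lin in lineages:
            kids = []
            for schild in snode.children:
                g = _Node()
                lin.add(g)
                kids.append((g, schild))
            for g, schild in kids:
                bottom = evolve_branch(g, schild)
                at_species_node(bottom, schild)

    root = _Node()
    at_species_node([root], species_tree.root)

    pruned = _prune_dead(root)
    if pruned is None or pruned.is_leaf:
        return None
    surviving_dups = []
    alive_nodes = set()

    def collect(node):
        alive_nodes.add(id(node))
        for c in node.children:
            collect(c)

    collect(pruned)
    for gnode, key in dup_nodes:
        if id(gnode) in alive_nodes and len(gnode.children) == 2:
            surviving_dups.append(key)
    for node in _iter_nodes(pruned):
        if node.children:
            noise = abs(rng.normal(0.0, support_noise)) if support_noise > 0 else 0.0
            node.support = float(np.clip(100.0 - noise, 0.0, 100.0))
    tree = GeneTree(pruned)
    truth = {
        "duplications_raw": events["duplications_raw"],
        "losses_raw": events["losses_raw"],
        "surviving_duplications": len(surviving_dups),
        "surviving_duplication_branches": sorted(surviving_dups),
        "n_genes": len(tree.leaves),
    }
    return tree, truth


def _leaves_of(node):
    if node.is_leaf:
        return [node]
    out = []
    for c in node.children:
        out.extend(_leaves_of(c))
    return out


def _iter_nodes(node):
    yield node
    for c in node.children:
        yield from _iter_nodes(c)


def _prune_dead(node: _Node) -> _Node | None:
    """Drop dead lineages, suppress unifurcations; None if all extinct.

    Prunes in place, preserving node identity so that recorded event nodes
    (duplications) can be checked for survival afterwards.
    """
    if not node.children:
        if node.label in (None, "__dead__"):
            return None
        return node
    kept = [p for c in node.children if (p := _prune_dead(c)) is not None]
    node.children = []
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    for k in kept:
        node.add(k)
    return node


# ---------------------------------------------------------------------------
# protein alignments with block-structured rate variation
# ---------------------------------------------------------------------------

def simulate_region_alignment(
    tree: BaseTree,
    n_columns: int,
    block_spec: list[tuple[int, int, float]],
    seed: int = 0,
    base_rate: float = 1.0,
    freqs: np.ndarray | None = None,
) -> tuple[Alignment, SimulationManifest]:
    """Protein alignment with planted rate-multiplier blocks.

    ``block_spec`` holds (start, end, multiplier) in 1-based inclusive
    column coordinates; blocks must not overlap.  Per-column substitution
    rate is ``base_rate * multiplier`` (multiplier 1 outside all blocks);
    sequences evolve down ``tree`` under the empirical amino-acid model.
    """
    rates = np.full(n_columns, float(base_rate))
    occupied = np.zeros(n_columns, dtype=bool)
    for start, end, mult in block_spec:
        if not (1 <= start <= end <= n_columns):
            raise ValueError(f"block ({start}, {end}) out of bounds 1..{n_columns}")
        sl = slice(start - 1, end)
        if occupied[sl].any():
            raise ValueError("overlapping blocks")
        occupied[sl] = True
        rates[sl] = base_rate * mult
    rng = np.random.default_rng(seed)
    Q, pi = aa_rate_matrix(freqs)
    rev = ReversibleMatrix(Q, pi)
    root_states = rng.choice(len(pi), size=n_columns, p=pi)
    unique_rates = np.unique(rates)
    tip_states = {lab: np.empty(n_columns, dtype=int) for lab in tree.tip_labels}
    for r in unique_rates:
        cols = np.nonzero(rates == r)[0]
        sub = _phylo.simulate_states(
            tree,
            root_states[cols],
            lambda node, r=r: rev.transition_matrix(r * (node.length or 0.0)),
            rng,
        )
        for lab, states in sub.items():
            tip_states[lab][cols] = states
    rows = ["".join(AMINO_ACIDS[s] for s in tip_states[lab]) for lab in tree.tip_labels]
    aln = Alignment(tree.tip_labels, rows)
    manifest = SimulationManifest(
        generator="simulate_region_alignment",
        seed=seed,
        parameters={
            "n_columns": n_columns,
            "block_spec": [list(b) for b in block_spec],
            "base_rate": base_rate,
            "tree": tree.to_newick(),
        },
        ground_truth={"column_rates": rates, "blocks": [list(b) for b in block_spec]},
    )
    return aln, manifest


# ---------------------------------------------------------------------------
# codon alignments with site-class omega mixtures
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    tree: BaseTree,
    n_codons: int,
    site_class_spec: list[tuple[float, float, float]],
    seed: int = 0,
    r_at: float = 1.0,
    r_ct: float = 1.0,
    r_gt: float = 1.0,
    pos_freqs: np.ndarray | None = None,
) -> tuple[CodonAlignment, SimulationManifest]:
    """Codon alignment with sites drawn from (fraction, dN, dS) classes.

    Stop codons are excluded from the state space by construction; the
    per-site class assignment is recorded as ground truth.
    """
    fractions = np.array([c[0] for c in site_class_spec], float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    if pos_freqs is None:
        pos_freqs = np.full((3, 4), 0.25)
    pi = codon_stationary(pos_freqs)
    _, norm = mg94_rate_matrix(r_at, r_ct, r_gt, pos_freqs, 1.0, 1.0)
    classes = rng.choice(len(site_class_spec), size=n_codons, p=fractions)
    root_states = rng.choice(len(pi), size=n_codons, p=pi)
    tip_states = {lab: np.empty(n_codons, dtype=int) for lab in tree.tip_labels}
    for k, (_, dn, ds) in enumerate(site_class_spec):
        cols = np.nonzero(classes == k)[0]
        if cols.size == 0:
            continue
        Q, _ = mg94_rate_matrix(r_at, r_ct, r_gt, pos_freqs, ds, dn, normalization=norm)
        rev = ReversibleMatrix(Q, pi)
        sub = _phylo.simulate_states(
            tree,
            root_states[cols],
            lambda node: rev.transition_matrix(node.length or 0.0),
            rng,
        )
        for lab, states in sub.items():
            tip_states[lab][cols] = states
    rows = ["".join(SENSE_CODONS[s] for s in tip_states[lab]) for lab in tree.tip_labels]
    aln = CodonAlignment(tree.tip_labels, rows)
    manifest = SimulationManifest(
        generator="simulate_codon_alignment",
        seed=seed,
        parameters={
            "n_codons": n_codons,
            "site_class_spec": [list(c) for c in site_class_spec],
            "R_AT": r_at,
            "R_CT": r_ct,
            "R_GT": r_gt,
            "tree": tree.to_newick(),
        },
        ground_truth={
            "site_classes": classes,
            "positive_sites": (1 + np.nonzero(
                np.array([c[1] > c[2] for c in site_class_spec])[classes]
            )[0]),
        },
    )
    return aln, manifest


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(
    genes: list[str],
    treatments: list[str],
    fold_change_matrix: pd.DataFrame,
    n_bio_reps: int = 5,
    sigma: float = 0.15,
    seed: int = 0,
    n_tech_reps: int = 2,
    baseline_dct: float = 3.0,
    reference_mean_ct: float = 20.0,
) -> tuple[pd.DataFrame, SimulationManifest]:
    """Replicated Ct measurements with planted fold changes.

    ``fold_change_matrix`` is genes x treatments; positive entries are
    true fold changes relative to the control (which should hold 1.0), NaN
    marks no detectable expression.  Reference Ct ~ N(reference_mean_ct,
    sigma); target Ct = reference + baseline_dct - log2(fold) + N(0,
    sigma).  Technical replicates repeat the biological value (technical
    noise is outside this generator's scope; they exist to exercise the
    averaging path).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        for tr in treatments:
            fold = fold_change_matrix.loc[gene, tr]
            for rep in range(1, n_bio_reps + 1):
                detectable = bool(pd.notna(fold))
                if detectable and fold <= 0:
                    raise ValueError("fold changes must be positive or NaN (N/D)")
                ref_ct = reference_mean_ct + rng.normal(0.0, sigma) if sigma else reference_mean_ct
                if detectable:
                    tgt = ref_ct + baseline_dct - np.log2(fold)
                    if sigma:
                        tgt += rng.normal(0.0, sigma)
                else:
                    tgt = np.nan
                for tech in range(1, n_tech_reps + 1):
                    rows.append(
                        {
                            "gene": gene,
                            "treatment": tr,
                            "bio_rep": rep,
                            "tech_rep": tech,
                            "ct_target": tgt,
                            "ct_reference": ref_ct,
                            "detectable": detectable,
                        }
                    )
    frame = pd.DataFrame(rows)
    manifest = SimulationManifest(
        generator="simulate_ct_table",
        seed=seed,
        parameters={
            "genes": genes,
            "treatments": treatments,
            "n_bio_reps": n_bio_reps,
            "n_tech_reps": n_tech_reps,
            "sigma": sigma,
            "baseline_dct": baseline_dct,
        },
        ground_truth={
            "fold_changes": {
                g: {t: (None if pd.isna(v) else float(v)) for t, v in fold_change_matrix.loc[g].items()}
                for g in genes
            }
        },
    )
    return frame, manifest
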