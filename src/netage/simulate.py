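"""Synthetic inputs with the statistical structure the pipeline assumes.

Profiles are generated by a single-gain-then-loss process down the
species tree: a gene is born on one branch and each descendant branch
loses it independently with a fixed probability (no regain), which is
exactly the generative story behind Dollo parsimony.  A Wagner-style
generator (independent gains and losses per branch) is available for
recovery tests of the multi-gain engine.  PTM networks are generated
with a tunable probability that interacting pairs share an age group.
Every generator is deterministic under (parameters, seed) and emits a
truth record sufficient to replay the data bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AgeScale, DEFAULT_SCALE, SpeciesTree
from .profiles import PhyloProfile
from .ptm import PTMNetwork, PTMPair

# PTM-type frequencies default to the proportions observed in the DDR
# pair table (phosphorylation dominates).
DEFAULT_PTM_PROBS = {"P": 0.77, "U": 0.14, "S": 0.06, "A": 0.02, "deA": 0.01}


@dataclass
class GeneHistoryTruth:
    gene: str
    gain_branch: str
    true_age_rank: int
    loss_branches: tuple[str, ...]


@dataclass
class ProfileSetTruth:
    seed: int
    loss_rate: float
    histories: list[GeneHistoryTruth]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [h.gene for h in self.histories],
                "gain_branch": [h.gain_branch for h in self.histories],
                "true_age_rank": [h.true_age_rank for h in self.histories],
                "loss_branches": ["|".join(h.loss_branches) for h in self.histories],
            }
        )


def replay_history(tree: SpeciesTree, truth: GeneHistoryTruth) -> pd.Series:
    """Reconstruct the leaf presence row implied by a truth record."""
    present = dict.fromkeys(tree.leaves, 0)
    gain_node = tree.node(truth.gain_branch)
    lost = set(truth.loss_branches)

    def walk(node, alive: bool):
        nid = tree.node_id(node)
        if nid in lost:
            alive = False
        if node.is_leaf():
            if alive:
                present[node.taxon.label] = 1
            return
        for ch in node.child_nodes():
            walk(ch, alive)

    walk(gain_node, True)
    return pd.Series(present, name=truth.gene)


def simulate_gene_history(
    tree: SpeciesTree,
    gain_branch: str,
    loss_rate: float,
    seed: int | np.random.Generator = 0,
    gene: str = "G1",
) -> tuple[pd.Series, GeneHistoryTruth]:
    """One gene history: gain on a branch, branch-wise Bernoulli loss below.

    The gene exists below ``gain_branch`` (a node id); every branch
    inside the clade loses it independently with probability
    ``loss_rate``; a loss is permanent.  Leaves outside the clade are 0.
    """
    if not (0 <= loss_rate < 1):
        raise ValueError("loss_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gain_node = tree.node(gain_branch)
    losses: list[str] = []

    def walk(node, alive: bool):
        for ch in node.child_nodes():
            ch_alive = alive
            if alive and rng.random() < loss_rate:
                losses.append(tree.node_id(ch))
                ch_alive = False
            walk(ch, ch_alive)

    walk(gain_node, True)
    truth = GeneHistoryTruth(
        gene, gain_branch, tree.oldest_rank_below(gain_branch), tuple(losses)
    )
    return replay_history(tree, truth), truth


def _branches_by_oldest_rank(tree: SpeciesTree) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    for node in tree.preorder():
        nid = tree.node_id(node)
        out.setdefault(tree.oldest_rank_below(nid), []).append(nid)
    return out


def simulate_profile_set(
    tree: SpeciesTree,
    n_genes: int,
    age_distribution: dict[int, float],
    loss_rate: float = 0.0,
    seed: int = 0,
) -> tuple[PhyloProfile, ProfileSetTruth]:
    """A profile of independent single-gain histories with planted ages.

    Gain branches are drawn so the clade's oldest age group follows
    ``age_distribution`` (rank -> weight, summing to 1); within a rank the
    branch is drawn uniformly among compatible branches.
    """
    weights = dict(age_distribution)
    if weights and abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("age_distribution weights must sum to 1")
    rng = np.random.default_rng(seed)
    candidates = _branches_by_oldest_rank(tree)
    for rank in weights:
        if weights[rank] > 0 and rank not in candidates:
            raise ValueError(f"no branch yields oldest age rank {rank}")
    ranks = sorted(weights)
    probs = np.array([weights[r] for r in ranks], float)
    species = sorted(tree.leaves, key=lambda s: (tree.group_rank(s), s))
    rows = {}
    histories = []
    width = max(4, len(str(n_genes)))
    for i in range(n_genes):
        gene = f"G{i + 1:0{width}d}"
        rank = int(rng.choice(ranks, p=probs)) if ranks else 1
        branch = candidates[rank][rng.integers(len(candidates[rank]))]
        row, truth = simulate_gene_history(tree, branch, loss_rate, rng, gene=gene)
        rows[gene] = row.reindex(species).astype(np.int8)
        histories.append(truth)
    if rows:
        matrix = pd.DataFrame(rows).T
        matrix.columns = species
    else:
        matrix = pd.DataFrame(np.zeros((0, len(species)), dtype=np.int8), columns=species)
    matrix.index.name = "gene"
    return PhyloProfile(matrix), ProfileSetTruth(seed, loss_rate, histories)


def simulate_wagner_history(
    tree: SpeciesTree,
    gain_rate: float,
    loss_rate: float,
    seed: int | np.random.Generator = 0,
    gene: str = "G1",
) -> pd.Series:
    """Wagner-style history: independent gain/loss per branch, absent root."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    present = dict.fromkeys(tree.leaves, 0)

    def walk(node, state: int):
        if node.is_leaf():
            present[node.taxon.label] = state
            return
        for ch in node.child_nodes():
            if state == 0:
                ch_state = 1 if rng.random() < gain_rate else 0
            else:
                ch_state = 0 if rng.random() < loss_rate else 1
            walk(ch, ch_state)

    walk(tree.root, 0)
    return pd.Series(present, name=gene)


def profile_to_hits(profile: PhyloProfile, seed_species: str = "Hsa") -> pd.DataFrame:
    """Flatten a profile into the bidirectional hit-table dialect.

    Every presence cell becomes a perfect-score bidirectional hit, so
    rebuilding the profile from these hits round-trips the matrix.
    """
    rows = []
    for g in profile.genes:
        for s in profile.species:
            if profile.matrix.loc[g, s] == 1:
                rows.append((g, seed_species, s, f"{g}_{s}", 1.0, True))
    return pd.DataFrame(
        rows,
        columns=[
            "seed_gene", "seed_species", "target_species",
            "hit_id", "score", "bidirectional",
        ],
    )


@dataclass
class PTMTruth:
    seed: int
    assortativity: float
    same_age_intended: tuple[bool, ...]


def simulate_ptm_network(
    gene_ages: dict[str, int],
    n_pairs: int,
    assortativity: float,
    seed: int = 0,
    ptm_probs: dict[str, float] | None = None,
    scale: AgeScale = DEFAULT_SCALE,
) -> tuple[PTMNetwork, PTMTruth]:
    """PTM network with a planted degree of age assortativity.

    Each pair draws a target uniformly; with probability
    ``assortativity`` the modifier comes from same-age genes, otherwise
    uniformly from all genes.  Self-pairs are rejected; if no same-age
    partner exists when one is required, the target is redrawn (bounded).
    """
    if not (0 <= assortativity <= 1):
        raise ValueError("assortativity must be in [0, 1]")
    if len(set(gene_ages.values())) < 2:
        raise ValueError("need at least two distinct ages")
    ptm_probs = dict(ptm_probs or DEFAULT_PTM_PROBS)
    rng = np.random.default_rng(seed)
    genes = sorted(gene_ages)
    by_age: dict[int, list[str]] = {}
    for g in genes:
        by_age.setdefault(gene_ages[g], []).append(g)
    ptm_types = sorted(ptm_probs)
    ptm_p = np.array([ptm_probs[t] for t in ptm_types], float)
    ptm_p = ptm_p / ptm_p.sum()
    pairs = []
    intended = []
    for _ in range(n_pairs):
        for _try in range(10_000):
            target = genes[rng.integers(len(genes))]
            same = rng.random() < assortativity
            pool = by_age[gene_ages[target]] if same else genes
            pool = [g for g in pool if g != target]
            if pool:
                modifier = pool[rng.integers(len(pool))]
                break
        else:
            raise RuntimeError("could not draw a valid pair")
        ptm = ptm_types[rng.choice(len(ptm_types), p=ptm_p)]
        pairs.append(
            PTMPair(target, modifier, "GR", "CHK", ptm,
                    gene_ages[target], gene_ages[modifier])
        )
        intended.append(same)
    net = PTMNetwork(pairs, scale=scale, harmonized=True)
    return net, PTMTruth(seed, assortativity, tuple(intended))
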