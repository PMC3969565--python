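"""Gene-age inference: oldest-hit rule, Dollo and Wagner parsimony.

Three ways of dating a gene from its phylogenetic profile:

* oldest hit -- the age group of the most distant species with a homolog;
* Dollo parsimony -- a single gain on the branch to the MRCA of all
  carriers, with losses covering the absences (gaining a gene is rarer
  than losing it);
* Wagner parsimony -- minimum-weighted-cost ancestral labelling allowing
  repeated gains and losses (Sankoff bottom-up recursion with a top-down
  backtrace).

Emergence curves aggregate assigned ages into cumulative fractions per
age group, optionally stratified by functional tier or subnetwork.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AgeScale, DEFAULT_SCALE, GeneAnnotation, SpeciesTree


@dataclass
class GeneAge:
    gene: str
    method: str  # oldest_hit | dollo | wagner
    rank: int
    flags: tuple[str, ...] = ()


@dataclass
class Reconstruction:
    """Ancestral states and gain/loss events for one gene on the tree.

    ``states`` maps node ids to 0/1; ``gains``/``losses`` list the child
    node ids of branches on which the state switches; ``cost`` is the
    weighted event total (for Dollo, the number of losses).
    """

    gene: str
    states: dict[str, int]
    gains: tuple[str, ...]
    losses: tuple[str, ...]
    cost: float
    method: str = "parsimony"


def assign_age_oldest_hit(
    row: pd.Series,
    tree: SpeciesTree,
    scale: AgeScale = DEFAULT_SCALE,
    discount_isolated: bool = False,
    isolated: pd.Series | None = None,
    gene: str | None = None,
) -> GeneAge:
    """Age of a gene as the rank of its most ancient presence.

    With ``discount_isolated`` on, if the oldest stratum is supported
    only by isolated-flagged cells the assignment skips to the next
    oldest stratum with a non-isolated presence (the lone bacterial hit
    of an otherwise animal gene is treated as an artifact or lateral
    transfer).
    """
    gene = gene if gene is not None else str(row.name)
    present = [s for s in row.index if row[s] == 1]
    if not present:
        raise ValueError(f"{gene}: no homologs in any species")
    ranks = sorted({tree.group_rank(s) for s in present})
    flags: tuple[str, ...] = ()
    chosen = ranks[0]
    if discount_isolated and isolated is not None:
        solid = {
            tree.group_rank(s) for s in present if not bool(isolated.get(s, False))
        }
        if chosen not in solid:
            if solid:
                chosen = min(solid)
                flags = ("discounted_isolated_hit",)
            else:
                flags = ("used_isolated_hit",)
    elif isolated is not None and any(
        bool(isolated.get(s, False)) and tree.group_rank(s) == chosen for s in present
    ):
        flags = ("used_isolated_hit",)
    return GeneAge(gene, "oldest_hit", chosen, flags)


def dollo_reconstruct(tree: SpeciesTree, row: pd.Series, gene: str | None = None) -> Reconstruction:
    """Dollo parsimony: one gain at the MRCA of carriers, minimal losses.

    The gain is placed on the branch leading to the most recent common
    ancestor of all present leaves.  Inside that clade a node is ancestral
    present iff its subtree retains at least one carrier; each maximal
    carrier-free subtree costs one loss on its stem branch.
    """
    gene = gene if gene is not None else str(row.name)
    present = {s for s in row.index if row[s] == 1}
    if not present:
        raise ValueError(f"{gene}: all-zero profile row")
    gain_id = tree.mrca(sorted(present))
    gain_node = tree.node(gain_id)
    inside = set()
    if gain_node.is_leaf():
        inside = {gain_node}
    else:
        inside = {gain_node} | set(gain_node.preorder_iter())
    states: dict[str, int] = {}
    losses: list[str] = []

    def has_carrier(node) -> bool:
        if node.is_leaf():
            return node.taxon.label in present
        return any(lf.taxon.label in present for lf in node.leaf_iter())

    for node in tree.postorder():
        nid = tree.node_id(node)
        if node not in inside:
            states[nid] = 0
        else:
            states[nid] = 1 if has_carrier(node) else 0
    # losses: state-0 nodes inside the clade whose parent is state-1
    for node in tree.preorder():
        if node not in inside or node is gain_node:
            continue
        nid = tree.node_id(node)
        pid = tree.node_id(node.parent_node)
        if states[pid] == 1 and states[nid] == 0:
            losses.append(nid)
    return Reconstruction(
        gene, states, (gain_id,), tuple(losses), float(len(losses)), method="dollo"
    )


def wagner_reconstruct(
    tree: SpeciesTree,
    row: pd.Series,
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
    gene: str | None = None,
) -> Reconstruction:
    """Wagner parsimony via Sankoff dynamic programming.

    Bottom-up cost propagation over {absent, present} with asymmetric
    event weights, then a top-down backtrace.  Ties prefer state 0 at the
    root (genes are born, not primordial) and state 0 at every other
    equal-cost decision, which makes the labelling deterministic.
    Multifurcations are handled natively by summing over children.
    """
    if gain_cost <= 0 or loss_cost <= 0:
        raise ValueError("gain_cost and loss_cost must be positive")
    gene = gene if gene is not None else str(row.name)
    INF = float("inf")
    w = {(0, 0): 0.0, (1, 1): 0.0, (0, 1): float(gain_cost), (1, 0): float(loss_cost)}
    cost: dict[str, tuple[float, float]] = {}
    for node in tree.postorder():
        nid = tree.node_id(node)
        if node.is_leaf():
            obs = int(row.get(node.taxon.label, 0))
            cost[nid] = (0.0 if obs == 0 else INF, 0.0 if obs == 1 else INF)
        else:
            c0 = c1 = 0.0
            for ch in node.child_nodes():
                cc = cost[tree.node_id(ch)]
                c0 += min(cc[0] + w[(0, 0)], cc[1] + w[(0, 1)])
                c1 += min(cc[0] + w[(1, 0)], cc[1] + w[(1, 1)])
            cost[nid] = (c0, c1)
    states: dict[str, int] = {}
    root = tree.root
    rid = tree.node_id(root)
    # a present root is itself a gain (on the branch into the root), so the
    # root decision carries the gain charge; ties prefer absence
    states[rid] = 0 if cost[rid][0] <= cost[rid][1] + gain_cost else 1
    for node in tree.preorder():
        nid = tree.node_id(node)
        if node is root:
            continue
        ps = states[tree.node_id(node.parent_node)]
        c = cost[nid]
        c_to0 = c[0] + w[(ps, 0)]
        c_to1 = c[1] + w[(ps, 1)]
        states[nid] = 0 if c_to0 <= c_to1 else 1
    gains: list[str] = []
    losses: list[str] = []
    if states[rid] == 1:
        gains.append(rid)  # gain on the branch into the root
    for node in tree.preorder():
        if node is root:
            continue
        nid = tree.node_id(node)
        ps = states[tree.node_id(node.parent_node)]
        if ps == 0 and states[nid] == 1:
            gains.append(nid)
        elif ps == 1 and states[nid] == 0:
            losses.append(nid)
    total = gain_cost * len(gains) + loss_cost * len(losses)
    return Reconstruction(
        gene, states, tuple(gains), tuple(losses), float(total), method="wagner"
    )


def age_from_reconstruction(
    recon: Reconstruction,
    tree: SpeciesTree,
    scale: AgeScale = DEFAULT_SCALE,
    reference: str = "Hsa",
) -> GeneAge:
    """Age implied by a reconstruction's gain placement.

    The age is the rank of the oldest age group with a leaf below the
    gain branch.  When Wagner parsimony yields several independent gains,
    the gain whose subtree contains the reference organism (human) dates
    the gene; if none does, the earliest (oldest-reaching) gain is used.
    """
    if not recon.gains:
        raise ValueError(f"{recon.gene}: reconstruction has no gain")
    gain = None
    if len(recon.gains) > 1:
        for gid in recon.gains:
            if reference in tree.leaves_below(gid):
                gain = gid
                break
    if gain is None:
        gain = min(recon.gains, key=lambda gid: tree.oldest_rank_below(gid))
    return GeneAge(recon.gene, recon.method, tree.oldest_rank_below(gain))


@dataclass
class EmergenceCurve:
    """Cumulative fraction of a stratum's genes present by each age group."""

    stratum: str
    cumulative: np.ndarray  # length G, non-decreasing, ends at 1.0

    def as_frame(self, scale: AgeScale = DEFAULT_SCALE) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "group_rank": np.arange(1, len(self.cumulative) + 1),
                "group_name": [scale.name(r) for r in range(1, len(self.cumulative) + 1)],
                "cumulative_fraction": self.cumulative,
            }
        )


def emergence_curves(
    ages: list[GeneAge],
    annotations: list[GeneAnnotation] | None,
    scale: AgeScale = DEFAULT_SCALE,
    stratify_by: str = "none",
    group_sizes: dict[int, int] | None = None,
) -> list[EmergenceCurve]:
    """Cumulative emergence of genes along the age scale.

    Per stratum ("all", or one curve per functional tier / subnetwork; a
    multi-membership gene counts once in every stratum it belongs to),
    the curve value at rank r is the fraction of the stratum's genes with
    age rank <= r.  By default the curve is normalized by stratum size so
    it ends at 1; passing ``group_sizes`` (rank -> species count) instead
    divides each group's increment by that group's size.
    """
    if stratify_by not in {"none", "tier", "subnetwork"}:
        raise ValueError("stratify_by must be none, tier or subnetwork")
    G = len(scale)
    strata: dict[str, list[int]] = {}
    if stratify_by == "none":
        strata["all"] = [a.rank for a in ages]
    else:
        ann_of = {a.gene: a for a in (annotations or [])}
        for age in ages:
            ann = ann_of.get(age.gene)
            if ann is None:
                continue
            keys = ann.tiers if stratify_by == "tier" else ann.subnetworks
            for key in keys:
                strata.setdefault(key, []).append(age.rank)
    curves = []
    for name in sorted(strata):
        ranks = strata[name]
        if not ranks:
            warnings.warn(f"stratum {name!r} is empty; curve omitted")
            continue
        counts = np.bincount(ranks, minlength=G + 1)[1:].astype(float)
        if group_sizes is not None:
            denom = np.array([group_sizes.get(r, 1) for r in range(1, G + 1)], float)
            inc = counts / denom
            cum = np.cumsum(inc)
            cum = cum / cum[-1] if cum[-1] > 0 else cum
        else:
            cum = np.cumsum(counts) / len(ranks)
        curves.append(EmergenceCurve(name, cum))
    return curves


def ages_table(ages: list[GeneAge], scale: AgeScale = DEFAULT_SCALE) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [a.gene for a in ages],
            "method": [a.method for a in ages],
            "age_rank": [a.rank for a in ages],
            "age_name": [scale.name(a.rank) for a in ages],
            "flags": ["|".join(a.flags) for a in ages],
        }
    )
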