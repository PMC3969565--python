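"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own algorithms: parsimony
costs come from exhaustive enumeration over ancestral labelings, Fisher
p-values from direct hypergeometric sums, and Mann-Whitney p-values from
enumeration over label assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from netage.core import DEFAULT_SCALE, SpeciesTree, parse_species_tree
from netage.datasets import load_ddr_ptm_pairs, load_fixture_tree


@pytest.fixture(scope="session")
def fixture_tree() -> SpeciesTree:
    return load_fixture_tree()


@pytest.fixture(scope="session")
def ddr_network():
    return load_ddr_ptm_pairs()


@pytest.fixture()
def four_leaf_tree() -> SpeciesTree:
    # ((A,B),(C,D)) with distinct groups so ages are informative
    return parse_species_tree(
        "((A,B),(C,D));",
        {"A": "Prokaryota", "B": "early Eukaryota", "C": "Opisthokonta", "D": "Mammalia"},
    )


def make_row(tree: SpeciesTree, present: set[str]) -> pd.Series:
    return pd.Series({s: int(s in present) for s in tree.leaves})


def random_tree(rng: np.random.Generator, n_leaves: int) -> SpeciesTree:
    """Random rooted tree (binary or multifurcating) with random leaf groups."""
    labels = [f"L{i}" for i in range(n_leaves)]
    subtrees = list(labels)
    while len(subtrees) > 1:
        k = min(len(subtrees), 2 if rng.random() < 0.7 else 3)
        picks = rng.choice(len(subtrees), size=k, replace=False)
        merged = "(" + ",".join(subtrees[i] for i in sorted(picks)) + ")"
        subtrees = [s for i, s in enumerate(subtrees) if i not in picks] + [merged]
    names = [g.name for g in DEFAULT_SCALE.groups]
    groups = {lab: names[rng.integers(len(names))] for lab in labels}
    return parse_species_tree(subtrees[0] + ";", groups)


# ---------------------------------------------------------------- oracles


def _edges(tree: SpeciesTree):
    out = []
    for node in tree.preorder():
        for ch in node.child_nodes():
            out.append((tree.node_id(node), tree.node_id(ch)))
    return out


def exhaustive_wagner_cost(
    tree: SpeciesTree, row: pd.Series, gain_cost: float, loss_cost: float
) -> float:
    """Minimum event cost over all ancestral labelings, by enumeration.

    A present root is itself one gain (on the branch into the root).
    """
    internal = [tree.node_id(n) for n in tree.preorder() if not n.is_leaf()]
    rid = tree.node_id(tree.root)
    edges = _edges(tree)
    leaf_state = {s: int(row[s]) for s in tree.leaves}
    best = math.inf
    for bits in itertools.product((0, 1), repeat=len(internal)):
        st = dict(zip(internal, bits))
        st.update(leaf_state)
        cost = gain_cost * st[rid]
        for p, c in edges:
            if st[p] == 0 and st[c] == 1:
                cost += gain_cost
            elif st[p] == 1 and st[c] == 0:
                cost += loss_cost
        best = min(best, cost)
    return best


def exhaustive_dollo(tree: SpeciesTree, row: pd.Series) -> tuple[int, str]:
    """(min losses, gain node id) over all single-gain labelings."""
    internal = [tree.node_id(n) for n in tree.preorder() if not n.is_leaf()]
    rid = tree.node_id(tree.root)
    edges = _edges(tree)
    leaf_state = {s: int(row[s]) for s in tree.leaves}
    best = None
    for bits in itertools.product((0, 1), repeat=len(internal)):
        st = dict(zip(internal, bits))
        st.update(leaf_state)
        gains = [c for p, c in edges if st[p] == 0 and st[c] == 1]
        if st[rid] == 1:
            gains.append(rid)
        if len(gains) != 1:
            continue
        losses = sum(1 for p, c in edges if st[p] == 1 and st[c] == 0)
        if best is None or losses < best[0]:
            best = (losses, gains[0])
    assert best is not None
    return best


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lf = [math.lgamma(k + 1) for k in range(n + 1)]

    def logp(x: int) -> float:
        # P(a = x) for fixed margins
        b_, c_, d_ = r1 - x, c1 - x, n - r1 - c1 + x
        return (
            lf[r1] + lf[n - r1] + lf[c1] + lf[n - c1]
            - lf[n] - lf[x] - lf[b_] - lf[c_] - lf[d_]
        )

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    obs = logp(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = logp(x)
        if lp <= obs + 1e-9:
            total += math.exp(lp)
    return min(1.0, total)


def mannwhitney_oracle(xs: list[float], ys: list[float]) -> tuple[float, float]:
    """U and exact two-sided p by enumeration over all label assignments."""
    from scipy.stats import rankdata

    n1 = len(xs)
    pooled = np.asarray(list(xs) + list(ys), float)
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * len(ys) / 2
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = float(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return u_obs, hits / total
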