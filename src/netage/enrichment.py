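"""Age-enrichment statistics of a gene set against a background.

Per age group, a two-sided Fisher exact test asks whether the input set
is over- or under-represented relative to the background; p-values are
Bonferroni-corrected over the groups tested.  A global Mann-Whitney U
test compares the full age-rank distributions.  Ages are in group-rank
units by default; an optional group-to-MYA map converts the summary
means/medians to millions of years.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AgeScale, DEFAULT_SCALE
from .gene_age import GeneAge


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Defined as the sum of hypergeometric probabilities of all tables with
    the same margins whose point probability does not exceed that of the
    observed table.  A table with any zero margin carries no information
    and returns 1.0 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def mann_whitney_u(
    xs: list[float], ys: list[float], exact_limit: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U (for ``xs``) with a two-sided p-value.

    U comes from midrank sums.  For small samples (n1 + n2 <=
    ``exact_limit``) the p-value is computed by exhaustive enumeration of
    all label assignments (correct under ties); otherwise the normal
    approximation with tie correction is used.
    """
    xs = list(map(float, xs))
    ys = list(map(float, ys))
    if not xs or not ys:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(xs), len(ys)
    pooled = np.asarray(xs + ys)
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 + n2 <= exact_limit:
        mu = n1 * n2 / 2
        obs_dev = abs(u1 - mu)
        total = 0
        hits = 0
        idx = range(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            u = float(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2)
            total += 1
            if abs(u - mu) >= obs_dev - 1e-9:
                hits += 1
        return u1, hits / total
    p = float(
        stats.mannwhitneyu(xs, ys, alternative="two-sided", method="asymptotic").pvalue
    )
    return u1, p


@dataclass
class EnrichmentReport:
    """Per-group Fisher tests plus a global rank comparison."""

    per_group: pd.DataFrame  # group_rank, group_name, observed, background,
    # p_fisher, p_bonferroni, direction
    u_statistic: float
    u_pvalue: float
    mean_input: float
    mean_background: float
    median_input: float
    median_background: float
    n_input: int
    n_background: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.per_group[self.per_group["p_bonferroni"] < alpha]


def age_enrichment_report(
    input_ages: list[GeneAge],
    background: dict[str, int] | pd.Series,
    scale: AgeScale = DEFAULT_SCALE,
    mya_map: dict[int, float] | None = None,
) -> EnrichmentReport:
    """Test whether a gene set is enriched at particular ages.

    ``background`` maps gene symbols to age ranks; input genes present in
    the background are removed from it before testing so the two samples
    are disjoint.  Per group the 2x2 table (input in/not in group vs
    background in/not in group) feeds a two-sided Fisher test; the
    Bonferroni factor is the number of groups with a nonzero background
    count.  Direction is "over" when the input proportion exceeds the
    background's.  ``mya_map`` (rank -> millions of years) switches the
    summary statistics from rank units to MYA.
    """
    if isinstance(background, pd.Series):
        background = background.to_dict()
    if not background:
        raise ValueError("background is empty")
    input_genes = {a.gene for a in input_ages}
    bg_ranks = [r for g, r in background.items() if g not in input_genes]
    if not bg_ranks:
        raise ValueError("background is empty after removing input genes")
    in_ranks = [a.rank for a in input_ages]
    n_in, n_bg = len(in_ranks), len(bg_ranks)
    G = len(scale)
    in_counts = np.bincount(in_ranks, minlength=G + 1)[1:]
    bg_counts = np.bincount(bg_ranks, minlength=G + 1)[1:]
    m = int((bg_counts > 0).sum())
    rows = []
    for r in range(1, G + 1):
        a = int(in_counts[r - 1])
        c = int(bg_counts[r - 1])
        p = fisher_exact_two_sided(a, n_in - a, c, n_bg - c)
        direction = "over" if a / n_in > c / n_bg else ("under" if a / n_in < c / n_bg else "none")
        rows.append(
            {
                "group_rank": r,
                "group_name": scale.name(r),
                "observed": a,
                "background": c,
                "p_fisher": p,
                "p_bonferroni": min(1.0, p * m),
                "direction": direction,
            }
        )
    per_group = pd.DataFrame(rows)
    conv = (lambda v: mya_map[v]) if mya_map else (lambda v: float(v))
    in_units = [conv(r) for r in in_ranks]
    bg_units = [conv(r) for r in bg_ranks]
    u, p_u = mann_whitney_u(in_units, bg_units)
    return EnrichmentReport(
        per_group=per_group,
        u_statistic=u,
        u_pvalue=p_u,
        mean_input=float(np.mean(in_units)),
        mean_background=float(np.mean(bg_units)),
        median_input=float(np.median(in_units)),
        median_background=float(np.median(bg_units)),
        n_input=n_in,
        n_background=n_bg,
    )
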