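"""Age coupling in the posttranslational-modification (PTM) network.

Each directed target-modifier pair (the modifier phosphorylates,
ubiquitinates, sumoylates, (de)acetylates the target) carries the age
group of both genes.  After harmonizing each gene to a single age, pairs
fall into three categories: same age, target younger, target older.  Two
permutation nulls assess whether interacting pairs share ages more often
than chance:

* free null -- the modifier column is permuted against the fixed target
  column, preserving both marginal age distributions and the pair count;
* stratified null -- modifiers are permuted only within each observed
  category, preserving the (same, younger, older) triple exactly while
  probing the distribution of age "jumps" (rank differences).

``AgeCouplingModel`` / ``AgeCouplingResults`` wrap the whole analysis in
a fit/results interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AgeScale, DEFAULT_SCALE

PTM_TYPES = ("P", "U", "S", "A", "deA")

PAIR_COLUMNS = [
    "target",
    "target_net",
    "modifier",
    "modifier_net",
    "ptm",
    "target_age",
    "modifier_age",
]


@dataclass
class PTMPair:
    target: str
    modifier: str
    target_net: str
    modifier_net: str
    ptm: str
    target_rank: int
    modifier_rank: int

    @property
    def is_self(self) -> bool:
        return self.target == self.modifier

    @property
    def delta(self) -> int:
        return abs(self.target_rank - self.modifier_rank)


class PTMNetwork:
    """A set of target-modifier pairs with per-gene ages."""

    def __init__(
        self,
        pairs: list[PTMPair],
        scale: AgeScale = DEFAULT_SCALE,
        harmonized: bool = False,
        change_log: list[dict] | None = None,
    ):
        self.pairs = list(pairs)
        self.scale = scale
        self.harmonized = harmonized
        self.change_log = list(change_log or [])

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def nonself(self) -> list[PTMPair]:
        return [p for p in self.pairs if not p.is_self]

    def age_map(self) -> dict[str, int]:
        """Gene -> rank; only well-defined after harmonization."""
        out: dict[str, int] = {}
        for p in self.pairs:
            for g, r in ((p.target, p.target_rank), (p.modifier, p.modifier_rank)):
                if g in out and out[g] != r:
                    raise ValueError(
                        f"gene {g} has inconsistent ages; harmonize first"
                    )
                out[g] = r
        return out

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": [p.target for p in self.pairs],
                "target_net": [p.target_net for p in self.pairs],
                "modifier": [p.modifier for p in self.pairs],
                "modifier_net": [p.modifier_net for p in self.pairs],
                "ptm": [p.ptm for p in self.pairs],
                "target_age": [self.scale.label(p.target_rank) for p in self.pairs],
                "modifier_age": [self.scale.label(p.modifier_rank) for p in self.pairs],
                "self": [p.is_self for p in self.pairs],
            }
        )


def load_ptm_pairs(path_or_buffer, scale: AgeScale = DEFAULT_SCALE) -> PTMNetwork:
    """Load a PTM pair table (TSV with ages as short group labels)."""
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PTM table missing columns: {sorted(missing)}")
    pairs = []
    for i, row in df.iterrows():
        if row["ptm"] not in PTM_TYPES:
            raise ValueError(f"row {i}: unknown PTM code {row['ptm']!r}")
        try:
            tr = scale.rank(row["target_age"])
            mr = scale.rank(row["modifier_age"])
        except KeyError as e:
            raise ValueError(f"row {i}: {e}") from None
        pairs.append(
            PTMPair(
                target=row["target"],
                modifier=row["modifier"],
                target_net=row["target_net"],
                modifier_net=row["modifier_net"],
                ptm=row["ptm"],
                target_rank=tr,
                modifier_rank=mr,
            )
        )
    return PTMNetwork(pairs, scale=scale)


def harmonize_ages(network: PTMNetwork) -> PTMNetwork:
    """Give every gene a single age by majority rule over its appearances.

    A gene printed with different ages in its target and modifier rows is
    mapped to its modal rank; ties break toward the older (smaller) rank.
    Pair ranks are rewritten from the map and every rewritten cell is
    logged.
    """
    votes: dict[str, list[int]] = {}
    for p in network.pairs:
        votes.setdefault(p.target, []).append(p.target_rank)
        votes.setdefault(p.modifier, []).append(p.modifier_rank)
    resolved: dict[str, int] = {}
    for g, ranks in votes.items():
        counts: dict[int, int] = {}
        for r in ranks:
            counts[r] = counts.get(r, 0) + 1
        resolved[g] = min(counts, key=lambda r: (-counts[r], r))
    changes = []
    new_pairs = []
    for i, p in enumerate(network.pairs):
        tr, mr = resolved[p.target], resolved[p.modifier]
        if tr != p.target_rank:
            changes.append(
                {"row": i, "gene": p.target, "role": "target",
                 "from": p.target_rank, "to": tr}
            )
        if mr != p.modifier_rank:
            changes.append(
                {"row": i, "gene": p.modifier, "role": "modifier",
                 "from": p.modifier_rank, "to": mr}
            )
        new_pairs.append(
            PTMPair(p.target, p.modifier, p.target_net, p.modifier_net, p.ptm, tr, mr)
        )
    return PTMNetwork(new_pairs, scale=network.scale, harmonized=True, change_log=changes)


CATEGORIES = ("same", "target_younger", "target_older")


def _category(target_rank: int, modifier_rank: int) -> str:
    if target_rank == modifier_rank:
        return "same"
    return "target_younger" if target_rank > modifier_rank else "target_older"


def classify_pairs(network: PTMNetwork) -> pd.DataFrame:
    """Per-pair age category and rank distance (self pairs excluded)."""
    _require_harmonized(network)
    rows = []
    for p in network.nonself:
        rows.append(
            {
                "target": p.target,
                "modifier": p.modifier,
                "category": _category(p.target_rank, p.modifier_rank),
                "delta": p.delta,
            }
        )
    return pd.DataFrame(rows, columns=["target", "modifier", "category", "delta"])


def _require_harmonized(network: PTMNetwork) -> None:
    if not network.harmonized:
        raise ValueError("network must be harmonized first (harmonize_ages)")


@dataclass
class SummaryCounts:
    n_pairs_with_self: int
    n_pairs: int  # non-self
    ptm_counts: dict[str, int]  # over non-self pairs
    n_targets: int
    n_modifiers: int
    categories: dict[str, int]
    modifiers_per_subnetwork: dict[str, int]


def summarize_network(network: PTMNetwork) -> SummaryCounts:
    """Headline counts of the PTM network (non-self unless noted)."""
    _require_harmonized(network)
    nonself = network.nonself
    ptm_counts = {t: 0 for t in PTM_TYPES}
    for p in nonself:
        ptm_counts[p.ptm] += 1
    cats = {c: 0 for c in CATEGORIES}
    for p in nonself:
        cats[_category(p.target_rank, p.modifier_rank)] += 1
    per_net: dict[str, set] = {}
    for p in network.pairs:
        per_net.setdefault(p.modifier_net, set()).add(p.modifier)
    return SummaryCounts(
        n_pairs_with_self=len(network.pairs),
        n_pairs=len(nonself),
        ptm_counts=ptm_counts,
        n_targets=len({p.target for p in network.pairs}),
        n_modifiers=len({p.modifier for p in network.pairs}),
        categories=cats,
        modifiers_per_subnetwork={k: len(v) for k, v in sorted(per_net.items())},
    )


def jump_profile(network: PTMNetwork, threshold: int = 3) -> tuple[int, int]:
    """(small, large) jump counts over non-self, different-age pairs.

    A jump is the absolute rank difference of a pair; jumps below
    ``threshold`` ranks are "small", the rest "large".
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    _require_harmonized(network)
    small = large = 0
    for p in network.nonself:
        if p.delta == 0:
            continue
        if p.delta < threshold:
            small += 1
        else:
            large += 1
    return small, large


@dataclass
class NullDistribution:
    """Replicate-level statistics from one randomization scheme."""

    scheme: str  # free | stratified
    replicates: int
    seed: int
    stats: pd.DataFrame  # one row per replicate
    observed: dict[str, float]
    mean: dict[str, float]
    sd: dict[str, float]
    p_two_sided: dict[str, float]
    p_greater: dict[str, float]  # one-sided: observed >= null


def _empirical_p(observed: float, values: np.ndarray) -> tuple[float, float]:
    """(two-sided, one-sided greater) empirical p with +1 smoothing."""
    n = len(values)
    p_hi = (1 + int((values >= observed).sum())) / (n + 1)
    p_lo = (1 + int((values <= observed).sum())) / (n + 1)
    return min(1.0, 2 * min(p_hi, p_lo)), p_hi


def _summarize_null(
    scheme: str, seed: int, stats_df: pd.DataFrame, observed: dict[str, float]
) -> NullDistribution:
    mean = {k: float(stats_df[k].mean()) for k in stats_df.columns}
    sd = {k: float(stats_df[k].std(ddof=0)) for k in stats_df.columns}
    p2, pg = {}, {}
    for k in stats_df.columns:
        p2[k], pg[k] = _empirical_p(observed[k], stats_df[k].to_numpy())
    return NullDistribution(
        scheme=scheme,
        replicates=len(stats_df),
        seed=seed,
        stats=stats_df,
        observed=observed,
        mean=mean,
        sd=sd,
        p_two_sided=p2,
        p_greater=pg,
    )


def _observed_stats(pairs: list[PTMPair], threshold: int) -> dict[str, float]:
    cats = {c: 0 for c in CATEGORIES}
    small = large = 0
    large_by = {"target_younger": 0, "target_older": 0}
    for p in pairs:
        c = _category(p.target_rank, p.modifier_rank)
        cats[c] += 1
        if p.delta > 0:
            if p.delta < threshold:
                small += 1
            else:
                large += 1
                if c in large_by:
                    large_by[c] += 1
    # "target_younger" pairs are those whose modifier is the older member
    return {
        **{c: float(cats[c]) for c in CATEGORIES},
        "different": float(cats["target_younger"] + cats["target_older"]),
        "small_jumps": float(small),
        "large_jumps": float(large),
        "large_jumps_modifier_older": float(large_by["target_younger"]),
        "large_jumps_modifier_younger": float(large_by["target_older"]),
    }


_MAX_REJECT = 10_000


def randomize_free(
    network: PTMNetwork, n_reps: int = 1000, seed: int = 0, threshold: int = 3
) -> NullDistribution:
    """Free permutation null over the non-self pairs.

    Each replicate permutes the modifier column against the fixed target
    column uniformly at random; replicates producing any self-pair are
    redrawn wholesale so the sample space matches the observed network
    (self-modifications excluded).  Category frequencies and jump counts
    are recorded per replicate, with mean/sd and empirical p-values
    ((r+1)/(n+1) smoothing; two-sided doubles the smaller tail).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    _require_harmonized(network)
    pairs = network.nonself
    targets = [p.target for p in pairs]
    t_ranks = np.array([p.target_rank for p in pairs])
    modifiers = [p.modifier for p in pairs]
    m_ranks = np.array([p.modifier_rank for p in pairs])
    rng = np.random.default_rng(seed)
    n = len(pairs)
    rows = []
    for _ in range(n_reps):
        for _try in range(_MAX_REJECT):
            perm = rng.permutation(n)
            if all(targets[i] != modifiers[perm[i]] for i in range(n)):
                break
        else:
            raise RuntimeError("could not draw a self-pair-free permutation")
        pm = m_ranks[perm]
        rep_pairs = [
            PTMPair(targets[i], modifiers[perm[i]], "", "", "x",
                    int(t_ranks[i]), int(pm[i]))
            for i in range(n)
        ]
        rows.append(_observed_stats(rep_pairs, threshold))
    stats_df = pd.DataFrame(rows)
    observed = _observed_stats(pairs, threshold)
    return _summarize_null("free", seed, stats_df, observed)


def randomize_stratified(
    network: PTMNetwork, n_reps: int = 1000, seed: int = 0, threshold: int = 3
) -> NullDistribution:
    """Category-preserving permutation null.

    Modifiers are permuted only within each observed category stratum
    (same / target-younger / target-older), so the observed category
    triple is preserved exactly by construction; a pair keeps its stratum
    label while its age distance is recomputed from the reassigned
    modifier.  Replicates creating a self-pair are redrawn.  The
    jump-size statistics probe whether observed distances differ from
    chance given the category counts.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    _require_harmonized(network)
    pairs = network.nonself
    strata: dict[str, list[int]] = {c: [] for c in CATEGORIES}
    for i, p in enumerate(pairs):
        strata[_category(p.target_rank, p.modifier_rank)].append(i)
    rng = np.random.default_rng(seed)
    rows = []
    cats_obs = {c: float(len(strata[c])) for c in CATEGORIES}
    for _ in range(n_reps):
        small = large = 0
        large_by = {"target_younger": 0, "target_older": 0}
        for cat, idx in strata.items():
            if not idx:
                continue
            for _try in range(_MAX_REJECT):
                perm = rng.permutation(len(idx))
                if all(
                    pairs[idx[k]].target != pairs[idx[perm[k]]].modifier
                    for k in range(len(idx))
                ):
                    break
            else:
                raise RuntimeError("could not draw a self-pair-free permutation")
            for k, i in enumerate(idx):
                j = idx[perm[k]]
                d = abs(pairs[i].target_rank - pairs[j].modifier_rank)
                if d > 0:
                    if d < threshold:
                        small += 1
                    else:
                        large += 1
                        if cat in large_by:
                            large_by[cat] += 1
        rows.append(
            {
                **cats_obs,
                "different": cats_obs["target_younger"] + cats_obs["target_older"],
                "small_jumps": float(small),
                "large_jumps": float(large),
                "large_jumps_modifier_older": float(large_by["target_younger"]),
                "large_jumps_modifier_younger": float(large_by["target_older"]),
            }
        )
    stats_df = pd.DataFrame(rows)
    observed = _observed_stats(pairs, threshold)
    return _summarize_null("stratified", seed, stats_df, observed)


class AgeCouplingModel:
    """Permutation test of age coupling in a target-modifier network.

    Parameters
    ----------
    network : PTMNetwork
        The pair table; harmonized automatically if needed.
    jump_threshold : int
        Rank difference from which a jump counts as "large" (default 3).
    """

    def __init__(self, network: PTMNetwork, jump_threshold: int = 3):
        self.network = network if network.harmonized else harmonize_ages(network)
        self.jump_threshold = jump_threshold

    def fit(self, n_reps: int = 1000, seed: int = 0) -> "AgeCouplingResults":
        free = randomize_free(self.network, n_reps, seed, self.jump_threshold)
        stratified = randomize_stratified(
            self.network, n_reps, seed + 1, self.jump_threshold
        )
        return AgeCouplingResults(self, free, stratified)


class AgeCouplingResults:
    """Observed counts and both permutation nulls, with a summary table."""

    def __init__(
        self,
        model: AgeCouplingModel,
        free: NullDistribution,
        stratified: NullDistribution,
    ):
        self.model = model
        self.free = free
        self.stratified = stratified
        self.summary_counts = summarize_network(model.network)

    @property
    def observed(self) -> dict[str, float]:
        return self.free.observed

    def summary(self) -> pd.DataFrame:
        rows = []
        for stat in self.free.observed:
            rows.append(
                {
                    "statistic": stat,
                    "observed": self.free.observed[stat],
                    "null_mean_free": self.free.mean[stat],
                    "null_sd_free": self.free.sd[stat],
                    "p_free": self.free.p_two_sided[stat],
                    "null_mean_stratified": self.stratified.mean[stat],
                    "null_sd_stratified": self.stratified.sd[stat],
                    "p_stratified_greater": self.stratified.p_greater[stat],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        s = self.summary_counts
        def _null(d: NullDistribution) -> dict:
            return {
                "scheme": d.scheme,
                "replicates": d.replicates,
                "seed": d.seed,
                "observed": d.observed,
                "mean": d.mean,
                "sd": d.sd,
                "p_two_sided": d.p_two_sided,
                "p_greater": d.p_greater,
            }
        return {
            "summary": {
                "n_pairs_with_self": s.n_pairs_with_self,
                "n_pairs": s.n_pairs,
                "ptm_counts": s.ptm_counts,
                "n_targets": s.n_targets,
                "n_modifiers": s.n_modifiers,
                "categories": s.categories,
                "modifiers_per_subnetwork": s.modifiers_per_subnetwork,
            },
            "harmonization_changes": self.model.network.change_log,
            "free_null": _null(self.free),
            "stratified_null": _null(self.stratified),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
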