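"""Age scale, species tree and gene annotations shared by every stage.

The evolutionary age of a gene is expressed on an ordered scale of clade
strata ("age groups"), from Prokaryota (rank 1, most ancient) to Mammalia
(rank 11, most recent).  A species tree carries one age group per leaf;
every downstream computation (oldest-hit ages, parsimony reconstructions,
age distances in the PTM network) compares genes on the integer ranks of
this scale.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy


class UnknownSpeciesError(KeyError):
    """A tree leaf has no age-group assignment."""


class UnknownAgeError(KeyError):
    """An age-group name or short label is not on the scale."""


@dataclass(frozen=True)
class AgeGroup:
    rank: int
    name: str
    label: str


# The 11 strata spanning the species panel, oldest first.  Short labels
# follow the convention used in the PTM pair table ("V" is Viridiplantae,
# "Vr" is Vertebrata).
_DEFAULT_GROUPS = [
    (1, "Prokaryota", "Pr"),
    (2, "early Eukaryota", "E"),
    (3, "Viridiplantae", "V"),
    (4, "Unikonta", "U"),
    (5, "Opisthokonta", "O"),
    (6, "Metazoa", "M"),
    (7, "Radiata", "R"),
    (8, "Bilateria", "B"),
    (9, "Chordata", "Ch"),
    (10, "Vertebrata", "Vr"),
    (11, "Mammalia", "Ma"),
]


@dataclass(frozen=True)
class AgeScale:
    """Ordered set of evolutionary age groups with integer ranks.

    Ranks are consecutive integers starting at 1; a lower rank is a more
    ancient stratum.  Lookup accepts full names and short labels,
    case-insensitively, as exact tokens.
    """

    groups: tuple[AgeGroup, ...]

    def __post_init__(self) -> None:
        ranks = [g.rank for g in self.groups]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be consecutive integers starting at 1")
        names = [g.name for g in self.groups]
        labels = [g.label for g in self.groups]
        if len(set(n.lower() for n in names + labels)) != len(names + labels):
            raise ValueError("group names and labels must be unique")

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def _lookup(self) -> dict[str, int]:
        return {
            **{g.name.lower(): g.rank for g in self.groups},
            **{g.label.lower(): g.rank for g in self.groups},
        }

    def rank(self, name_or_label: str) -> int:
        try:
            return self._lookup[name_or_label.strip().lower()]
        except KeyError:
            valid = ", ".join(f"{g.name}/{g.label}" for g in self.groups)
            raise UnknownAgeError(
                f"unknown age group {name_or_label!r}; valid: {valid}"
            ) from None

    def name(self, rank: int) -> str:
        return self.groups[rank - 1].name

    def label(self, rank: int) -> str:
        return self.groups[rank - 1].label


DEFAULT_SCALE = AgeScale(tuple(AgeGroup(*g) for g in _DEFAULT_GROUPS))


def age_rank(scale: AgeScale, name_or_label: str) -> int:
    """Rank of an age group given its full name or short label."""
    return scale.rank(name_or_label)


@dataclass
class GeneAnnotation:
    """Functional annotation of one gene: subnetwork(s) and tier(s).

    Subnetworks are the four DDR compartments (GR, RF, DSB, CHK); tiers
    are the four functional roles (sensor, transducer, mediator,
    effector).  Multi-membership is allowed in both.
    """

    gene: str
    subnetworks: frozenset[str]
    tiers: frozenset[str]
    pathways: tuple[str, ...] = ()

    VALID_SUBNETWORKS = frozenset({"GR", "RF", "DSB", "CHK"})
    VALID_TIERS = frozenset({"sensor", "transducer", "mediator", "effector"})

    def __post_init__(self) -> None:
        if not self.subnetworks:
            raise ValueError(f"{self.gene}: at least one subnetwork required")
        if not self.tiers:
            raise ValueError(f"{self.gene}: at least one tier required")
        bad = set(self.subnetworks) - self.VALID_SUBNETWORKS
        if bad:
            raise ValueError(f"{self.gene}: unknown subnetworks {sorted(bad)}")
        bad = set(self.tiers) - self.VALID_TIERS
        if bad:
            raise ValueError(f"{self.gene}: unknown tiers {sorted(bad)}")


class SpeciesTree:
    """Rooted species tree whose leaves carry species codes and age groups.

    Multifurcating and binary trees are both accepted.  Internal nodes get
    stable identifiers ``N0, N1, ...`` in preorder; a branch is referred to
    by the identifier of its child node (leaf branches by the species
    code).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        group_of: dict[str, str],
        scale: AgeScale = DEFAULT_SCALE,
        complete: dict[str, bool] | None = None,
        full_names: dict[str, str] | None = None,
    ):
        self.tree = tree
        self.scale = scale
        self.full_names = dict(full_names or {})
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            dupes = sorted({x for x in leaves if leaves.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        missing = [lf for lf in leaves if lf not in group_of]
        if missing:
            raise UnknownSpeciesError(f"unknown species: {', '.join(missing)}")
        self.leaves = leaves
        self.group_of = {s: group_of[s] for s in leaves}
        self.complete = {s: (complete or {}).get(s, True) for s in leaves}
        # stable node ids: species code at leaves, preorder N<i> internally
        self._node_id: dict[dendropy.Node, str] = {}
        i = 0
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                self._node_id[node] = node.taxon.label
            else:
                self._node_id[node] = f"N{i}"
                i += 1
        self._id_node = {v: k for k, v in self._node_id.items()}

    # -- structure ---------------------------------------------------------

    def node_id(self, node: dendropy.Node) -> str:
        return self._node_id[node]

    def node(self, node_id: str) -> dendropy.Node:
        return self._id_node[node_id]

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def postorder(self):
        return self.tree.postorder_node_iter()

    def preorder(self):
        return self.tree.preorder_node_iter()

    def leaves_below(self, node_id: str) -> list[str]:
        """Species codes of all leaves in the clade under this branch."""
        node = self.node(node_id)
        if node.is_leaf():
            return [node.taxon.label]
        return [lf.taxon.label for lf in node.leaf_iter()]

    def mrca(self, species: list[str]) -> str:
        """Node id of the most recent common ancestor of these leaves."""
        if not species:
            raise ValueError("mrca of an empty leaf set")
        if len(species) == 1:
            return species[0]
        node = self.tree.mrca(taxon_labels=list(species))
        return self._node_id[node]

    # -- ages --------------------------------------------------------------

    def group_rank(self, species: str) -> int:
        return self.scale.rank(self.group_of[species])

    def oldest_rank_below(self, node_id: str) -> int:
        """Rank of the most ancient age group with a leaf under this branch."""
        return min(self.group_rank(s) for s in self.leaves_below(node_id))

    def species_by_group(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for s in self.leaves:
            out.setdefault(self.group_rank(s), []).append(s)
        return out

    # -- io ----------------------------------------------------------------

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_species_tree(
    newick_text: str,
    group_map: dict[str, str],
    scale: AgeScale = DEFAULT_SCALE,
    complete: dict[str, bool] | None = None,
) -> SpeciesTree:
    """Parse a Newick species tree and attach age groups to its leaves.

    Every leaf label must appear in ``group_map`` (species code ->
    age-group name or short label); branch lengths, if present, are
    ignored.  Leaf order is preserved as written.
    """
    from dendropy.dataio.newickreader import NewickReader

    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate leaf labels: {e}") from None
    tree.is_rooted = True
    for label in group_map.values():
        scale.rank(label)  # validates group names up front
    return SpeciesTree(tree, group_map, scale=scale, complete=complete)


def read_group_map(path_or_buffer) -> tuple[dict[str, str], dict[str, bool]]:
    """Read a species-to-age-group TSV (``species<TAB>age_group[<TAB>complete]``)."""
    import pandas as pd

    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
    if "species" not in df.columns or "age_group" not in df.columns:
        raise ValueError("group map needs columns 'species' and 'age_group'")
    groups = dict(zip(df["species"], df["age_group"]))
    if len(groups) != len(df):
        raise ValueError("duplicate species in group map")
    complete = {}
    if "complete" in df.columns:
        complete = {
            s: str(c).strip().lower() in {"true", "1", "yes"}
            for s, c in zip(df["species"], df["complete"])
        }
    return groups, complete


def write_group_map(tree: SpeciesTree, path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tage_group\tcomplete\n")
        for s in tree.leaves:
            fh.write(f"{s}\t{tree.group_of[s]}\t{str(tree.complete[s]).lower()}\n")


def load_tree_files(tree_path, groups_path, scale: AgeScale = DEFAULT_SCALE) -> SpeciesTree:
    """Convenience loader: Newick file plus group-map TSV."""
    with open(tree_path) as fh:
        newick = fh.read()
    groups, complete = read_group_map(groups_path)
    return parse_species_tree(newick, groups, scale=scale, complete=complete)
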