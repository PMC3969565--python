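"""Gene x species presence/absence matrices (phylogenetic profiles).

A profile row records, for one human gene, which species of the panel
carry a detectable homolog.  Cells derive from scored bidirectional
ortholog hits; a transitive extension can rescue distant homologs through
a secondary seed organism, and isolated hits (single-species presences far
from the rest of the profile) are flagged as possible artifacts or
horizontal transfers.  Clustering and loss detection operate on the
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpeciesTree

HIT_COLUMNS = [
    "seed_gene",
    "seed_species",
    "target_species",
    "hit_id",
    "score",
    "bidirectional",
]

PROVENANCE_DIRECT = "direct"
PROVENANCE_TRANSITIVE = "transitive"
PROVENANCE_ABSENT = "absent"


def read_hits(path_or_buffer) -> pd.DataFrame:
    """Read a flattened ortholog hit table (TSV).

    Columns: seed_gene, seed_species, target_species, hit_id, score
    (ortholog confidence in [0, 1]) and bidirectional (true/false).
    """
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    df = df[HIT_COLUMNS].copy()
    df["score"] = df["score"].astype(float)
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValueError("hit scores must lie in [0, 1]")
    df["bidirectional"] = (
        df["bidirectional"].astype(str).str.strip().str.lower().isin({"true", "1", "yes"})
    )
    return df


@dataclass
class LossRecord:
    """A candidate gene loss: absence in a species despite older presence."""

    gene: str
    species: str
    oldest_present_rank: int
    note: str = ""


class PhyloProfile:
    """Binary presence/absence matrix with per-cell provenance and flags.

    ``matrix`` holds 0/1 with genes as rows and species as columns;
    ``provenance`` marks each presence as direct or transitive;
    ``isolated`` marks presences suspected to be artifacts.  Species
    columns are ordered by (age-group rank, code).
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        provenance: pd.DataFrame | None = None,
        isolated: pd.DataFrame | None = None,
    ):
        self.matrix = matrix.astype(np.int8)
        self.matrix.index.name = "gene"
        if provenance is None:
            provenance = pd.DataFrame(
                np.where(self.matrix.values == 1, PROVENANCE_DIRECT, PROVENANCE_ABSENT),
                index=matrix.index,
                columns=matrix.columns,
            )
        self.provenance = provenance
        if isolated is None:
            isolated = pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
        self.isolated = isolated
        self._validate()

    def _validate(self) -> None:
        vals = set(np.unique(self.matrix.values)) if self.matrix.size else set()
        if not vals <= {0, 1}:
            raise ValueError("profile cells must be 0 or 1")
        trans = self.provenance.values == PROVENANCE_TRANSITIVE
        if (trans & (self.matrix.values == 0)).any():
            raise ValueError("transitive provenance requires presence")
        if (self.isolated.values & (self.matrix.values == 0)).any():
            raise ValueError("isolated flags require presence")

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def species(self) -> list[str]:
        return list(self.matrix.columns)

    def copy(self) -> "PhyloProfile":
        return PhyloProfile(
            self.matrix.copy(), self.provenance.copy(), self.isolated.copy()
        )

    def row(self, gene: str) -> pd.Series:
        return self.matrix.loc[gene]

    # -- io ----------------------------------------------------------------

    def write(self, matrix_path, flags_path=None) -> None:
        out = self.matrix.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(matrix_path, sep="\t", index=False)
        if flags_path is not None:
            rows = []
            for g in self.genes:
                for s in self.species:
                    if self.provenance.loc[g, s] == PROVENANCE_TRANSITIVE:
                        rows.append((g, s, "transitive"))
                    if self.isolated.loc[g, s]:
                        rows.append((g, s, "isolated"))
            pd.DataFrame(rows, columns=["gene", "species", "flag"]).to_csv(
                flags_path, sep="\t", index=False
            )

    @classmethod
    def read(cls, matrix_path, flags_path=None) -> "PhyloProfile":
        df = pd.read_csv(matrix_path, sep="\t", dtype={"gene": str})
        df = df.set_index("gene")
        prof = cls(df)
        if flags_path is not None:
            flags = pd.read_csv(flags_path, sep="\t", dtype=str)
            for _, r in flags.iterrows():
                if r["flag"] == "transitive":
                    prof.provenance.loc[r["gene"], r["species"]] = PROVENANCE_TRANSITIVE
                elif r["flag"] == "isolated":
                    prof.isolated.loc[r["gene"], r["species"]] = True
        prof._validate()
        return prof


def _species_order(tree: SpeciesTree) -> list[str]:
    return sorted(tree.leaves, key=lambda s: (tree.group_rank(s), s))


def build_profile(
    hits: pd.DataFrame,
    genes: list[str],
    tree: SpeciesTree,
    min_score: float = 0.05,
    seed_species: str | None = "Hsa",
) -> PhyloProfile:
    """Build a presence/absence profile from a bidirectional hit table.

    A cell (gene, species) is 1 iff at least one bidirectional hit with
    score >= ``min_score`` exists.  The seed organism's own column is set
    to 1 for every gene (each seed gene trivially has itself); pass
    ``seed_species=None`` to disable.  Hits for genes outside ``genes``
    are skipped with a warning; hits in species absent from the tree are
    an error.
    """
    if not genes:
        raise ValueError("gene list is empty")
    unknown_sp = set(hits["target_species"]) - set(tree.leaves)
    if unknown_sp:
        raise KeyError(f"unknown species in hit table: {sorted(unknown_sp)}")
    gene_set = set(genes)
    unknown_genes = sorted(set(hits["seed_gene"]) - gene_set)
    if unknown_genes:
        warnings.warn(f"skipping hits for unknown genes: {unknown_genes}")
    species = _species_order(tree)
    mat = pd.DataFrame(0, index=list(genes), columns=species, dtype=np.int8)
    kept = hits[
        hits["seed_gene"].isin(gene_set)
        & hits["bidirectional"]
        & (hits["score"] >= min_score)
    ]
    for g, s in zip(kept["seed_gene"], kept["target_species"]):
        mat.loc[g, s] = 1
    if seed_species is not None:
        if seed_species not in species:
            raise KeyError(f"seed species {seed_species!r} not in tree")
        mat[seed_species] = 1
    return PhyloProfile(mat)


def apply_transitive_extension(
    profile: PhyloProfile,
    secondary_hits: dict[str, pd.DataFrame],
    links: pd.DataFrame,
    min_score: float = 0.05,
) -> PhyloProfile:
    """Extend a profile through secondary seed organisms.

    ``links`` maps a human gene to its ortholog in a secondary seed
    organism (columns: human_gene, seed_species, seed_gene); the link is
    only trusted when the human gene is itself present (bidirectional) in
    that seed organism.  Wherever the human gene is absent but the linked
    seed gene has a bidirectional hit, the cell becomes 1 with transitive
    provenance.  Existing presences are never unset; the operation is
    idempotent.
    """
    out = profile.copy()
    for col in ("human_gene", "seed_species", "seed_gene"):
        if col not in links.columns:
            raise ValueError(f"links table missing column {col!r}")
    for _, link in links.iterrows():
        g, seed_org, seed_gene = link["human_gene"], link["seed_species"], link["seed_gene"]
        if seed_org not in secondary_hits:
            raise KeyError(f"no secondary hit table for seed organism {seed_org!r}")
        if g not in out.matrix.index:
            warnings.warn(f"link for unknown gene {g!r} ignored")
            continue
        if seed_org not in out.matrix.columns or out.matrix.loc[g, seed_org] != 1:
            warnings.warn(
                f"link {g}->{seed_gene} ignored: {g} has no bidirectional hit in {seed_org}"
            )
            continue
        sec = secondary_hits[seed_org]
        ok = sec[
            (sec["seed_gene"] == seed_gene)
            & sec["bidirectional"]
            & (sec["score"] >= min_score)
        ]
        for s in ok["target_species"]:
            if s in out.matrix.columns and out.matrix.loc[g, s] == 0:
                out.matrix.loc[g, s] = 1
                out.provenance.loc[g, s] = PROVENANCE_TRANSITIVE
    return out


def flag_isolated_hits(
    profile: PhyloProfile,
    tree: SpeciesTree,
    max_group_support: int = 1,
    min_gap: int = 2,
) -> PhyloProfile:
    """Flag presences isolated from the rest of a gene's profile.

    A presence cell is flagged when its age group holds at most
    ``max_group_support`` present species for that gene and the nearest
    other age group with any presence is at least ``min_gap`` ranks away.
    Such hits (a lone bacterial homolog of an otherwise animal-only gene)
    suggest contamination, annotation artifacts or horizontal transfer.
    Flags never alter the matrix.
    """
    if max_group_support < 1 or min_gap < 1:
        raise ValueError("max_group_support and min_gap must be >= 1")
    out = profile.copy()
    by_group = tree.species_by_group()
    for g in out.genes:
        row = out.matrix.loc[g]
        support = {
            rank: int(sum(row.get(s, 0) for s in members))
            for rank, members in by_group.items()
        }
        present_ranks = [r for r, n in support.items() if n > 0]
        if len(present_ranks) < 2:
            continue
        for rank in present_ranks:
            if support[rank] > max_group_support:
                continue
            gap = min(abs(rank - r) for r in present_ranks if r != rank)
            if gap >= min_gap:
                for s in by_group[rank]:
                    if row.get(s, 0) == 1:
                        out.isolated.loc[g, s] = True
    return out


def _upgma(data: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) agglomeration with a deterministic tie-break.

    Returns a scipy-style linkage matrix.  When two candidate merges are
    at equal distance, the pair whose smallest original row index is
    lowest wins (then the other member's smallest index).
    """
    n = data.shape[0]
    # active cluster id -> (size, min original index)
    size = {i: 1 for i in range(n)}
    min_idx = {i: i for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(np.linalg.norm(data[i] - data[j]))
    active = set(range(n))
    Z = np.zeros((max(n - 1, 0), 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                d = dist[(min(i, j), max(i, j))]
                a, b = sorted((min_idx[i], min_idx[j]))
                key = (d, a, b)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        Z[step] = [i, j, d, size[i] + size[j]]
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = (size[i] * dik + size[j] * djk) / (size[i] + size[j])
            dist[(min(k, next_id), max(k, next_id))] = dnew
        size[next_id] = size[i] + size[j]
        min_idx[next_id] = min(min_idx[i], min_idx[j])
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return Z


def cluster_genes(profile: PhyloProfile) -> tuple[list[str], np.ndarray]:
    """Hierarchically cluster gene rows (Euclidean distance, UPGMA).

    Returns the dendrogram leaf order (gene symbols) and the merge
    history as a scipy-compatible linkage matrix.  Ties are broken by the
    smallest original row index, so the result is deterministic.
    """
    genes = profile.genes
    if len(genes) == 0:
        raise ValueError("profile has no genes")
    if len(genes) == 1:
        return list(genes), np.zeros((0, 4))
    Z = _upgma(profile.matrix.values.astype(float))
    n = len(genes)
    # leaf order: expand clusters recursively, lower-min-index side first
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    min_idx: dict[int, int] = {i: i for i in range(n)}
    for step, (i, j, _, _) in enumerate(Z[:, :4]):
        i, j = int(i), int(j)
        first, second = (i, j) if min_idx[i] <= min_idx[j] else (j, i)
        members[n + step] = members[first] + members[second]
        min_idx[n + step] = min(min_idx[i], min_idx[j])
    order = members[2 * n - 2]
    return [genes[k] for k in order], Z


def detect_model_organism_losses(
    profile: PhyloProfile,
    tree: SpeciesTree,
    targets: list[str],
) -> list[LossRecord]:
    """Candidate gene losses in selected (model) species.

    For each target species and gene with an absent cell, a loss is
    recorded iff the gene is present in at least one species of a
    strictly older age group -- i.e. the gene predates the target's
    stratum, so its absence there is a loss rather than a late birth.
    Absences in draft genomes are recorded with a cautionary note.
    """
    unknown = set(targets) - set(tree.leaves)
    if unknown:
        raise KeyError(f"unknown target species: {sorted(unknown)}")
    records: list[LossRecord] = []
    ranks = {s: tree.group_rank(s) for s in profile.species if s in tree.group_of}
    for g in profile.genes:
        row = profile.matrix.loc[g]
        present_ranks = [ranks[s] for s in profile.species if row[s] == 1]
        if not present_ranks:
            continue
        oldest = min(present_ranks)
        for t in targets:
            if row.get(t, 0) == 0 and oldest < tree.group_rank(t):
                note = "" if tree.complete.get(t, True) else "draft genome"
                records.append(LossRecord(g, t, oldest, note))
    return records
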