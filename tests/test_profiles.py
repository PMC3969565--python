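"""Profile construction, transitive extension, flags, clustering, losses."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from netage.core import parse_species_tree
from netage.profiles import (
    PhyloProfile,
    apply_transitive_extension,
    build_profile,
    cluster_genes,
    detect_model_organism_losses,
    flag_isolated_hits,
)
from netage.simulate import profile_to_hits, simulate_profile_set


def hits_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["seed_gene", "seed_species", "target_species", "hit_id", "score", "bidirectional"],
    )


@pytest.fixture()
def tiny_tree():
    return parse_species_tree(
        "((Hsa,Dme),Ath);",
        {"Hsa": "Mammalia", "Dme": "Bilateria", "Ath": "Viridiplantae"},
    )


class TestBuildProfile:
    def test_single_hit_row(self, tiny_tree):
        hits = hits_frame([("ATM", "Hsa", "Ath", "id1", 1.0, True)])
        prof = build_profile(hits, ["ATM"], tiny_tree)
        # species sorted by (group rank, code): Ath(3), Dme(8), Hsa(11)
        assert prof.species == ["Ath", "Dme", "Hsa"]
        assert list(prof.matrix.loc["ATM"]) == [1, 0, 1]

    def test_seed_self_presence_with_empty_hits(self, tiny_tree):
        prof = build_profile(hits_frame([]), ["X"], tiny_tree)
        assert list(prof.matrix.loc["X"]) == [0, 0, 1]

    def test_unknown_species_is_error(self, tiny_tree):
        hits = hits_frame([("ATM", "Hsa", "Zzz", "id1", 1.0, True)])
        with pytest.raises(KeyError, match="Zzz"):
            build_profile(hits, ["ATM"], tiny_tree)

    def test_unknown_gene_warned_and_skipped(self, tiny_tree):
        hits = hits_frame([("NOPE", "Hsa", "Ath", "id1", 1.0, True)])
        with pytest.warns(UserWarning, match="NOPE"):
            prof = build_profile(hits, ["ATM"], tiny_tree)
        assert prof.matrix.loc["ATM", "Ath"] == 0

    def test_non_bidirectional_and_low_score_ignored(self, tiny_tree):
        hits = hits_frame(
            [
                ("ATM", "Hsa", "Ath", "id1", 1.0, False),
                ("ATM", "Hsa", "Dme", "id2", 0.01, True),
            ]
        )
        prof = build_profile(hits, ["ATM"], tiny_tree, min_score=0.05)
        assert list(prof.matrix.loc["ATM"]) == [0, 0, 1]

    @pytest.mark.parametrize("lo,hi", [(0.0, 0.3), (0.3, 0.9)])
    def test_monotone_in_min_score(self, tiny_tree, lo, hi):
        rng = np.random.default_rng(5)
        rows = [
            (f"G{i%4}", "Hsa", sp, f"h{i}", float(rng.random()), True)
            for i, sp in enumerate(rng.choice(["Ath", "Dme"], size=40))
        ]
        genes = [f"G{i}" for i in range(4)]
        low = build_profile(hits_frame(rows), genes, tiny_tree, min_score=lo)
        high = build_profile(hits_frame(rows), genes, tiny_tree, min_score=hi)
        assert (high.matrix.values <= low.matrix.values).all()

    def test_roundtrip_through_generator(self, fixture_tree):
        prof, _ = simulate_profile_set(
            fixture_tree, 100, {1: 0.2, 2: 0.5, 5: 0.3}, loss_rate=0.25, seed=11
        )
        rebuilt = build_profile(
            profile_to_hits(prof), prof.genes, fixture_tree, seed_species=None
        )
        pd.testing.assert_frame_equal(rebuilt.matrix, prof.matrix)


class TestTransitiveExtension:
    def links(self, gene="X"):
        return pd.DataFrame(
            [{"human_gene": gene, "seed_species": "Sce", "seed_gene": f"{gene}_sce"}]
        )

    @pytest.fixture()
    def tree(self):
        return parse_species_tree(
            "((Hsa,Sce),Ngr);",
            {"Hsa": "Mammalia", "Sce": "Opisthokonta", "Ngr": "early Eukaryota"},
        )

    def test_rescues_distant_homolog(self, tree):
        prof = build_profile(
            hits_frame([("X", "Hsa", "Sce", "h1", 1.0, True)]), ["X"], tree
        )
        sec = {"Sce": hits_frame([("X_sce", "Sce", "Ngr", "h2", 0.9, True)])}
        ext = apply_transitive_extension(prof, sec, self.links())
        assert ext.matrix.loc["X", "Ngr"] == 1
        assert ext.provenance.loc["X", "Ngr"] == "transitive"

    def test_existing_presence_untouched(self, tree):
        prof = build_profile(
            hits_frame(
                [("X", "Hsa", "Sce", "h1", 1.0, True), ("X", "Hsa", "Ngr", "h0", 1.0, True)]
            ),
            ["X"],
            tree,
        )
        sec = {"Sce": hits_frame([("X_sce", "Sce", "Ngr", "h2", 0.9, True)])}
        ext = apply_transitive_extension(prof, sec, self.links())
        assert ext.provenance.loc["X", "Ngr"] == "direct"

    def test_link_without_bidirectional_anchor_ignored(self, tree):
        prof = build_profile(hits_frame([]), ["X"], tree)  # X absent in Sce
        sec = {"Sce": hits_frame([("X_sce", "Sce", "Ngr", "h2", 0.9, True)])}
        with pytest.warns(UserWarning, match="no bidirectional hit"):
            ext = apply_transitive_extension(prof, sec, self.links())
        assert ext.matrix.loc["X", "Ngr"] == 0

    def test_idempotent_and_monotone(self, tree):
        prof = build_profile(
            hits_frame([("X", "Hsa", "Sce", "h1", 1.0, True)]), ["X"], tree
        )
        sec = {"Sce": hits_frame([("X_sce", "Sce", "Ngr", "h2", 0.9, True)])}
        once = apply_transitive_extension(prof, sec, self.links())
        twice = apply_transitive_extension(once, sec, self.links())
        assert (once.matrix.values >= prof.matrix.values).all()
        pd.testing.assert_frame_equal(once.matrix, twice.matrix)
        pd.testing.assert_frame_equal(once.provenance, twice.provenance)


class TestIsolatedFlags:
    def test_lone_ancient_hit_flagged(self, fixture_tree):
        # present in the single prokaryote and again only from Metazoa on
        present = {"Eco", "Tad", "Nve", "Dme", "Cin", "Dre", "Hsa"}
        mat = pd.DataFrame(
            {s: [int(s in present)] for s in fixture_tree.leaves}, index=["UBR5ish"]
        )
        prof = flag_isolated_hits(PhyloProfile(mat), fixture_tree)
        assert prof.isolated.loc["UBR5ish", "Eco"]
        assert not prof.isolated.loc["UBR5ish", "Tad"]

    def test_ubiquitous_gene_unflagged(self, fixture_tree):
        mat = pd.DataFrame({s: [1] for s in fixture_tree.leaves}, index=["G"])
        prof = flag_isolated_hits(PhyloProfile(mat), fixture_tree)
        assert not prof.isolated.values.any()

    def test_adjacent_groups_not_isolated(self, fixture_tree):
        # presence in two adjacent strata only: gap 1 < min_gap 2
        mat = pd.DataFrame(
            {s: [int(s in {"Dre", "Hsa"})] for s in fixture_tree.leaves}, index=["G"]
        )
        prof = flag_isolated_hits(PhyloProfile(mat), fixture_tree, max_group_support=1, min_gap=2)
        assert not prof.isolated.values.any()

    def test_flags_never_change_matrix(self, fixture_tree):
        prof, _ = simulate_profile_set(fixture_tree, 30, {1: 0.5, 6: 0.5}, 0.4, seed=3)
        flagged = flag_isolated_hits(prof, fixture_tree)
        pd.testing.assert_frame_equal(flagged.matrix, prof.matrix)
        assert not (flagged.isolated.values & (flagged.matrix.values == 0)).any()


class TestClusterGenes:
    def test_identical_rows_merge_first(self):
        mat = pd.DataFrame(
            [[1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 0, 0]],
            index=["a", "b", "c"],
            columns=["s1", "s2", "s3", "s4"],
        )
        order, Z = cluster_genes(PhyloProfile(mat))
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 2}

    def test_hand_computed_average_linkage(self):
        # rows [1,1,0],[1,0,0],[0,0,1]: first merge at distance 1, then
        # average of sqrt(3) and sqrt(2)
        mat = pd.DataFrame(
            [[1, 1, 0], [1, 0, 0], [0, 0, 1]],
            index=["a", "b", "c"],
            columns=["s1", "s2", "s3"],
        )
        _, Z = cluster_genes(PhyloProfile(mat))
        assert Z[0, 2] == pytest.approx(1.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[1, 2] == pytest.approx((np.sqrt(3) + np.sqrt(2)) / 2)

    def test_matches_scipy_on_tie_free_data(self):
        from netage.profiles import _upgma

        rng = np.random.default_rng(0)
        data = rng.random((12, 6))  # continuous, ties have probability 0
        Z = _upgma(data)
        Z_ref = linkage(data, method="average", metric="euclidean")
        np.testing.assert_allclose(Z[:, 2], Z_ref[:, 2], rtol=1e-9)
        np.testing.assert_allclose(Z[:, 3], Z_ref[:, 3])

    def test_single_gene_identity(self):
        mat = pd.DataFrame([[1, 0]], index=["a"], columns=["s1", "s2"])
        order, Z = cluster_genes(PhyloProfile(mat))
        assert order == ["a"]
        assert Z.shape == (0, 4)

    def test_recovers_planted_blocks(self):
        rng = np.random.default_rng(42)
        patterns = np.array(
            [[1] * 10 + [0] * 20, [0] * 10 + [1] * 10 + [0] * 10, [0] * 20 + [1] * 10]
        )
        labels = np.repeat([0, 1, 2], [17, 17, 16])
        data = patterns[labels]
        noise = rng.random(data.shape) < 0.05
        data = np.abs(data - noise.astype(int))
        mat = pd.DataFrame(data, index=[f"g{i}" for i in range(50)])
        prof = PhyloProfile(mat)
        _, Z = cluster_genes(prof)
        from scipy.cluster.hierarchy import fcluster
        from sklearn.metrics import adjusted_rand_score

        found = fcluster(Z, t=3, criterion="maxclust")
        assert adjusted_rand_score(labels, found) >= 0.8

    def test_merge_structure_invariant_to_row_permutation(self):
        from netage.profiles import _upgma

        rng = np.random.default_rng(3)
        data = rng.random((10, 5))
        Z = _upgma(data)
        perm = rng.permutation(10)
        Zp = _upgma(data[perm])
        np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(Zp[:, 2]), rtol=1e-9)

    def test_deterministic_on_repeated_calls(self, fixture_tree):
        prof, _ = simulate_profile_set(fixture_tree, 20, {1: 0.3, 2: 0.4, 5: 0.3}, 0.2, seed=9)
        order1, Z1 = cluster_genes(prof)
        order2, Z2 = cluster_genes(prof)
        assert order1 == order2
        np.testing.assert_array_equal(Z1, Z2)


class TestLossDetection:
    def test_definition_instance(self, fixture_tree):
        present = set(fixture_tree.leaves) - {"Sce"}
        mat = pd.DataFrame({s: [int(s in present)] for s in fixture_tree.leaves}, index=["G"])
        records = detect_model_organism_losses(PhyloProfile(mat), fixture_tree, ["Sce"])
        assert len(records) == 1
        assert records[0].species == "Sce"
        assert records[0].oldest_present_rank == 1

    def test_absence_is_not_loss_without_older_presence(self, fixture_tree):
        mat = pd.DataFrame({s: [int(s == "Hsa")] for s in fixture_tree.leaves}, index=["G"])
        records = detect_model_organism_losses(PhyloProfile(mat), fixture_tree, ["Sce"])
        assert records == []

    def test_planted_losses_recovered_exactly(self, fixture_tree):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(25)]
        mat = pd.DataFrame(1, index=genes, columns=fixture_tree.leaves)
        planted = set(rng.choice(25, size=10, replace=False))
        for i in planted:
            mat.loc[genes[i], "Dme"] = 0
        records = detect_model_organism_losses(PhyloProfile(mat), fixture_tree, ["Dme"])
        assert {r.gene for r in records} == {genes[i] for i in planted}
        # every record refers to a zero cell with older presence
        for r in records:
            assert mat.loc[r.gene, r.species] == 0
            assert r.oldest_present_rank < fixture_tree.group_rank(r.species)

    def test_draft_genome_noted(self, fixture_tree):
        present = set(fixture_tree.leaves) - {"Tbr"}
        mat = pd.DataFrame({s: [int(s in present)] for s in fixture_tree.leaves}, index=["G"])
        records = detect_model_organism_losses(PhyloProfile(mat), fixture_tree, ["Tbr"])
        assert records[0].note == "draft genome"
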