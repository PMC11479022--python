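import numpy as np
import pandas as pd
import pytest

import germeval as g
from germeval.errors import GermevalError


def _scores(points, ids=None):
    arr = np.asarray(points, dtype=float)
    ids = ids or [f"A{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=ids,
                        columns=[f"PC{j+1}" for j in range(arr.shape[1])])


def upgma_oracle(points):
    """Quadratic-scan average linkage: cluster distance = mean of all
    pairwise point distances; returns sorted merge heights."""
    pts = np.asarray(points, dtype=float)
    clusters = [[i] for i in range(len(pts))]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([np.linalg.norm(pts[a] - pts[b])
                             for a in clusters[i] for b in clusters[j]])
                if d < best[0]:
                    best = (d, (i, j))
        d, (i, j) = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


class TestLinkage:
    def test_two_points_merge_at_their_distance(self):
        d = g.linkage_average(_scores([[0.0, 0.0], [3.0, 4.0]]))
        assert d.heights[0] == pytest.approx(5.0)

    def test_three_point_hand_example(self):
        # mutual distances (1, 5, 5.5): first merge at 1, then at 5.25
        y = np.sqrt(25 - 4.515625)
        pts = [[0.0, 0.0], [1.0, 0.0], [-2.125, y]]
        d = g.linkage_average(_scores(pts))
        assert d.heights[0] == pytest.approx(1.0)
        assert d.heights[1] == pytest.approx(5.25)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        pts = rng.normal(size=(n, 3))
        d = g.linkage_average(_scores(pts))
        assert np.allclose(np.sort(d.heights), np.sort(upgma_oracle(pts)),
                           atol=1e-10)

    def test_single_accession_errors(self):
        with pytest.raises(GermevalError):
            g.linkage_average(_scores([[1.0, 2.0]]))

    def test_heights_non_decreasing(self, survey_matrix):
        model = g.fit_pca(survey_matrix)
        scores = g.component_scores(model, survey_matrix)
        d = g.linkage_average(scores, [0, 1, 2])
        assert np.all(np.diff(d.heights) >= -1e-12)


class TestCut:
    @pytest.fixture
    def toy(self):
        pts = [[0, 0], [0.1, 0], [0.2, 0.1],  # tight clump
               [5, 5], [5.1, 5.0], [5.0, 5.2]]  # second clump
        return g.linkage_average(_scores(pts, [f"S{i}" for i in range(6)]))

    def test_k_equals_n_gives_singletons(self, toy):
        part = g.cut_k(toy, 6)
        assert sorted(part.values()) == [1, 2, 3, 4, 5, 6]

    def test_k_one_single_group(self, toy):
        assert set(g.cut_k(toy, 1).values()) == {1}

    def test_two_planted_clumps_recovered(self, toy):
        part = g.cut_k(toy, 2)
        assert len({part["S0"], part["S1"], part["S2"]}) == 1
        assert len({part["S3"], part["S4"], part["S5"]}) == 1
        assert part["S0"] != part["S3"]

    def test_k_out_of_range(self, toy):
        with pytest.raises(GermevalError):
            g.cut_k(toy, 7)

    def test_input_order_invariance(self, survey_matrix):
        model = g.fit_pca(survey_matrix)
        scores = g.component_scores(model, survey_matrix)
        part = g.cut_k(g.linkage_average(scores, [0, 1, 2]), 6)
        shuffled = scores.sample(frac=1.0, random_state=9)
        part2 = g.cut_k(g.linkage_average(shuffled, [0, 1, 2]), 6)
        assert part == part2

    def test_partition_label_diversity(self, survey_matrix):
        model = g.fit_pca(survey_matrix)
        scores = g.component_scores(model, survey_matrix)
        part = g.cut_k(g.linkage_average(scores, [0, 1, 2]), 6)
        sizes = g.group_sizes(part)
        assert g.partition_diversity(part) == pytest.approx(
            g.shannon_index(list(sizes.values())))


class TestGroupProfile:
    def test_percentages_and_dominance(self, scheme, tiny_table):
        # group of 10 with 9 Ovoid capsules: 90%, flagged at the 80% rule
        rows = pd.concat([tiny_table.data.iloc[[0]]] * 10)
        rows.index = [f"G{i}" for i in range(10)]
        rows["Capsule form"] = ["Ovoid"] * 9 + ["Globose"]
        table = g.validate_table(rows, scheme)
        part = {i: 1 for i in table.ids}
        prof = g.group_profile(part, table, scheme)
        ovoid = prof[(prof["trait"] == "Capsule form")
                     & (prof["class"] == "Ovoid")]
        assert ovoid["percent"].iloc[0] == pytest.approx(90.0)
        assert bool(ovoid["dominant"].iloc[0])

    def test_uniform_class_is_100_percent(self, scheme, tiny_table):
        rows = pd.concat([tiny_table.data.iloc[[1]]] * 4)
        rows.index = [f"U{i}" for i in range(4)]
        table = g.validate_table(rows, scheme)
        prof = g.group_profile({i: 1 for i in table.ids}, table, scheme)
        cell = prof[(prof["trait"] == "Capsule form")
                    & (prof["class"] == "Globose")]
        assert cell["percent"].iloc[0] == pytest.approx(100.0)
        assert bool(cell["dominant"].iloc[0])

    def test_percentages_sum_to_100_per_group_trait(self, survey_table,
                                                    survey_matrix, scheme):
        model = g.fit_pca(survey_matrix)
        scores = g.component_scores(model, survey_matrix)
        part = g.cut_k(g.linkage_average(scores, [0, 1, 2]), 6)
        prof = g.group_profile(part, survey_table, scheme)
        sums = prof.groupby(["group", "trait"])["percent"].sum()
        assert np.allclose(sums, 100.0, atol=0.01)

    def test_planted_dominant_class_is_flagged(self, scheme):
        # strongly diverged latent groups: each group's modal class of some
        # trait should cross the 80% dominance threshold
        cfg = g.SyntheticConfig(n_accessions=120, seed=8, n_latent_groups=2,
                                group_concentration=0.5)
        table, truth = g.sample_with_truth(cfg)
        part = {aid: int(lab) + 1 for aid, lab in zip(table.ids, truth)}
        prof = g.group_profile(part, table, scheme)
        flagged = prof[prof["dominant"]]
        assert set(flagged["group"]) == {1, 2}


class TestNewick:
    def test_round_trip_leaf_names_and_heights(self):
        pts = [[0.0, 0.0], [3.0, 4.0], [10.0, 0.0]]
        d = g.linkage_average(_scores(pts, ["x", "y", "z"]))
        nwk = g.to_newick(d)
        assert nwk.endswith(";")
        for leaf in ("x", "y", "z"):
            assert leaf in nwk
        # parses as a tree with matching tip count
        import io

        from Bio import Phylo
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert tree.count_terminals() == 3
        # root-to-tip depth equals the final merge height
        depths = tree.depths()
        tips = [d_ for c, d_ in depths.items() if c.is_terminal()]
        assert max(tips) == pytest.approx(d.heights[-1], rel=1e-6)
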