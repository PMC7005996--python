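"""Count-table ingestion, empirical landscapes, trajectories, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coexland as cx
from coexland.data_pipeline import ANNOTATION_COLUMNS


def make_table(rows, genes=("sox2", "t"), stage_order=cx.DEFAULT_STAGE_ORDER):
    df = pd.DataFrame(rows, columns=[*genes, *ANNOTATION_COLUMNS])
    for g in genes:
        df[g] = df[g].astype(int)
    return cx.CellCountTable(df=df, stage_order=stage_order)


@pytest.fixture
def toy_table():
    return make_table([
        (0, 0, 8, "blastula", "root"),
        (2, 3, 8, "blastula", "root"),
        (5, 1, 10, "neural", "blastula"),
        (1, 6, 10, "mesoderm", "blastula"),
        (4, 4, 12, "neural", "neural"),
        (0, 9, 12, "mesoderm", "mesoderm"),
    ])


class TestReadWrite:
    def test_round_trip(self, toy_table, tmp_path):
        path = tmp_path / "counts.tsv"
        cx.write_annotated_counts(toy_table, path)
        back = cx.read_annotated_counts(path)
        pd.testing.assert_frame_equal(back.df, toy_table.df)

    def test_negative_count_row_skipped(self, tmp_path, caplog):
        path = tmp_path / "counts.tsv"
        path.write_text("sox2\tt\tstage\tcell_type\tparent_cell_type\n"
                        "1\t2\t8\ta\troot\n"
                        "-1\t2\t8\ta\troot\n"
                        "3\tx\t8\ta\troot\n")
        import logging
        with caplog.at_level(logging.WARNING, logger="coexland.data_pipeline"):
            table = cx.read_annotated_counts(path)
        assert table.n_cells == 1
        assert "skipped 2" in caplog.text

    def test_missing_annotation_column_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("sox2\tt\tstage\tcell_type\n1\t2\t8\ta\n")
        with pytest.raises(ValueError, match="parent_cell_type"):
            cx.read_annotated_counts(path)

    def test_unknown_stage_named_in_error(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("sox2\tt\tstage\tcell_type\tparent_cell_type\n"
                        "1\t2\t99\ta\troot\n")
        with pytest.raises(ValueError, match="99"):
            cx.read_annotated_counts(path)


class TestLineageSelection:
    def test_all_types_is_identity(self, toy_table):
        spec = cx.LineageSpec("sox2", "t", {
            s: {"blastula", "neural", "mesoderm"} for s in (8, 10, 12)})
        out = cx.select_lineage_cells(toy_table, spec)
        assert out.n_cells == toy_table.n_cells

    def test_lineage_filter_keeps_only_in_lineage_cells(self, toy_table):
        spec = cx.LineageSpec("sox2", "t", {8: {"blastula"}, 10: {"neural"},
                                            12: {"neural"}}, branch_point=10)
        out = cx.select_lineage_cells(toy_table, spec)
        assert out.n_cells == 4  # 2 blastula parents + neural daughters
        assert set(out.df["cell_type"]) == {"blastula", "neural"}

    def test_disjoint_types_rejected(self, toy_table):
        spec = cx.LineageSpec("sox2", "t", {8: {"notochord"}})
        with pytest.raises(ValueError, match="no cells"):
            cx.select_lineage_cells(toy_table, spec)

    def test_missing_gene_rejected(self, toy_table):
        spec = cx.LineageSpec("sox2", "gata5", {8: {"blastula"}})
        with pytest.raises(ValueError, match="gata5"):
            cx.select_lineage_cells(toy_table, spec)


class TestEmpiricalLandscape:
    def test_frequency_grid(self):
        table = make_table([(0, 0, 8, "a", "r"), (0, 0, 8, "a", "r"),
                            (2, 3, 8, "a", "r")])
        land, report = cx.empirical_landscape(table, ("sox2", "t"), M=21)
        assert land.grid[0, 0] == pytest.approx(2 / 3)
        assert land.grid[2, 3] == pytest.approx(1 / 3)
        assert land.grid.sum() == pytest.approx(1.0)
        assert land.provenance == "empirical"
        assert report["truncation_fraction"] == 0.0

    def test_truncation_reported(self):
        table = make_table([(21, 5, 8, "a", "r"), (1, 1, 8, "a", "r"),
                            (2, 2, 8, "a", "r"), (3, 3, 8, "a", "r")])
        land, report = cx.empirical_landscape(table, ("sox2", "t"), M=21)
        assert report["n_dropped"] == 1
        assert report["truncation_fraction"] == pytest.approx(1 / 4)
        assert land.grid.sum() == pytest.approx(1.0)

    def test_all_cells_truncated_rejected(self):
        table = make_table([(30, 30, 8, "a", "r")])
        with pytest.raises(ValueError, match="truncation"):
            cx.empirical_landscape(table, ("sox2", "t"), M=21)


class TestEmpiricalQuasipotential:
    def test_unobserved_cells_at_pseudo_floor(self):
        table = make_table([(1, 1, 8, "a", "r")])
        land, _ = cx.empirical_landscape(table, ("sox2", "t"), M=5)
        phi = cx.empirical_quasipotential(land)
        assert phi.grid[0, 0] == pytest.approx(-np.log(1e-6))
        assert phi.grid[0, 0] == pytest.approx(13.8155, abs=1e-4)
        assert phi.grid[1, 1] == pytest.approx(0.0)

    def test_matches_model_quasipotential_transform(self):
        table = make_table([(1, 1, 8, "a", "r"), (2, 0, 8, "a", "r")])
        land, _ = cx.empirical_landscape(table, ("sox2", "t"), M=5)
        assert np.array_equal(cx.empirical_quasipotential(land).grid,
                              cx.quasipotential(land, floor=1e-6).grid)

    def test_low_frequency_above_pseudo(self):
        grid = np.zeros((5, 5))
        grid[1, 1] = 1e-5
        grid[0, 0] = 1 - 1e-5
        phi = cx.empirical_quasipotential(
            cx.CoexpressionLandscape(grid=grid, provenance="empirical"))
        assert phi.grid[1, 1] == pytest.approx(11.5129, abs=1e-3)

    def test_nonpositive_pseudo_rejected(self):
        grid = np.zeros((3, 3))
        grid[0, 0] = 1.0
        with pytest.raises(ValueError):
            cx.empirical_quasipotential(
                cx.CoexpressionLandscape(grid=grid), pseudo=0.0)


class TestTrajectoryDistance:
    def traj(self, coords, stages=None):
        coords = np.atleast_2d(coords)
        return cx.TrajectoryMatrix(
            coords=coords, stages=tuple(range(coords.shape[0])))

    def test_identity(self):
        A = self.traj([[1.0, 2.0], [3.0, 4.0]])
        assert cx.trajectory_distance(A, A) == 0.0

    def test_single_entry(self):
        A = self.traj([[0.0, 0.0]])
        B = self.traj([[3.0, 0.0]])
        assert cx.trajectory_distance(A, B) == 3.0

    def test_three_four_five(self):
        A = self.traj([[0.0, 0.0], [0.0, 0.0]])
        B = self.traj([[3.0, 0.0], [0.0, 4.0]])
        assert cx.trajectory_distance(A, B) == 5.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            cx.trajectory_distance(self.traj([[1.0, 2.0]]),
                                   self.traj([[1.0, 2.0], [0.0, 0.0]]))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_is_a_metric(self, seed):
        rng = np.random.default_rng(seed)
        A, B, C = (self.traj(rng.normal(size=(4, 3))) for _ in range(3))
        dAB = cx.trajectory_distance(A, B)
        dBA = cx.trajectory_distance(B, A)
        assert dAB == dBA >= 0
        assert cx.trajectory_distance(A, C) <= dAB + \
            cx.trajectory_distance(B, C) + 1e-12


@pytest.fixture(scope="module")
def landscape():
    p = cx.KineticParameters(g_hi_x=1.4, g_hi_y=1.4, h_a=100., f_a=1000.,
                             h_r=100., f_r=100., regime="fast")
    return cx.compute_landscape(cx.make_misa_model(p, 21))


class TestSimulateCells:
    def test_fixed_seed_identical(self, landscape):
        t1 = cx.simulate_cells({8: landscape}, 500, seed=9)
        t2 = cx.simulate_cells({8: landscape}, 500, seed=9)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_zero_cells_empty_table(self, landscape):
        table = cx.simulate_cells({8: landscape}, 0, seed=0)
        assert table.n_cells == 0

    def test_quasipotential_input_rejected(self, landscape):
        with pytest.raises(ValueError, match="probability"):
            cx.simulate_cells({8: cx.quasipotential(landscape)}, 10, seed=0)

    def test_large_sample_recovers_landscape(self, landscape):
        table = cx.simulate_cells({8: landscape}, 100_000, seed=17)
        est, _ = cx.empirical_landscape(table, ("gene_x", "gene_y"), M=21)
        tv = 0.5 * np.abs(est.grid - landscape.grid).sum()
        assert tv < 0.02


@pytest.fixture(scope="module")
def space(mini_misa_library):
    return cx.fit_shape_space(mini_misa_library, n_components=3)


class TestTrajectoriesEndToEnd:
    def test_single_stage_gives_one_row(self, space):
        land = cx.archetype_landscape("hi/hi")
        table = cx.simulate_cells({10: land}, 2000, seed=1)
        spec = cx.LineageSpec("gene_x", "gene_y", {10: {"synthetic"}})
        traj = cx.build_trajectory(table, spec, space)
        assert traj.shape == (1, 3)
        assert traj.stages == (10,)

    def test_fixed_landscape_trajectory_tightens_with_sampling(self, space):
        """Stage scatter around the true projection shrinks as cells grow."""
        land = cx.archetype_landscape("antagonistic")
        truth = cx.project(cx.quasipotential(land), space).scores
        spreads = []
        for n in (200, 20_000):
            table = cx.simulate_cells(
                {s: land for s in (8, 10, 11, 12)}, n, seed=5)
            spec = cx.LineageSpec("gene_x", "gene_y",
                                  {s: {"synthetic"} for s in (8, 10, 11, 12)})
            traj = cx.build_trajectory(table, spec, space)
            spreads.append(
                np.linalg.norm(traj.coords - truth, axis=1).max())
        assert spreads[1] < spreads[0]

    def test_morphing_landscapes_move_along_expression_component(self, space):
        """lo/lo -> hi/hi morph climbs the overall-expression component."""
        lo = cx.archetype_landscape("lo/lo").grid
        hi = cx.archetype_landscape("hi/hi").grid
        stages = (8, 10, 12, 14)
        lands = {}
        for frac, s in zip(np.linspace(0, 1, len(stages)), stages):
            lands[s] = cx.CoexpressionLandscape(
                grid=(1 - frac) * lo + frac * hi)
        table = cx.simulate_cells(lands, 30_000, seed=23)
        spec = cx.LineageSpec("gene_x", "gene_y",
                              {s: {"synthetic"} for s in stages})
        traj = cx.build_trajectory(table, spec, space)
        c1 = traj.coords[:, 0]
        assert np.all(np.diff(c1) > 0)

    def test_stage_without_cells_dropped(self, space):
        land = cx.archetype_landscape("hi/hi")
        table = cx.simulate_cells({8: land, 12: land}, 1000, seed=2)
        spec = cx.LineageSpec("gene_x", "gene_y",
                              {8: {"synthetic"}, 12: {"synthetic"}})
        traj = cx.build_trajectory(table, spec, space)
        assert traj.stages == (8, 12)


class TestClustering:
    def make_group(self, center, n, jitter, rng):
        return [cx.TrajectoryMatrix(coords=center + rng.normal(0, jitter,
                                                               center.shape),
                                    stages=tuple(range(center.shape[0])))
                for _ in range(n)]

    def test_two_separated_groups_recovered(self):
        rng = np.random.default_rng(31)
        c1 = np.zeros((5, 3))
        c2 = np.full((5, 3), 50.0)
        trajs = self.make_group(c1, 6, 0.1, rng) + \
            self.make_group(c2, 7, 0.1, rng)
        labels, Z = cx.cluster_trajectories(trajs, n_clusters=2)
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicates_co_cluster_at_zero_distance(self):
        rng = np.random.default_rng(32)
        base = cx.TrajectoryMatrix(coords=rng.normal(size=(4, 2)),
                                   stages=(0, 1, 2, 3))
        trajs = [base, base,
                 cx.TrajectoryMatrix(coords=base.coords + 10.0,
                                     stages=(0, 1, 2, 3))]
        labels, Z = cx.cluster_trajectories(trajs, n_clusters=2)
        assert labels[0] == labels[1] != labels[2]
        assert Z[0, 2] == 0.0  # first merge happens at distance zero

    def test_threshold_cut(self):
        rng = np.random.default_rng(33)
        trajs = self.make_group(np.zeros((3, 2)), 4, 0.01, rng) + \
            self.make_group(np.full((3, 2), 30.0), 4, 0.01, rng)
        labels, _ = cx.cluster_trajectories(trajs, threshold=5.0)
        assert len(set(labels)) == 2

    def test_inconsistent_shapes_rejected(self):
        a = cx.TrajectoryMatrix(coords=np.zeros((3, 2)), stages=(0, 1, 2))
        b = cx.TrajectoryMatrix(coords=np.zeros((4, 2)), stages=(0, 1, 2, 3))
        with pytest.raises(ValueError, match="share"):
            cx.cluster_trajectories([a, b], n_clusters=2)

    def test_requires_cluster_spec(self):
        a = cx.TrajectoryMatrix(coords=np.zeros((3, 2)), stages=(0, 1, 2))
        with pytest.raises(ValueError, match="exactly one"):
            cx.cluster_trajectories([a, a], n_clusters=2, threshold=1.0)


class TestMlpSignatureEndToEnd:
    def test_morph_traces_coexpression_loop(self, mini_misa_library):
        """lo/lo -> coexpressing -> antagonistic: the coexpression component
        rises then falls while antagonism dominates at the end."""
        space = cx.fit_shape_space(mini_misa_library, n_components=3)
        lo = cx.archetype_landscape("lo/lo").grid
        hi = cx.archetype_landscape("hi/hi").grid
        anti = cx.archetype_landscape("antagonistic").grid
        stages = (8, 10, 12)
        lands = {8: cx.CoexpressionLandscape(grid=lo),
                 10: cx.CoexpressionLandscape(grid=hi),
                 12: cx.CoexpressionLandscape(grid=anti)}
        table = cx.simulate_cells(lands, 50_000, seed=41, stage_order=stages)
        spec = cx.LineageSpec("gene_x", "gene_y",
                              {s: {"synthetic"} for s in stages})
        traj = cx.build_trajectory(table, spec, space)
        c2 = traj.coords[:, 1]
        assert c2[1] > c2[0]       # coexpression rises
        assert c2[2] < c2[1]       # then falls as antagonism takes over
        assert c2[2] < 0           # ending on the antagonistic side
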