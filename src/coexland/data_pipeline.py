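"""Single-cell count tables, empirical landscapes, and trajectories.

Ingests annotated per-cell count tables (genes + developmental stage +
cell type + parent cell type, tab-delimited), selects cells of one
lineage, bins gene-pair counts into empirical M x M landscapes per
stage, projects those into a fitted shape-space to form stage-ordered
landscape-shape trajectories, and clusters trajectories by their
Frobenius distance. A synthetic-cell generator samples count pairs
from model landscapes to emulate such tables stage by stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .shape_space import ShapeSpace, project_features
from .steady_state import CoexpressionLandscape, quasipotential

__all__ = [
    "ANNOTATION_COLUMNS",
    "DEFAULT_STAGE_ORDER",
    "CellCountTable",
    "LineageSpec",
    "TrajectoryMatrix",
    "read_annotated_counts",
    "write_annotated_counts",
    "select_lineage_cells",
    "empirical_landscape",
    "empirical_quasipotential",
    "build_trajectory",
    "trajectory_distance",
    "cluster_trajectories",
    "simulate_cells",
]

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("stage", "cell_type", "parent_cell_type")

#: Developmental stages of the Xenopus tropicalis reference atlas.
DEFAULT_STAGE_ORDER = (8, 10, 11, 12, 13, 14, 16, 18, 20, 22)


@dataclass(frozen=True)
class CellCountTable:
    """Per-cell integer gene counts plus stage/lineage annotations."""

    df: pd.DataFrame
    stage_order: tuple = DEFAULT_STAGE_ORDER

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing annotation columns: {missing}")
        unknown = set(self.df["stage"]) - set(self.stage_order)
        if unknown:
            raise ValueError(
                f"unknown stage label(s) {sorted(unknown)}; expected one of "
                f"{list(self.stage_order)}")
        for g in self.genes:
            col = self.df[g]
            if not np.issubdtype(col.dtype, np.integer) or (col < 0).any():
                raise ValueError(f"gene column {g!r} must hold counts >= 0")

    @property
    def genes(self) -> list[str]:
        return [c for c in self.df.columns if c not in ANNOTATION_COLUMNS]

    @property
    def n_cells(self) -> int:
        return len(self.df)


def read_annotated_counts(path, stage_order=DEFAULT_STAGE_ORDER) -> CellCountTable:
    """Read a tab-delimited annotated count table.

    Rows with unparseable or negative counts, or missing annotations,
    are skipped with a logged count; an annotation column missing from
    the header, or an undeclared stage label, is an error.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns: {missing}")
    genes = [c for c in df.columns if c not in ANNOTATION_COLUMNS]
    n_raw = len(df)
    bad = df[ANNOTATION_COLUMNS[0]].isna()
    for c in ANNOTATION_COLUMNS:
        bad |= df[c].isna()
    for g in genes:
        counts = pd.to_numeric(df[g], errors="coerce")
        bad |= counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        logger.warning("%s: skipped %d of %d unparseable row(s)",
                       path, int(bad.sum()), n_raw)
    df = df[~bad].copy()
    for g in genes:
        df[g] = pd.to_numeric(df[g]).astype(int)
    try:
        df["stage"] = pd.to_numeric(df["stage"])
    except (ValueError, TypeError):
        pass  # non-numeric stage labels are allowed if declared in stage_order
    return CellCountTable(df=df.reset_index(drop=True), stage_order=stage_order)


def write_annotated_counts(table: CellCountTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LineageSpec:
    """Gene pair and the per-stage cell-type sets forming one lineage.

    ``cell_types_by_stage`` maps each stage to the cell types included
    in the lineage at that stage (parents before the branch point,
    daughters after); stages absent from the mapping select no cells.
    """

    gene_x: str
    gene_y: str
    cell_types_by_stage: dict = field(default_factory=dict)
    branch_point: object = None

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene_x, self.gene_y)


def select_lineage_cells(table: CellCountTable, spec: LineageSpec) -> CellCountTable:
    """Filter the table to in-lineage cells, stage by stage."""
    for g in spec.gene_pair:
        if g not in table.genes:
            raise ValueError(f"gene {g!r} not present in the table")
    keep = np.zeros(table.n_cells, dtype=bool)
    for stage, types in spec.cell_types_by_stage.items():
        keep |= ((table.df["stage"] == stage)
                 & table.df["cell_type"].isin(set(types))).to_numpy()
    if not keep.any():
        raise ValueError("lineage selection retained no cells at any stage")
    out = table.df[keep].reset_index(drop=True)
    per_stage = out.groupby("stage").size().to_dict()
    logger.info("lineage %s-%s: retained %d cells (%s)",
                spec.gene_x, spec.gene_y, len(out), per_stage)
    return CellCountTable(df=out, stage_order=table.stage_order)


def empirical_landscape(cells: CellCountTable, gene_pair: tuple[str, str],
                        M: int = 21):
    """Bin gene-pair counts into an M x M frequency landscape.

    Cells with either count above M - 1 are dropped (the truncation
    fraction is reported); the remaining counts form a normalized
    M x M grid, the sampled estimator of the stationary distribution.

    Returns ``(landscape, report)`` where report holds ``n_cells``,
    ``n_dropped`` and ``truncation_fraction``.
    """
    gx, gy = gene_pair
    for g in (gx, gy):
        if g not in cells.genes:
            raise ValueError(f"gene {g!r} not present in the table")
    nx = cells.df[gx].to_numpy()
    ny = cells.df[gy].to_numpy()
    keep = (nx <= M - 1) & (ny <= M - 1)
    n_total = len(nx)
    n_dropped = int(n_total - keep.sum())
    if n_total == 0 or keep.sum() == 0:
        raise ValueError("no cells survive truncation at M - 1")
    grid = np.zeros((M, M))
    np.add.at(grid, (nx[keep], ny[keep]), 1.0)
    grid /= grid.sum()
    land = CoexpressionLandscape(grid=grid, representation="probability",
                                 provenance="empirical")
    report = {"n_cells": n_total, "n_dropped": n_dropped,
              "truncation_fraction": n_dropped / n_total}
    return land, report


def empirical_quasipotential(pi: CoexpressionLandscape,
                             pseudo: float = 1e-6) -> CoexpressionLandscape:
    """Sampled quasipotential with unobserved cells floored at ``pseudo``.

    1e-6 is below the least estimable frequency at ~1e5 cells, and in
    line with model predictions for the low-probability edges.
    """
    return quasipotential(pi, floor=pseudo)


@dataclass(frozen=True)
class TrajectoryMatrix:
    """Stage-ordered shape coordinates of one gene pair (m stages x n)."""

    coords: np.ndarray
    stages: tuple
    gene_pair: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, float))
        object.__setattr__(self, "coords", coords)
        if coords.shape[0] != len(self.stages):
            raise ValueError("one coordinate row per stage required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.coords.shape


def build_trajectory(table: CellCountTable, spec: LineageSpec,
                     space: ShapeSpace,
                     stage_order=None, pseudo: float = 1e-6) -> TrajectoryMatrix:
    """Per-stage empirical landscapes projected into the shape-space.

    Stages with no retained (or fully truncated) cells are dropped from
    the trajectory with a log message rather than imputed.
    """
    stage_order = table.stage_order if stage_order is None else stage_order
    selected = select_lineage_cells(table, spec)
    rows, stages = [], []
    for stage in stage_order:
        sub = selected.df[selected.df["stage"] == stage]
        if len(sub) == 0:
            logger.info("stage %s: no retained cells; dropped", stage)
            continue
        cells = CellCountTable(df=sub.reset_index(drop=True),
                               stage_order=selected.stage_order)
        try:
            land, _ = empirical_landscape(cells, spec.gene_pair, M=space.M)
        except ValueError:
            logger.info("stage %s: all cells truncated; dropped", stage)
            continue
        if space.representation == "quasipotential":
            land = empirical_quasipotential(land, pseudo=pseudo)
        rows.append(project_features(land.features(), space)[0])
        stages.append(stage)
    if not rows:
        raise ValueError("no stage produced a landscape")
    return TrajectoryMatrix(coords=np.asarray(rows), stages=tuple(stages),
                            gene_pair=spec.gene_pair)


def trajectory_distance(A: TrajectoryMatrix, B: TrajectoryMatrix) -> float:
    """Frobenius distance between two same-shape trajectory matrices."""
    if A.shape != B.shape:
        raise ValueError(f"trajectory shapes differ: {A.shape} vs {B.shape}")
    return float(np.sqrt(((A.coords - B.coords) ** 2).sum()))


def cluster_trajectories(trajectories: list[TrajectoryMatrix],
                         n_clusters: int | None = None,
                         threshold: float | None = None,
                         method: str = "average"):
    """Agglomerative clustering on pairwise Frobenius distances.

    Cut the dendrogram either at a fixed cluster count or at a distance
    threshold. Returns ``(labels, linkage_matrix)`` with 1-based labels
    as produced by the flat-cut routine.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    shape = trajectories[0].shape
    if any(t.shape != shape for t in trajectories):
        raise ValueError("all trajectories must share (stages x components) shape")
    if (n_clusters is None) == (threshold is None):
        raise ValueError("specify exactly one of n_clusters or threshold")
    n = len(trajectories)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = trajectory_distance(trajectories[i],
                                                    trajectories[j])
    Z = sch.linkage(squareform(D, checks=False), method=method)
    if n_clusters is not None:
        labels = sch.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        labels = sch.fcluster(Z, t=threshold, criterion="distance")
    return labels, Z


def simulate_cells(landscapes_per_stage: dict, n_cells_per_stage: int,
                   seed: int, gene_pair: tuple[str, str] = ("gene_x", "gene_y"),
                   stage_order=None) -> CellCountTable:
    """Sample synthetic cells from probability landscapes, one per stage.

    Draws ``n_cells_per_stage`` i.i.d. (n_x, n_y) pairs from each
    stage's landscape and annotates them with the stage and a dummy
    lineage, emulating an annotated count table. Reproducible per seed.
    """
    if n_cells_per_stage < 0:
        raise ValueError("n_cells_per_stage must be >= 0")
    for stage, land in landscapes_per_stage.items():
        if land.representation != "probability":
            raise ValueError(
                f"stage {stage}: simulate_cells needs probability landscapes")
    if stage_order is None:
        stage_order = tuple(landscapes_per_stage)
    rng = np.random.default_rng(seed)
    gx, gy = gene_pair
    frames = []
    for stage in stage_order:
        land = landscapes_per_stage[stage]
        M = land.M
        idx = rng.choice(M * M, size=n_cells_per_stage, p=land.grid.ravel())
        frames.append(pd.DataFrame({
            gx: idx // M, gy: idx % M,
            "stage": stage, "cell_type": "synthetic",
            "parent_cell_type": "synthetic",
        }))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=[gx, gy, *ANNOTATION_COLUMNS])
    df[gx] = df[gx].astype(int)
    df[gy] = df[gy].astype(int)
    return CellCountTable(df=df, stage_order=tuple(stage_order))
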