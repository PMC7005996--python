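"""Parameter sweeps: model grids, landscape libraries, persistence.

A sweep crosses a set of regulatory-logic variants with log-spaced
binding/unbinding rates and synthesis levels, solves every model's
master equation, and collects the landscapes as rows of a library
matrix (R models x M^2 features) that serves as a PCA training set.
Libraries are exact-solver output, so their content is a pure function
of the sweep configuration — no seed involved.

The default grids are scaled-down versions of the full published
sweeps (which used unpublished grids of ~34k Flex and ~23k MISA
models): ~2,300 Flex models across the 14 interacting motifs and
~1,300 fast-regime MISA models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .network_model import (
    INTERACTING_MOTIF_IDS,
    MISA_MOTIF_ID,
    FAST_F_RANGE,
    FAST_H_RANGE,
    SLOW_RANGE,
    GeneNetworkModel,
    KineticParameters,
    make_flex_model,
)
from .steady_state import DEFAULT_FLOOR, SolverError, compute_landscape

__all__ = [
    "SweepConfig",
    "LandscapeLibrary",
    "default_misa_config",
    "default_flex_config",
    "generate_misa_grid",
    "generate_flex_grid",
    "compute_landscape_library",
]

DESCRIPTOR_COLUMNS = [
    "motif_id", "motif_class", "g_hi_x", "g_hi_y", "g_lo", "k",
    "h_a", "f_a", "h_r", "f_r",
]


@dataclass(frozen=True)
class SweepConfig:
    """Grid specification for a landscape sweep.

    ``g_hi_values`` are synthesis levels in [0.8, 1.4] mRNA/hr; with
    ``asymmetric_g`` all ordered (g_hi_x, g_hi_y) pairs are used,
    otherwise only symmetric pairs. Binding (h) and unbinding (f)
    values must lie within the catalogued range of the tagged regime
    (fast: h in [10, 500], f in [10, 1e5]; slow: both in [1e-6, 10]);
    ``regime=None`` allows the combined slow+fast span.
    """

    motifs: tuple[int, ...] = INTERACTING_MOTIF_IDS
    g_hi_values: tuple[float, ...] = (0.8, 1.4)
    asymmetric_g: bool = False
    h_a_values: tuple[float, ...] = ()
    f_a_values: tuple[float, ...] = ()
    h_r_values: tuple[float, ...] = ()
    f_r_values: tuple[float, ...] = ()
    regime: str | None = None
    g_lo: float = 0.001
    k: float = 0.2
    M: int = 21
    representation: str = "probability"
    floor: float = DEFAULT_FLOOR
    workers: int = 1

    def __post_init__(self) -> None:
        if self.representation not in ("probability", "quasipotential"):
            raise ValueError(f"bad representation {self.representation!r}")
        for name in ("h_a_values", "f_a_values", "h_r_values", "f_r_values",
                     "g_hi_values"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be nonempty")
        lo_h, hi_h = (SLOW_RANGE[0],
                      FAST_H_RANGE[1]) if self.regime is None else (
            FAST_H_RANGE if self.regime == "fast" else SLOW_RANGE)
        lo_f, hi_f = (SLOW_RANGE[0],
                      FAST_F_RANGE[1]) if self.regime is None else (
            FAST_F_RANGE if self.regime == "fast" else SLOW_RANGE)
        for name, (lo, hi) in (("h_a_values", (lo_h, hi_h)),
                               ("h_r_values", (lo_h, hi_h)),
                               ("f_a_values", (lo_f, hi_f)),
                               ("f_r_values", (lo_f, hi_f))):
            for v in getattr(self, name):
                if not lo <= v <= hi:
                    raise ValueError(f"{name} value {v} outside [{lo}, {hi}]")
        for g in self.g_hi_values:
            if not 0.8 <= g <= 1.4:
                raise ValueError(f"g_hi value {g} outside [0.8, 1.4]")

    def grid_size(self) -> int:
        """Number of models the grid will contain (reported pre-execution)."""
        n_g = len(self.g_hi_values) ** 2 if self.asymmetric_g else len(
            self.g_hi_values)
        return (len(self.motifs) * n_g * len(self.h_a_values)
                * len(self.f_a_values) * len(self.h_r_values)
                * len(self.f_r_values))


def _log_points(lo: float, hi: float, n: int) -> tuple[float, ...]:
    return tuple(np.logspace(np.log10(lo), np.log10(hi), n))


def default_misa_config(**overrides) -> SweepConfig:
    """Scaled-down fast-regime MISA sweep (~1,300 models, asymmetric g)."""
    cfg = dict(
        motifs=(MISA_MOTIF_ID,),
        g_hi_values=(0.8, 1.1, 1.4),
        asymmetric_g=True,
        h_a_values=_log_points(*FAST_H_RANGE, 3),
        h_r_values=_log_points(*FAST_H_RANGE, 3),
        f_a_values=_log_points(*FAST_F_RANGE, 4),
        f_r_values=_log_points(*FAST_F_RANGE, 4),
        regime="fast",
        representation="quasipotential",
    )
    cfg.update(overrides)
    return SweepConfig(**cfg)


def default_flex_config(**overrides) -> SweepConfig:
    """Scaled-down Two-Gene Flex sweep (~2,300 models, slow+fast span)."""
    cfg = dict(
        motifs=INTERACTING_MOTIF_IDS,
        g_hi_values=(0.8, 1.4),
        asymmetric_g=False,
        h_a_values=_log_points(SLOW_RANGE[0], FAST_H_RANGE[1], 3),
        h_r_values=_log_points(SLOW_RANGE[0], FAST_H_RANGE[1], 3),
        f_a_values=_log_points(SLOW_RANGE[0], FAST_F_RANGE[1], 3),
        f_r_values=_log_points(SLOW_RANGE[0], FAST_F_RANGE[1], 3),
        regime=None,
        representation="probability",
    )
    cfg.update(overrides)
    return SweepConfig(**cfg)


def _grid_models(config: SweepConfig) -> list[GeneNetworkModel]:
    if config.asymmetric_g:
        g_pairs = list(itertools.product(config.g_hi_values, repeat=2))
    else:
        g_pairs = [(g, g) for g in config.g_hi_values]
    seen: dict[tuple, GeneNetworkModel] = {}
    for motif in config.motifs:
        for (gx, gy), ha, fa, hr, fr in itertools.product(
                g_pairs, config.h_a_values, config.f_a_values,
                config.h_r_values, config.f_r_values):
            key = (motif, gx, gy, ha, fa, hr, fr)
            if key in seen:
                continue
            params = KineticParameters(
                g_hi_x=gx, g_hi_y=gy, g_lo=config.g_lo, k=config.k,
                h_a=ha, f_a=fa, h_r=hr, f_r=fr, regime=config.regime)
            seen[key] = make_flex_model(motif, params, config.M)
    models = list(seen.values())
    if not models:
        raise ValueError("sweep grid is empty")
    return models


def generate_misa_grid(config: SweepConfig) -> list[GeneNetworkModel]:
    """Cartesian MISA grid over g_hi pairs and the four binding rates."""
    return _grid_models(replace(config, motifs=(MISA_MOTIF_ID,)))


def generate_flex_grid(config: SweepConfig) -> list[GeneNetworkModel]:
    """Per-motif grids over the interacting Flex logic variants."""
    for motif in config.motifs:
        if motif not in INTERACTING_MOTIF_IDS:
            raise ValueError(
                f"motif {motif} encodes no gene-gene interaction and is "
                "excluded from Flex sweeps")
    return _grid_models(config)


@dataclass(frozen=True)
class LandscapeLibrary:
    """R landscapes x M^2 features plus per-row model descriptors."""

    data: np.ndarray
    descriptors: pd.DataFrame
    representation: str
    M: int
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.descriptors), self.M * self.M):
            raise ValueError("library shape does not match descriptors/M")

    @property
    def n_models(self) -> int:
        return self.data.shape[0]

    def landscape(self, row: int):
        """Reconstruct one row as a CoexpressionLandscape."""
        from .steady_state import CoexpressionLandscape
        return CoexpressionLandscape(
            grid=self.data[row].reshape(self.M, self.M),
            representation=self.representation, provenance="model",
            floor=self.floor if self.representation == "quasipotential" else None,
            metadata=self.descriptors.iloc[row].to_dict())

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.attrs["representation"] = self.representation
            f.attrs["M"] = self.M
            f.attrs["floor"] = self.floor
            grp = f.create_group("descriptors")
            for col in self.descriptors.columns:
                vals = self.descriptors[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                grp.create_dataset(col, data=vals)

    @classmethod
    def load(cls, path) -> "LandscapeLibrary":
        with h5py.File(path, "r") as f:
            data = f["data"][:]
            cols = {}
            for col, ds in f["descriptors"].items():
                vals = ds[:]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
            desc = pd.DataFrame(cols)[
                [c for c in DESCRIPTOR_COLUMNS if c in cols]]
            return cls(data=data, descriptors=desc,
                       representation=str(f.attrs["representation"]),
                       M=int(f.attrs["M"]), floor=float(f.attrs["floor"]))

    def export_descriptors(self, path) -> None:
        self.descriptors.to_csv(path, sep="\t", index=False)


def _solve_one(model: GeneNetworkModel, representation: str, floor: float):
    try:
        return compute_landscape(model, representation, floor).features(), None
    except SolverError as exc:
        return None, str(exc)


def compute_landscape_library(models: list[GeneNetworkModel],
                              representation: str = "probability",
                              workers: int = 1,
                              floor: float = DEFAULT_FLOOR) -> LandscapeLibrary:
    """Solve every model and stack the landscapes into a library.

    Output row order follows the model list regardless of worker count.
    Models whose solve fails are excluded, with the failure reason kept
    in the returned library's ``failures`` metadata attribute.
    """
    if not models:
        raise ValueError("no models to compute")
    M = models[0].M
    if any(m.M != M for m in models):
        raise ValueError("all models in a library must share M")
    if workers > 1:
        results = Parallel(n_jobs=workers)(
            delayed(_solve_one)(m, representation, floor) for m in models)
    else:
        results = [_solve_one(m, representation, floor) for m in models]

    rows, desc_rows, failures = [], [], []
    for model, (feat, err) in zip(models, results):
        if feat is None:
            failures.append((model, err))
            continue
        rows.append(feat)
        p = model.params
        desc_rows.append({
            "motif_id": model.logic.motif_id,
            "motif_class": model.logic.motif_class,
            "g_hi_x": p.g_hi_x, "g_hi_y": p.g_hi_y, "g_lo": p.g_lo,
            "k": p.k, "h_a": p.h_a, "f_a": p.f_a, "h_r": p.h_r, "f_r": p.f_r,
        })
    if not rows:
        raise SolverError("every model in the sweep failed to solve")
    lib = LandscapeLibrary(
        data=np.asarray(rows), descriptors=pd.DataFrame(desc_rows),
        representation=representation, M=M, floor=floor)
    object.__setattr__(lib, "failures", failures)
    return lib
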