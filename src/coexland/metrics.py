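"""Scalar coexpression metrics of a probability landscape.

Four pairwise measures commonly applied to single-cell gene-pair data,
computed as plug-in population quantities from the bivariate count
distribution pi(n_x, n_y): Shannon entropy, Pearson correlation of the
counts, mutual information, and the coexpression index — the
conditional probability that both counts are nonzero given that at
least one is. Entropy and mutual information use natural logarithms
(nats), consistent with the quasipotential phi = -ln(pi).
"""

from __future__ import annotations

import numpy as np

from .steady_state import CoexpressionLandscape

__all__ = [
    "UndefinedMetricError",
    "shannon_entropy",
    "pearson_correlation",
    "mutual_information",
    "coexpression_index",
    "metric_report",
]

_NORM_TOL = 1e-6


class UndefinedMetricError(ValueError):
    """The metric is undefined for this distribution (e.g. zero variance)."""


def _checked_grid(pi: CoexpressionLandscape | np.ndarray) -> np.ndarray:
    grid = pi.grid if isinstance(pi, CoexpressionLandscape) else np.asarray(pi, float)
    if isinstance(pi, CoexpressionLandscape) and pi.representation != "probability":
        raise ValueError("metrics require a probability landscape")
    if grid.ndim != 2:
        raise ValueError("landscape grid must be 2-D")
    if np.any(grid < 0) or abs(grid.sum() - 1.0) > _NORM_TOL:
        raise ValueError("input is not a normalized probability grid")
    return grid


def shannon_entropy(pi: CoexpressionLandscape | np.ndarray) -> float:
    """H = -sum pi ln pi in nats, with 0 ln 0 = 0."""
    grid = _checked_grid(pi)
    nz = grid[grid > 0]
    return float(-(nz * np.log(nz)).sum())


def pearson_correlation(pi: CoexpressionLandscape | np.ndarray) -> float:
    """Population Pearson correlation of the count pair (n_x, n_y)."""
    grid = _checked_grid(pi)
    nx = np.arange(grid.shape[0], dtype=float)
    ny = np.arange(grid.shape[1], dtype=float)
    px, py = grid.sum(axis=1), grid.sum(axis=0)
    mx, my = px @ nx, py @ ny
    vx = px @ (nx - mx) ** 2
    vy = py @ (ny - my) ** 2
    if vx <= 0 or vy <= 0:
        raise UndefinedMetricError("correlation undefined: zero marginal variance")
    cov = np.einsum("ij,i,j->", grid, nx - mx, ny - my)
    return float(cov / np.sqrt(vx * vy))


def mutual_information(pi: CoexpressionLandscape | np.ndarray) -> float:
    """I(X;Y) = sum pi(x,y) ln[pi(x,y)/(px py)] in nats, zero cells skipped."""
    grid = _checked_grid(pi)
    px, py = grid.sum(axis=1), grid.sum(axis=0)
    prod = np.outer(px, py)
    mask = grid > 0
    return float((grid[mask] * np.log(grid[mask] / prod[mask])).sum())


def coexpression_index(pi: CoexpressionLandscape | np.ndarray) -> float:
    """P(n_x > 0 and n_y > 0 | n_x > 0 or n_y > 0).

    The ratio of probability mass with both counts positive to the mass
    with at least one positive; undefined if all mass sits at (0, 0).
    """
    grid = _checked_grid(pi)
    both = grid[1:, 1:].sum()
    either = grid.sum() - grid[0, 0]
    if either <= 0:
        raise UndefinedMetricError(
            "coexpression index undefined: all mass at (0, 0)"
        )
    return float(both / either)


def metric_report(pi: CoexpressionLandscape | np.ndarray) -> dict[str, float]:
    """All four metrics; undefined ones reported as NaN."""
    report = {"shannon_entropy": shannon_entropy(pi),
              "mutual_information": mutual_information(pi)}
    for name, fn in (("pearson_correlation", pearson_correlation),
                     ("coexpression_index", coexpression_index)):
        try:
            report[name] = fn(pi)
        except UndefinedMetricError:
            report[name] = float("nan")
    return report
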