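"""Posterior summaries: effect tables, smooth curves, spatial maps, diagnostics.

Turns :class:`~geoprobit.mcmc.PosteriorDraws` into the reported surfaces:

* linear-effect tables with posterior means, equal-tailed 95 % credible
  intervals and a significance flag (CrI excludes zero);
* nonlinear-effect curves with pointwise mean and credible bands;
* per-region spatial posterior means with a three-class significance map
  (+1 significantly positive, -1 significantly negative, 0 otherwise);
* effective sample size and split-chain R-hat diagnostics (via ArviZ).
"""

from __future__ import annotations

import warnings

import arviz as az
import numpy as np
import pandas as pd

from .design_priors import bspline_basis
from .mcmc import BlockDraws, PosteriorDraws

__all__ = [
    "summarize_linear",
    "summarize_curve",
    "summarize_spatial",
    "convergence_diagnostics",
    "plot_curve",
    "plot_spatial",
]


def _interval(draws: np.ndarray, level: float = 0.95):
    lo = np.quantile(draws, (1 - level) / 2, axis=0)
    hi = np.quantile(draws, 1 - (1 - level) / 2, axis=0)
    return lo, hi


def summarize_linear(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean and equal-tailed CrI for every linear coefficient.

    One row per coefficient of every parameter's linear block; the
    ``significant`` star corresponds to the CrI excluding zero.
    """
    rows = []
    for b in draws.linear_blocks():
        if b.beta.size == 0:
            raise ValueError("empty chain")
        lo, hi = _interval(b.beta, level)
        mean = b.beta.mean(axis=0)
        for i, name in enumerate(b.colnames):
            rows.append(
                {
                    "parameter": b.param,
                    "term": name,
                    "mean": mean[i],
                    "lower": lo[i],
                    "upper": hi[i],
                    "significant": bool(lo[i] > 0 or hi[i] < 0),
                }
            )
    return pd.DataFrame(rows)


def summarize_curve(
    draws_or_block: PosteriorDraws | BlockDraws,
    grid: np.ndarray,
    param: str | None = None,
    label: str | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Pointwise posterior mean and credible band of a smooth effect.

    The curve is evaluated as ``f(w) = B(w) beta`` per kept draw on the
    requested grid (which must lie inside the covariate range used for
    fitting — no extrapolation).  The fitted curve is centred by the
    sum-to-zero constraint imposed during sampling.
    """
    block = (
        draws_or_block
        if isinstance(draws_or_block, BlockDraws)
        else draws_or_block.get_block(param, label)
    )
    if block.kind != "spline":
        raise ValueError(f"block {block.label!r} is not a smooth term")
    grid = np.asarray(grid, dtype=float)
    deg = block.degree
    lo_k, hi_k = block.knots[deg], block.knots[-deg - 1]
    if grid.min() < lo_k - 1e-9 or grid.max() > hi_k + 1e-9:
        raise ValueError(
            f"grid extends outside the fitted covariate range [{lo_k:g}, {hi_k:g}]"
        )
    B = bspline_basis(grid, knots=block.knots, degree=deg)
    curves = block.beta @ B.T  # n_kept x n_grid
    lo, hi = _interval(curves, level)
    return pd.DataFrame(
        {
            "grid": grid,
            "mean": curves.mean(axis=0),
            "lower": lo,
            "upper": hi,
        }
    )


def summarize_spatial(
    draws_or_block: PosteriorDraws | BlockDraws,
    param: str | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-region posterior mean, CrI and three-class significance.

    Class +1 when the lower CrI bound is above zero, -1 when the upper
    bound is below zero, 0 otherwise ("no significance").
    """
    block = (
        draws_or_block
        if isinstance(draws_or_block, BlockDraws)
        else draws_or_block.get_block(param, "spatial(region)")
    )
    if block.kind != "spatial":
        raise ValueError(f"block {block.label!r} is not a spatial term")
    lo, hi = _interval(block.beta, level)
    mean = block.beta.mean(axis=0)
    cls = np.where(lo > 0, 1, np.where(hi < 0, -1, 0))
    return pd.DataFrame(
        {
            "region": block.regions,
            "mean": mean,
            "lower": lo,
            "upper": hi,
            "class": cls,
        }
    )


def convergence_diagnostics(draws: PosteriorDraws, min_length: int = 100) -> pd.DataFrame:
    """Effective sample size and split-chain R-hat per scalar parameter.

    The single chain is split into two halves for the R-hat computation.
    Scalars with R-hat above 1.1 or ESS below 100 are flagged.
    """
    frame = draws.to_frame()
    L = len(frame)
    if L < min_length:
        raise ValueError(f"chain too short for diagnostics ({L} < {min_length})")
    half = L // 2
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, col in frame.items():
            x = col.to_numpy()
            split = np.stack([x[:half], x[half : 2 * half]])
            if np.allclose(x, x[0]):
                ess, rhat = 1.0, np.nan
            else:
                ess = float(az.ess(np.asarray([x])))
                rhat = float(az.rhat(split))
            rows.append(
                {
                    "parameter": name,
                    "ess": ess,
                    "rhat": rhat,
                    "flagged": bool(ess < 100 or (np.isfinite(rhat) and rhat > 1.1)),
                }
            )
    return pd.DataFrame(rows)


def plot_curve(curve: pd.DataFrame, ax=None, title: str | None = None):
    """Posterior-mean curve (solid) with credible band (dashed)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    ax.plot(curve["grid"], curve["mean"], "-", color="black")
    ax.plot(curve["grid"], curve["lower"], "--", color="grey")
    ax.plot(curve["grid"], curve["upper"], "--", color="grey")
    ax.axhline(0.0, lw=0.5, color="steelblue")
    if title:
        ax.set_title(title)
    return ax


def plot_spatial(spatial: pd.DataFrame, shape: tuple[int, int], ax=None, what: str = "mean"):
    """Lattice heat map of posterior means, or the three-class significance map."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    values = spatial[what].to_numpy().reshape(shape)
    if what == "class":
        im = ax.imshow(values, cmap="gray", vmin=-1, vmax=1)
    else:
        vmax = np.abs(values).max() or 1.0
        im = ax.imshow(values, cmap="RdYlGn_r", vmin=-vmax, vmax=vmax)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
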