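"""Pre-modelling covariate screening: chi-square tests and the VIF check.

Each categorical covariate is cross-tabulated against each binary outcome
and tested for independence with the plain Pearson chi-square statistic (no
continuity correction).  A covariate enters the model when it is associated
with *either* outcome at the chosen level (default 0.05).  Continuous
covariates bypass screening and always enter as smooth terms.

Multicollinearity among the selected covariates is then checked with
variance inflation factors computed on the dummy-coded linear design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .data_io import Dataset

__all__ = [
    "DegenerateTableError",
    "ContingencyTable",
    "chi_square_independence",
    "select_model_variables",
    "compute_vif",
]

log = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """A contingency table has a zero margin and the test is undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative counts with row/column labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self):
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or min(counts.shape) < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("table total must be positive")

    @classmethod
    def from_observations(cls, x, y) -> "ContingencyTable":
        tab = pd.crosstab(pd.Series(x, name="x"), pd.Series(y, name="y"))
        return cls(
            counts=tab.to_numpy(),
            row_labels=tuple(map(str, tab.index)),
            col_labels=tuple(map(str, tab.columns)),
        )

    @property
    def df(self) -> int:
        r, c = self.counts.shape
        return (r - 1) * (c - 1)


def chi_square_independence(table: ContingencyTable):
    """Pearson chi-square test of independence: ``(statistic, df, p)``.

    ``X^2 = sum (O - E)^2 / E`` with expected counts from the margin
    product; the p-value is the upper tail of the chi-square distribution
    with ``(r-1)(c-1)`` degrees of freedom.  No continuity correction is
    applied.  A zero row or column margin raises
    :class:`DegenerateTableError`.
    """
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DegenerateTableError("table has a zero margin")
    stat, p, df, _expected = chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def select_model_variables(ds: Dataset, alpha: float = 0.05) -> pd.DataFrame:
    """Screen every categorical covariate against both outcomes.

    Returns a frame with one row per covariate: the chi-square p-values
    against stunting and wasting and a ``selected`` flag set when the
    smaller p-value is below ``alpha`` (the either-outcome union rule).
    Covariates with degenerate tables are skipped with a warning and appear
    with missing p-values and ``selected=False``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    for cov in ds.categorical:
        x = ds.frame[cov].astype(str)
        try:
            _, _, p1 = chi_square_independence(ContingencyTable.from_observations(x, ds.y1))
            _, _, p2 = chi_square_independence(ContingencyTable.from_observations(x, ds.y2))
            selected = min(p1, p2) < alpha
        except (DegenerateTableError, ValueError) as exc:
            log.warning("screening skipped for %r: %s", cov, exc)
            p1 = p2 = np.nan
            selected = False
        rows.append(
            {"covariate": cov, "p_stunting": p1, "p_wasting": p2, "selected": selected}
        )
    return pd.DataFrame(rows)


def _dummy_design(ds: Dataset, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for cov in covariates:
        if cov in ds.categorical:
            levels = ds.levels(cov)
            obs = ds.frame[cov].astype(str).to_numpy()
            for lvl in levels[1:]:
                cols.append((obs == lvl).astype(float))
                names.append(f"{cov}[{lvl}]")
        else:
            cols.append(ds.frame[cov].to_numpy(dtype=float))
            names.append(cov)
    return np.column_stack(cols), names


def compute_vif(ds: Dataset, covariates: list[str]) -> pd.DataFrame:
    """Variance inflation factors of the dummy-coded linear design.

    ``VIF_j = 1 / (1 - R_j^2)`` where ``R_j^2`` comes from regressing term
    j on all other terms (with intercept).  Exact collinearity is flagged
    with an infinite VIF rather than an exception.
    """
    if len(covariates) < 2:
        raise ValueError("VIF needs at least two covariates")
    X, names = _dummy_design(ds, covariates)
    n, k = X.shape
    out = []
    for j in range(k):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _res, _rank, _sv = np.linalg.lstsq(others, X[:, j], rcond=None)
        fitted = others @ coef
        ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        ss_res = np.sum((X[:, j] - fitted) ** 2)
        if ss_tot <= 0:
            vif = np.inf
        else:
            r2 = 1.0 - ss_res / ss_tot
            vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append({"term": names[j], "vif": vif})
    return pd.DataFrame(out)
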