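"""Design matrices and prior precision matrices for the geoadditive predictors.

Each of the three distribution parameters (mu1, mu2, rho-predictor) gets a
list of :class:`DesignBlock` objects:

* ``linear`` — intercept plus dummy-coded categorical covariates with a
  declared reference level and a flat (improper uniform) prior;
* ``spline`` — cubic B-spline basis on equidistant knots with a
  second-order random-walk (second-difference) penalty, the Bayesian
  P-spline prior;
* ``spatial`` — region-indicator design with the intrinsic GMRF precision
  ``K = diag(|N(s)|) - A`` whose conditional mean is the neighbour average.

Smooth and spatial blocks carry a sum-to-zero constraint for
identifiability (absorbed by the intercept).  The constraint is enforced
exactly by reparameterising onto an orthonormal basis ``T`` of the
constraint null space: the sampler works with the reduced design ``Z @ T``
and penalty ``T' K T`` and maps draws back to the original coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

from .data_io import AdjacencyGraph, Dataset, SchemaError

__all__ = [
    "DesignError",
    "SmoothTerm",
    "ModelSpec",
    "DesignBlock",
    "bspline_basis",
    "bspline_knots",
    "rw2_penalty",
    "gmrf_precision",
    "build_designs",
    "PARAMS",
]

PARAMS = ("mu1", "mu2", "rho")


class DesignError(ValueError):
    """Design construction failed (constant covariate, unknown level, ...)."""


@dataclass(frozen=True)
class SmoothTerm:
    column: str
    n_knots: int = 20
    degree: int = 3


@dataclass
class ModelSpec:
    """Per-parameter term lists for the three predictors.

    ``linear`` lists categorical covariate names (dummy coded against the
    reference level declared on the Dataset); ``smooth`` lists
    :class:`SmoothTerm`; ``spatial`` toggles the region GMRF term.  Every
    parameter always receives exactly one intercept (part of the linear
    block).  By default the correlation predictor uses the same covariate
    set as the two means, the distributional-regression choice used for
    reporting linear, nonlinear and spatial effects on all three
    parameters.
    """

    linear: dict[str, list[str]] = field(default_factory=dict)
    smooth: dict[str, list[SmoothTerm]] = field(default_factory=dict)
    spatial: dict[str, bool] = field(default_factory=dict)

    @classmethod
    def from_terms(
        cls,
        linear: list[str],
        smooth: list[str | SmoothTerm] = (),
        spatial: bool = True,
        params: tuple[str, ...] = PARAMS,
    ) -> "ModelSpec":
        """Same term list on every requested parameter (the default layout)."""
        sm = [t if isinstance(t, SmoothTerm) else SmoothTerm(t) for t in smooth]
        return cls(
            linear={k: list(linear) for k in params},
            smooth={k: list(sm) for k in params},
            spatial={k: spatial for k in params},
        )

    def validate(self, ds: Dataset) -> None:
        for k in PARAMS:
            for c in self.linear.get(k, []):
                if c not in ds.categorical:
                    raise SchemaError(f"linear term {c!r} is not a declared categorical covariate")
            for t in self.smooth.get(k, []):
                if t.column not in ds.continuous:
                    raise SchemaError(f"smooth term {t.column!r} is not a declared continuous covariate")


@dataclass
class DesignBlock:
    """One additive term of one predictor: design, penalty and prior metadata.

    ``Z`` (n x d) and ``K`` (d x d) are in the original coefficient
    parameterisation; ``constraint`` is the linear functional whose null
    space the coefficients are restricted to (None for unconstrained
    blocks).  ``Zr``/``Kr`` are the reduced (constraint-free) design and
    penalty actually sampled, with ``T`` the map back (``beta = T @ alpha``)
    and ``rank`` the penalty rank entering the inverse-gamma variance
    update.  Linear blocks have ``K is None`` (flat prior, no variance
    parameter).
    """

    kind: str
    param: str
    label: str
    Z: np.ndarray
    colnames: list[str]
    K: np.ndarray | None = None
    constraint: np.ndarray | None = None
    # spline metadata for re-evaluating the basis on a grid
    column: str | None = None
    knots: np.ndarray | None = None
    degree: int | None = None
    regions: list[str] | None = None

    def __post_init__(self):
        self.region_index: np.ndarray | None = None
        if self.constraint is not None:
            self.T = null_space(np.atleast_2d(self.constraint))
        else:
            self.T = None
        self.Zr = self.Z @ self.T if self.T is not None else self.Z
        if self.K is not None:
            Kr = self.T.T @ self.K @ self.T if self.T is not None else self.K
            Kr = 0.5 * (Kr + Kr.T)
            self.Kr = Kr
            self.rank = int(np.linalg.matrix_rank(Kr, tol=1e-8))
        else:
            self.Kr = None
            self.rank = 0

    @property
    def dim(self) -> int:
        return self.Z.shape[1]

    @property
    def dim_reduced(self) -> int:
        return self.Zr.shape[1]

    @property
    def penalized(self) -> bool:
        return self.K is not None

    def to_original(self, alpha: np.ndarray) -> np.ndarray:
        """Map reduced coefficients back to the original parameterisation."""
        return alpha @ self.T.T if self.T is not None else alpha


def bspline_knots(lo: float, hi: float, n_knots: int = 20, degree: int = 3) -> np.ndarray:
    """Extended equidistant knot vector over [lo, hi].

    ``n_knots`` equidistant knots span the covariate range (n_knots - 1
    interior intervals); the vector is extended by ``degree`` knots on each
    side so the basis has ``n_knots + degree - 1`` columns.
    """
    if n_knots < 2:
        raise DesignError("need at least 2 knots")
    h = (hi - lo) / (n_knots - 1)
    inner = np.linspace(lo, hi, n_knots)
    left = lo - h * np.arange(degree, 0, -1)
    right = hi + h * np.arange(1, degree + 1)
    return np.concatenate([left, inner, right])


def bspline_basis(w, n_knots: int = 20, degree: int = 3, knots: np.ndarray | None = None) -> np.ndarray:
    """B-spline design matrix on equidistant knots spanning the data range.

    Rows form a partition of unity; with the default cubic basis on twenty
    equidistant knots the design has 22 columns.  Pass ``knots`` (an
    extended knot vector from :func:`bspline_knots`) to evaluate the same
    basis on new points, e.g. a plotting grid.
    """
    w = np.asarray(w, dtype=float)
    if knots is None:
        lo, hi = float(np.min(w)), float(np.max(w))
        if hi <= lo:
            raise DesignError("covariate is constant; cannot build a spline basis")
        knots = bspline_knots(lo, hi, n_knots, degree)
    return BSpline.design_matrix(w, knots, degree, extrapolate=True).toarray()


def rw2_penalty(d: int) -> np.ndarray:
    """Second-order random-walk penalty ``K = D2' D2`` of dimension d.

    ``D2`` is the second-difference operator, so constants and linear
    sequences lie in the null space (rank d - 2).
    """
    if d < 3:
        raise DesignError("RW2 penalty needs dimension >= 3")
    D2 = np.diff(np.eye(d), n=2, axis=0)
    return D2.T @ D2


def gmrf_precision(g: AdjacencyGraph) -> np.ndarray:
    """Intrinsic GMRF precision ``K = diag(|N(s)|) - adjacency``.

    Row sums are zero; the rank is S minus the number of connected
    components.  Island regions yield an all-zero row (their spatial effect
    is not informed by the prior); callers fix such effects at zero.
    """
    S = g.n_regions
    K = np.zeros((S, S))
    for s, nbs in enumerate(g.neighbours):
        K[s, s] = len(nbs)
        for r in nbs:
            K[s, r] = -1.0
    return K


def _linear_block(ds: Dataset, param: str, columns: list[str]) -> DesignBlock:
    cols = [np.ones(ds.n)]
    names = ["intercept"]
    for c in columns:
        levels = ds.levels(c)
        obs = ds.frame[c].astype(str).to_numpy()
        unknown = set(obs) - set(levels)
        if unknown:
            raise DesignError(f"unknown level(s) {sorted(unknown)} in column {c!r}")
        for lvl in levels[1:]:  # reference level dropped
            cols.append((obs == lvl).astype(float))
            names.append(f"{c}[{lvl}]")
    Z = np.column_stack(cols)
    return DesignBlock(kind="linear", param=param, label="linear", Z=Z, colnames=names)


def _spline_block(ds: Dataset, param: str, term: SmoothTerm) -> DesignBlock:
    w = ds.frame[term.column].to_numpy(dtype=float)
    lo, hi = float(w.min()), float(w.max())
    if hi <= lo:
        raise DesignError(f"smooth covariate {term.column!r} is constant")
    knots = bspline_knots(lo, hi, term.n_knots, term.degree)
    Z = bspline_basis(w, knots=knots, degree=term.degree)
    d = Z.shape[1]
    K = rw2_penalty(d)
    # centre the curve over an equidistant grid on the covariate range
    grid = np.linspace(lo, hi, 201)
    constraint = bspline_basis(grid, knots=knots, degree=term.degree).sum(axis=0)
    return DesignBlock(
        kind="spline",
        param=param,
        label=f"s({term.column})",
        Z=Z,
        colnames=[f"s({term.column}).{j}" for j in range(d)],
        K=K,
        constraint=constraint,
        column=term.column,
        knots=knots,
        degree=term.degree,
    )


def _spatial_block(ds: Dataset, param: str, g: AdjacencyGraph) -> DesignBlock:
    index = {r: i for i, r in enumerate(g.regions)}
    labels = ds.region.to_numpy()
    unknown = set(labels) - set(index)
    if unknown:
        raise DesignError(f"region(s) {sorted(unknown)} absent from the adjacency graph")
    S = g.n_regions
    ridx = np.array([index[r] for r in labels])
    Z = np.zeros((ds.n, S))
    Z[np.arange(ds.n), ridx] = 1.0
    K = gmrf_precision(g)
    # sum-to-zero constraint; island regions get their effect pinned at 0
    # (their precision row is zero, so the prior says nothing about them)
    constraint = [np.ones(S)]
    for lbl in g.islands():
        row = np.zeros(S)
        row[index[lbl]] = 1.0
        constraint.append(row)
    block = DesignBlock(
        kind="spatial",
        param=param,
        label="spatial(region)",
        Z=Z,
        colnames=[f"spatial[{r}]" for r in g.regions],
        K=K,
        constraint=np.vstack(constraint),
        regions=list(g.regions),
    )
    block.region_index = ridx  # fast-path gather index for the sampler
    return block


def build_designs(ds: Dataset, spec: ModelSpec, g: AdjacencyGraph | None = None) -> dict[str, list[DesignBlock]]:
    """Assemble per-parameter DesignBlock lists from a validated ModelSpec."""
    spec.validate(ds)
    blocks: dict[str, list[DesignBlock]] = {}
    for k in PARAMS:
        blist = [_linear_block(ds, k, spec.linear.get(k, []))]
        for term in spec.smooth.get(k, []):
            blist.append(_spline_block(ds, k, term))
        if spec.spatial.get(k, False):
            if g is None:
                raise DesignError("spatial term requested but no adjacency graph supplied")
            blist.append(_spatial_block(ds, k, g))
        blocks[k] = blist
    return blocks
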