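"""Gaussian GEE with exchangeable working correlation, plus spline designs.

This is the statistical engine shared by both analyses: an identity-link
Gaussian generalized-estimating-equations solver with an exchangeable
working correlation (constant within-cluster correlation ``alpha``),
robust (sandwich) covariance, B-spline and tensor-product design
construction, and joint Wald tests on named coefficient blocks.

Model
-----
For cluster i with :math:`n_i` observations, the working covariance is

.. math:: V_i = \\phi\\,[(1-\\alpha) I + \\alpha \\mathbf{1}\\mathbf{1}^T]

and the coefficient update solves
:math:`(\\sum_i X_i^T V_i^{-1} X_i)\\beta = \\sum_i X_i^T V_i^{-1} y_i`.
Moment estimates of the dispersion and correlation are interleaved with
coefficient updates until the maximum coefficient change falls below the
tolerance.  The robust covariance is the sandwich
:math:`B^{-1} M B^{-1}` with :math:`B = \\sum_i X_i^T V_i^{-1} X_i` and
:math:`M = \\sum_i X_i^T V_i^{-1} e_i e_i^T V_i^{-1} X_i`, consistent even
when the exchangeable working structure is wrong.

The exchangeable inverse is applied analytically via the Sherman–Morrison
identity, so the solver is fully vectorised over clusters (no per-cluster
Python loops) and handles tens of thousands of rows in milliseconds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

log = logging.getLogger(__name__)

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100


# ---------------------------------------------------------------------------
# B-spline and tensor-product design construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a B-spline basis.

    ``df`` counts the columns retained after dropping the first basis
    column (absorbed by the model intercept), matching the convention of
    common statistical spline formulas.  Interior knots are placed at
    quantiles of the observed predictor; boundary knots are clamped at the
    observed min/max (each repeated ``degree + 1`` times).
    """

    df: int
    degree: int = 3

    def __post_init__(self) -> None:
        if self.df < self.degree:
            raise ValueError(f"df={self.df} must be >= degree={self.degree}")

    @property
    def n_interior(self) -> int:
        return self.df - self.degree


def spline_knots(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Clamped knot vector with interior knots at quantiles of ``x``."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    m = spec.n_interior
    if m > 0:
        probs = np.arange(1, m + 1) / (m + 1)
        interior = np.quantile(x, probs)
    else:
        interior = np.empty(0)
    reps = spec.degree + 1
    return np.concatenate([np.full(reps, lo), interior, np.full(reps, hi)])


def bspline_basis(
    x: np.ndarray,
    spec: SplineSpec,
    knots: Optional[np.ndarray] = None,
    drop_first: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the clamped B-spline basis at ``x``.

    Returns ``(basis, knots)``: the design columns (``df`` of them when
    ``drop_first``, else ``df + 1``) and the knot vector used, so that new
    data can be evaluated on the training knots.

    Raises if ``x`` has too few distinct values to support the basis or
    falls outside the (training) boundary.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if len(np.unique(x)) <= spec.df:
            raise ValueError(
                f"need more than df={spec.df} distinct predictor values, "
                f"got {len(np.unique(x))}"
            )
        knots = spline_knots(x, spec)
    lo, hi = knots[0], knots[-1]
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError(f"predictor values outside spline boundary [{lo}, {hi}]")
    full = BSpline.design_matrix(x, knots, spec.degree, extrapolate=False).toarray()
    return (full[:, 1:] if drop_first else full), knots


def tensor_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All pairwise element-wise column products, A-major column order."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"row counts differ: {a.shape[0]} vs {b.shape[0]}")
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


@dataclass
class DesignMatrix:
    """A design matrix with named, disjoint column blocks and cluster ids.

    ``blocks`` maps block names (``intercept``, ``time_spline``,
    ``age_spline``, ``time_x_age``, ``outcome``, ...) to column index
    arrays.  Rows need not arrive grouped by cluster; the fitter sorts
    stably by cluster id.
    """

    values: np.ndarray
    blocks: Dict[str, np.ndarray]
    cluster_ids: np.ndarray
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cluster_ids = np.asarray(self.cluster_ids)
        if self.values.ndim != 2:
            raise ValueError("design values must be 2-D")
        if len(self.cluster_ids) != self.values.shape[0]:
            raise ValueError("cluster_ids length must match row count")
        seen: set[int] = set()
        for name, idx in self.blocks.items():
            idx = np.asarray(idx, dtype=int)
            self.blocks[name] = idx
            if seen & set(idx.tolist()):
                raise ValueError(f"block {name!r} overlaps another block")
            seen |= set(idx.tolist())
        if seen != set(range(self.values.shape[1])):
            raise ValueError("blocks must cover all columns exactly")

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def block_columns(self, *names: str) -> np.ndarray:
        """Concatenated column indices of one or more blocks."""
        return np.concatenate([self.blocks[n] for n in names])


def build_design(
    time: np.ndarray,
    cluster_ids: np.ndarray,
    time_spec: SplineSpec,
    *,
    age: Optional[np.ndarray] = None,
    bmi: Optional[np.ndarray] = None,
    covariate_spec: Optional[SplineSpec] = None,
    outcome: Optional[np.ndarray] = None,
    time_knots: Optional[np.ndarray] = None,
) -> DesignMatrix:
    """Assemble the analysis design: intercept + time spline (+ extras).

    With ``age``/``bmi``, adds their own B-spline main effects and the
    tensor products with the time spline (the varying-coefficient terms).
    With ``outcome`` (a 0/1 indicator), adds a linear outcome term and the
    outcome-by-time linear interaction used by the pre-loss model.
    """
    time = np.asarray(time, dtype=float)
    n = len(time)
    cols = [np.ones((n, 1))]
    blocks: Dict[str, np.ndarray] = {"intercept": np.array([0])}
    meta: Dict[str, object] = {"time_spec": time_spec}
    pos = 1

    t_basis, t_knots = bspline_basis(time, time_spec, knots=time_knots)
    meta["time_knots"] = t_knots
    cols.append(t_basis)
    blocks["time_spline"] = np.arange(pos, pos + t_basis.shape[1])
    pos += t_basis.shape[1]

    for name, cov in (("age", age), ("bmi", bmi)):
        if cov is None:
            continue
        if covariate_spec is None:
            raise ValueError("covariate_spec required when age/bmi supplied")
        c_basis, c_knots = bspline_basis(np.asarray(cov, float), covariate_spec)
        meta[f"{name}_knots"] = c_knots
        meta[f"{name}_spec"] = covariate_spec
        cols.append(c_basis)
        blocks[f"{name}_spline"] = np.arange(pos, pos + c_basis.shape[1])
        pos += c_basis.shape[1]
        tp = tensor_product(t_basis, c_basis)
        cols.append(tp)
        blocks[f"time_x_{name}"] = np.arange(pos, pos + tp.shape[1])
        pos += tp.shape[1]

    if outcome is not None:
        out = np.asarray(outcome, dtype=float).reshape(-1, 1)
        cols.append(out)
        blocks["outcome"] = np.array([pos])
        pos += 1
        cols.append(out * time.reshape(-1, 1))
        blocks["outcome_x_time"] = np.array([pos])
        pos += 1

    return DesignMatrix(np.hstack(cols), blocks, np.asarray(cluster_ids), meta)


# ---------------------------------------------------------------------------
# GEE fitting
# ---------------------------------------------------------------------------


@dataclass
class GEEFit:
    """Result of an exchangeable-GEE fit."""

    beta: np.ndarray
    alpha: float
    phi: float
    cov_naive: np.ndarray
    cov_robust: np.ndarray
    n_iter: int
    converged: bool
    n_obs: int
    n_clusters: int
    blocks: Dict[str, np.ndarray] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))

    def to_json(self) -> str:
        """Serialise the fit (coefficients, covariances, block map)."""
        doc = {
            "beta": self.beta.tolist(),
            "alpha": self.alpha,
            "phi": self.phi,
            "cov_naive": self.cov_naive.tolist(),
            "cov_robust": self.cov_robust.tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "blocks": {k: v.tolist() for k, v in self.blocks.items()},
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "GEEFit":
        doc = json.loads(text)
        return cls(
            beta=np.array(doc["beta"]),
            alpha=doc["alpha"],
            phi=doc["phi"],
            cov_naive=np.array(doc["cov_naive"]),
            cov_robust=np.array(doc["cov_robust"]),
            n_iter=doc["n_iter"],
            converged=doc["converged"],
            n_obs=doc["n_obs"],
            n_clusters=doc["n_clusters"],
            blocks={k: np.array(v) for k, v in doc["blocks"].items()},
        )


@dataclass(frozen=True)
class WaldResult:
    """Joint Wald chi-square test on a coefficient block."""

    statistic: float
    df: int
    p: float


def _cluster_slices(cluster_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stable sort order and per-cluster start offsets (for reduceat)."""
    order = np.argsort(cluster_ids, kind="stable")
    sorted_ids = cluster_ids[order]
    starts = np.concatenate([[0], np.flatnonzero(sorted_ids[1:] != sorted_ids[:-1]) + 1])
    return order, starts


def fit_gee(
    y: np.ndarray,
    X: DesignMatrix,
    *,
    alpha_fixed: Optional[float] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> GEEFit:
    """Fit an identity-link Gaussian GEE with exchangeable correlation.

    Iterates coefficient solves against the working covariance
    ``phi * [(1-alpha) I + alpha 11']`` with moment updates of ``phi``
    (Pearson, ``sum(e^2)/(N-p)``) and ``alpha`` (within-cluster pairwise
    residual products over ``phi * (sum n_i(n_i-1)/2 - p)``), until the
    largest coefficient change drops below ``tol``.  ``alpha_fixed`` pins
    the working correlation (useful for oracles and diagnostics).

    Non-convergence is reported on the returned fit, never silently.
    """
    y = np.asarray(y, dtype=float)
    order, starts = _cluster_slices(X.cluster_ids)
    ys = y[order]
    Xs = X.values[order]
    n_obs, p = Xs.shape
    sizes = np.diff(np.concatenate([starts, [n_obs]])).astype(float)
    n_clusters = len(starts)
    if n_clusters < 2:
        raise ValueError("GEE requires at least 2 clusters")
    if np.linalg.matrix_rank(Xs) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    max_size = sizes.max()
    alpha_lo = -1.0 / (max_size - 1.0) + 1e-6 if max_size > 1 else 0.0
    alpha_hi = 1.0 - 1e-6
    n_pairs_total = float(np.sum(sizes * (sizes - 1.0) / 2.0))

    beta = np.linalg.lstsq(Xs, ys, rcond=None)[0]  # OLS start
    alpha = 0.0 if alpha_fixed is None else float(alpha_fixed)
    phi = 1.0
    converged = False
    it = 0

    XtX = Xs.T @ Xs
    Xty = Xs.T @ ys

    Sx = np.add.reduceat(Xs, starts, axis=0)  # cluster sums of rows, (G,p)
    Sy = np.add.reduceat(ys, starts)  # (G,)

    for it in range(1, max_iter + 1):
        # Moment updates of (phi, alpha) from the current residuals, then
        # a coefficient solve against the updated working covariance.
        e = ys - Xs @ beta
        phi = float(e @ e) / max(n_obs - p, 1)
        if alpha_fixed is None:
            Se = np.add.reduceat(e, starts)
            Se2 = np.add.reduceat(e * e, starts)
            cross = 0.5 * float(np.sum(Se**2 - Se2))
            denom = phi * max(n_pairs_total - p, 1.0)
            # perfect fits (phi == 0) or no within-cluster pairs: alpha moot
            alpha = float(np.clip(cross / denom, alpha_lo, alpha_hi)) if denom > 0 else 0.0

        # Sherman–Morrison: V_i^-1 = (1/(phi(1-alpha))) [I - c_i 11'],
        # c_i = alpha / (1 - alpha + n_i alpha).
        c = alpha / (1.0 - alpha + sizes * alpha)  # per cluster
        B_unscaled = XtX - (Sx * c[:, None]).T @ Sx
        rhs = Xty - (Sx * c[:, None]).T @ Sy
        beta_new = np.linalg.solve(B_unscaled, rhs)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new

        if delta < tol and it > 1:
            converged = True
            break

    if not converged:
        log.warning("GEE did not converge in %d iterations (tol=%g)", max_iter, tol)

    # Final bread and meat at the converged (alpha, phi, beta).  A perfect
    # fit (phi == 0) degenerates to zero covariances; weight with unit
    # dispersion to keep the bread finite.
    c = alpha / (1.0 - alpha + sizes * alpha)
    scale = 1.0 / (max(phi, np.finfo(float).tiny) * (1.0 - alpha)) if phi > 0 else 1.0
    Sx = np.add.reduceat(Xs, starts, axis=0)
    e = ys - Xs @ beta
    Se = np.add.reduceat(e, starts)
    B = scale * (XtX - (Sx * c[:, None]).T @ Sx)
    # u_i = X_i' V_i^-1 e_i, vectorised over clusters.
    Xe = np.add.reduceat(Xs * e[:, None], starts, axis=0)  # (G, p) of X_i'e_i
    U = scale * (Xe - c[:, None] * Se[:, None] * Sx)
    M = U.T @ U
    B_inv = np.linalg.inv(B)
    cov_robust = B_inv @ M @ B_inv
    cov_robust = 0.5 * (cov_robust + cov_robust.T)  # enforce symmetry

    return GEEFit(
        beta=beta,
        alpha=alpha,
        phi=phi,
        cov_naive=B_inv,
        cov_robust=cov_robust,
        n_iter=it,
        converged=converged,
        n_obs=n_obs,
        n_clusters=n_clusters,
        blocks=dict(X.blocks),
        meta=dict(X.meta),
    )


def joint_wald(fit: GEEFit, block: Sequence[int] | str) -> WaldResult:
    """Joint Wald chi-square test that a coefficient block is zero.

    ``block`` is a block name from the fit's design or an explicit column
    index set.  The statistic is ``b' V_bb^{-1} b`` on the robust
    covariance with df equal to the block size.  A singular sub-covariance
    raises (no generalized inverse): it signals a design problem.
    """
    if isinstance(block, str):
        idx = fit.blocks[block]
        name = block
    else:
        idx = np.asarray(block, dtype=int)
        name = str(idx.tolist())
    if len(idx) == 0:
        raise ValueError("empty coefficient block")
    if np.any(idx < 0) or np.any(idx >= len(fit.beta)):
        raise IndexError(f"block {name} outside coefficient range")
    b = fit.beta[idx]
    V = fit.cov_robust[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular robust sub-covariance for block {name}"
        ) from err
    stat = max(stat, 0.0)
    df = len(idx)
    return WaldResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))


def joint_wald_blocks(fit: GEEFit, *names: str) -> WaldResult:
    """Joint Wald test over the union of several named blocks."""
    idx = np.concatenate([fit.blocks[n] for n in names])
    return joint_wald(fit, idx)


def predict_curve(fit: GEEFit, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fitted values and robust pointwise SEs for new design rows."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != len(fit.beta):
        raise ValueError(
            f"design has {X_new.shape[1]} columns, fit expects {len(fit.beta)}"
        )
    yhat = X_new @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X_new, fit.cov_robust, X_new))
    return yhat, se
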