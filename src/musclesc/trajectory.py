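"""Principal-curve pseudotime and the exercise maturation-shift statistic.

The myogenic differentiation continuum is modelled with a
Hastie-Stuetzle principal curve fitted in PC space: starting from the
first-principal-component line, the algorithm alternates orthogonal
projection of every cell onto the current polyline with a local-linear
(tricube-weighted) smoothing of each coordinate against the arc-length
parameter, re-parameterizing by cumulative chord length, until the
total squared projection distance stabilizes. Pseudotime is the
arc-length coordinate of a cell's orthogonal projection, with the curve
oriented so the designated start population (PAX7+ satellite cells)
sits at the origin.

The exercise effect is summarized per lineage as
``delta_pct = 100 * (mean lambda_post - mean lambda_pre) / L`` together
with a rank-sum p-value and the two pseudotime ECDFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .differential import rank_sum_test

__all__ = [
    "PrincipalCurve",
    "ShiftResult",
    "fit_principal_curve",
    "project_pseudotime",
    "orient_curve",
    "gene_trend_regression",
    "exercise_shift",
    "ecdf_table",
]


def _project_to_polyline(nodes: np.ndarray, node_lambda: np.ndarray, X: np.ndarray,
                         chunk: int = 512) -> tuple:
    """Orthogonal projection of points onto a node polyline.

    Every segment is checked; ties in distance resolve to the smaller
    arc-length coordinate. Returns (lambda, squared residual).
    """
    n_seg = len(nodes) - 1
    if n_seg < 1:
        raise ValidationError("curve must have >= 2 nodes")
    A = nodes[:-1]  # seg starts
    D = nodes[1:] - nodes[:-1]  # seg vectors
    seg_len2 = np.einsum("ij,ij->i", D, D)
    seg_len2 = np.maximum(seg_len2, 1e-300)
    lam_out = np.empty(len(X))
    res_out = np.empty(len(X))
    for lo in range(0, len(X), chunk):
        P = X[lo:lo + chunk]
        # t: (points, segs) clamped projection parameter
        diff = P[:, None, :] - A[None, :, :]
        t = np.einsum("psd,sd->ps", diff, D) / seg_len2[None, :]
        np.clip(t, 0.0, 1.0, out=t)
        proj = A[None, :, :] + t[:, :, None] * D[None, :, :]
        d2 = np.einsum("psd,psd->ps", P[:, None, :] - proj, P[:, None, :] - proj)
        lam_cand = node_lambda[:-1][None, :] + t * np.sqrt(seg_len2)[None, :]
        # smallest distance; ties -> smallest lambda
        d2r = np.round(d2, 12)
        best = np.lexsort((lam_cand, d2r))[:, 0]
        rows = np.arange(len(P))
        lam_out[lo:lo + chunk] = lam_cand[rows, best]
        res_out[lo:lo + chunk] = d2[rows, best]
    return lam_out, res_out


def _local_linear_pass(lam: np.ndarray, Y: np.ndarray, span: float,
                       w0: np.ndarray) -> np.ndarray:
    """One tricube local-linear pass with per-point base weights."""
    n, d = Y.shape
    m = max(int(np.ceil(span * n)), 2)
    out = np.empty_like(Y, dtype=float)
    lo = 0
    for i in range(n):
        # slide window [lo, lo+m) to the m nearest neighbours of lam[i]
        while lo + m < n and lam[lo + m] - lam[i] < lam[i] - lam[lo]:
            lo += 1
        xs = lam[lo:lo + m]
        ys = Y[lo:lo + m]
        dmax = max(abs(xs[0] - lam[i]), abs(xs[-1] - lam[i]))
        if dmax <= 0:
            w = w0[lo:lo + m] + 1e-12
            out[i] = (w @ ys) / w.sum()
            continue
        u = np.abs(xs - lam[i]) / dmax
        w = (1.0 - u ** 3) ** 3 * w0[lo:lo + m]
        w = np.maximum(w, 1e-12)
        sw = w.sum()
        xb = (w @ xs) / sw
        yb = (w @ ys) / sw
        xc = xs - xb
        denom = w @ (xc ** 2)
        if denom <= 1e-300:
            out[i] = yb
            continue
        slope = (w * xc) @ ys / denom - (w * xc).sum() * yb / denom
        out[i] = yb + slope * (lam[i] - xb)
    return out


def _local_linear_smooth(lam: np.ndarray, Y: np.ndarray, span: float,
                         robust_iter: int = 2) -> np.ndarray:
    """Robust tricube local-linear smoother of Y (n x d) against lam.

    ``lam`` must be sorted ascending. After each pass, points are
    down-weighted by the bisquare of their joint residual norm (lowess
    robustness iterations) so off-manifold outliers cannot drag the
    curve, which matters most near its ends.
    """
    w0 = np.ones(len(lam))
    out = _local_linear_pass(lam, Y, span, w0)
    for _ in range(robust_iter):
        resid = np.linalg.norm(Y - out, axis=1)
        s = np.median(resid)
        if s <= 0:
            break
        u = resid / (6.0 * s)
        w0 = np.where(u < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        if w0.sum() < max(3.0, 0.1 * len(lam)):
            break
        out = _local_linear_pass(lam, Y, span, w0)
    return out


class PrincipalCurve(BaseEstimator, TransformerMixin):
    """Hastie-Stuetzle principal curve with arc-length pseudotime.

    Parameters
    ----------
    span : float
        Fraction of points in each local-linear smoothing window.
    max_iter : int
        Maximum projection-expectation iterations.
    tol : float
        Relative change in total squared projection distance below
        which the fit is declared converged. ``inf`` stops after the
        first projection, i.e. the plain PC1-line projection.

    Fitted attributes: ``nodes_`` (ordered polyline in input space),
    ``node_lambda_`` (arc-length per node), ``length_``,
    ``pseudotime_`` and ``residuals_`` for the training points,
    ``loss_path_`` (accepted total squared projection distances),
    ``n_iter_``, ``converged_``.
    """

    def __init__(self, span: float = 0.6, max_iter: int = 50, tol: float = 1e-4):
        self.span = span
        self.max_iter = max_iter
        self.tol = tol

    # -- fitting ----------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2 or len(X) < 10:
            raise ValidationError("need a 2-D array with >= 10 points")
        if not (0 < self.span <= 1):
            raise ValidationError(f"span must be in (0, 1], got {self.span}")
        mu = X.mean(axis=0)
        Xc = X - mu
        # rank-0 check and PC1 init
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        if s[0] <= 1e-12:
            raise ValidationError("all points identical: no curve to fit")
        v = Vt[0]
        j = np.argmax(np.abs(v))
        if v[j] < 0:
            v = -v
        lam0 = Xc @ v
        order = np.argsort(lam0, kind="stable")
        nodes = mu + lam0[order, None] * v
        node_lambda = lam0[order] - lam0[order][0]

        prev_loss = None
        prev_state = None
        loss_path: list = []
        converged = False
        n_iter = 0
        for it in range(1, self.max_iter + 1):
            lam, res2 = _project_to_polyline(nodes, node_lambda, X)
            loss = float(res2.sum())
            if prev_loss is not None and loss > prev_loss * (1 + 1e-12):
                # smoothing increased the projection loss: keep previous
                nodes, node_lambda, lam, res2, loss = prev_state
                converged = True
                n_iter = it - 1
                break
            loss_path.append(loss)
            n_iter = it
            rel = np.inf if prev_loss is None else abs(prev_loss - loss) / max(prev_loss, 1e-300)
            if np.isinf(self.tol) or (prev_loss is not None and rel < self.tol) or loss == 0.0:
                converged = True
                break
            prev_state = (nodes, node_lambda, lam, res2, loss)
            prev_loss = loss

            # expectation: smooth each coordinate against lambda
            order = np.lexsort((np.arange(len(lam)), lam))
            smoothed = _local_linear_smooth(lam[order], X[order], self.span)
            # re-parameterize by cumulative chord length
            seg = np.linalg.norm(np.diff(smoothed, axis=0), axis=1)
            new_lambda = np.concatenate([[0.0], np.cumsum(seg)])
            keep = np.concatenate([[True], seg > 1e-12])
            nodes = smoothed[keep]
            node_lambda = new_lambda[keep]
            if len(nodes) < 2:
                raise ValidationError("curve collapsed to a point during smoothing")
        else:
            # max_iter exhausted after a smoothing step: re-project so the
            # reported pseudotime matches the final node set
            lam_f, res2_f = _project_to_polyline(nodes, node_lambda, X)
            loss_f = float(res2_f.sum())
            if prev_loss is not None and loss_f > prev_loss * (1 + 1e-12):
                nodes, node_lambda, lam, res2, loss = prev_state
            else:
                lam, res2, loss = lam_f, res2_f, loss_f
                loss_path.append(loss)
            warnings.warn("principal curve did not converge within max_iter")

        self.nodes_ = nodes
        self.node_lambda_ = node_lambda
        self.length_ = float(node_lambda[-1])
        self.pseudotime_ = lam
        self.residuals_ = np.sqrt(res2)
        self.loss_path_ = loss_path
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.smoother_span = self.span
        return self

    # -- projection -------------------------------------------------
    def project(self, X) -> tuple:
        """(arc-length coordinate, residual distance) for new points."""
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.nodes_.shape[1]:
            raise ValidationError(
                f"points have dim {X.shape[1]}, curve has dim {self.nodes_.shape[1]}"
            )
        lam, res2 = _project_to_polyline(self.nodes_, self.node_lambda_, X)
        return lam, np.sqrt(res2)

    def transform(self, X):
        return self.project(X)[0][:, None]

    # -- orientation ------------------------------------------------
    def orient(self, start_points, other_points) -> "PrincipalCurve":
        """Flip so start points sit at small arc length (in place)."""
        start_points = np.asarray(start_points, float)
        other_points = np.asarray(other_points, float)
        if len(start_points) == 0:
            raise ValidationError("start_cells must be nonempty")
        lam_start = self.project(start_points)[0].mean()
        lam_other = self.project(other_points)[0].mean() if len(other_points) else np.inf
        if np.isclose(lam_start, lam_other):
            raise ValidationError(
                "start and other cells have equal mean pseudotime; inspect the embedding"
            )
        if lam_start > lam_other:
            self.flip()
        return self

    def flip(self) -> "PrincipalCurve":
        """Reverse curve direction; arc length re-anchored at 0."""
        self.nodes_ = self.nodes_[::-1].copy()
        self.node_lambda_ = (self.length_ - self.node_lambda_)[::-1].copy()
        if hasattr(self, "pseudotime_") and self.pseudotime_ is not None:
            self.pseudotime_ = self.length_ - self.pseudotime_
        return self


def fit_principal_curve(
    points, span: float = 0.6, max_iter: int = 50, tol: float = 1e-4
) -> PrincipalCurve:
    """Fit a principal curve to a cells x dims matrix."""
    return PrincipalCurve(span=span, max_iter=max_iter, tol=tol).fit(points)


def project_pseudotime(curve: PrincipalCurve, points) -> pd.DataFrame:
    """Pseudotime table: lambda, lambda/L and residual per point."""
    lam, resid = curve.project(points)
    L = curve.length_
    return pd.DataFrame(
        {
            "lambda": lam,
            "lambda_norm": lam / L if L > 0 else lam,
            "residual_distance": resid,
        }
    )


def orient_curve(curve: PrincipalCurve, start_cells, other_cells) -> PrincipalCurve:
    """Orient so the start population has the smaller mean pseudotime."""
    return curve.orient(start_cells, other_cells)


def gene_trend_regression(norm, coordinate, genes) -> pd.DataFrame:
    """OLS of normalized expression on a 1-D coordinate, per gene.

    ``norm`` may be an ExpressionMatrix or a genes x cells array paired
    with a gene list. Reports slope, Pearson r, r^2 and the slope's
    two-sided p-value.
    """
    from .preprocess import ExpressionMatrix

    coordinate = np.asarray(coordinate, float)
    if len(coordinate) < 3:
        raise ValidationError("need >= 3 cells for a trend regression")
    if np.std(coordinate) == 0:
        raise ValidationError("coordinate has zero variance")
    rows = []
    for gene in genes:
        if isinstance(norm, ExpressionMatrix):
            yv = norm.gene_row(gene)
        else:
            yv = np.asarray(norm[gene], float)
        if len(yv) != len(coordinate):
            raise ValidationError(f"gene {gene!r}: length mismatch with coordinate")
        if np.std(yv) == 0:
            rows.append((gene, 0.0, 0.0, 0.0, 1.0))
            continue
        fit = scipy.stats.linregress(coordinate, yv)
        rows.append((gene, fit.slope, fit.rvalue, fit.rvalue ** 2, fit.pvalue))
    return pd.DataFrame(rows, columns=["gene", "slope", "pearson_r", "r_squared", "p"])


# ---------------------------------------------------------------------------
# Exercise shift
# ---------------------------------------------------------------------------

@dataclass
class ShiftResult:
    """Pre/post pseudotime shift for one lineage."""

    lineage: str
    delta_pct: float  # 100 * (mean post - mean pre) / L
    p_two_sided: float
    p_one_sided: float  # in the direction of delta
    n_pre: int
    n_post: int
    ecdf_pre: pd.DataFrame = field(repr=False)
    ecdf_post: pd.DataFrame = field(repr=False)


def ecdf_table(values: np.ndarray) -> pd.DataFrame:
    """Step-function table (x, F) of the empirical CDF."""
    x = np.sort(np.asarray(values, float))
    return pd.DataFrame({"x": x, "F": np.arange(1, len(x) + 1) / len(x)})


def exercise_shift(pt: pd.DataFrame, curve_length: float | None = None) -> dict:
    """Pre- vs post-exercise pseudotime shift per lineage.

    ``pt`` needs columns ``lineage``, ``lambda``, ``timepoint``; the
    curve length per lineage is either given (single-lineage tables) or
    taken from a ``curve_length`` column. Both timepoints must be
    present with >= 3 cells each. Returns lineage -> ShiftResult.
    """
    required = {"lineage", "lambda", "timepoint"}
    if not required <= set(pt.columns):
        raise ValidationError(f"pseudotime table needs columns {sorted(required)}")
    out: dict = {}
    for lineage, sub in pt.groupby("lineage", sort=True):
        pre = sub.loc[sub["timepoint"] == "pre", "lambda"].to_numpy()
        post = sub.loc[sub["timepoint"] == "post", "lambda"].to_numpy()
        if len(pre) < 3 or len(post) < 3:
            raise ValidationError(
                f"lineage {lineage!r}: both timepoints need >= 3 cells "
                f"(got {len(pre)} pre, {len(post)} post)"
            )
        if curve_length is not None:
            L = float(curve_length)
        elif "curve_length" in sub.columns:
            L = float(sub["curve_length"].iloc[0])
        else:
            L = float(sub["lambda"].max())
        if L <= 0:
            raise ValidationError(f"lineage {lineage!r}: non-positive curve length")
        delta_pct = 100.0 * (post.mean() - pre.mean()) / L
        if np.array_equal(np.sort(pre), np.sort(post)):
            p_two, p_one = 1.0, 1.0
        else:
            p_two = rank_sum_test(post, pre, "two").p
            p_one = rank_sum_test(post, pre, "greater" if delta_pct >= 0 else "less").p
        out[lineage] = ShiftResult(
            lineage=str(lineage),
            delta_pct=float(delta_pct),
            p_two_sided=p_two,
            p_one_sided=p_one,
            n_pre=len(pre),
            n_post=len(post),
            ecdf_pre=ecdf_table(pre),
            ecdf_post=ecdf_table(post),
        )
    return out
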