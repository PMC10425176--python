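"""Expression dynamics: fate-weighted spline GAMs over latent time and
spatial smooths over the mediolateral axis.

The temporal model regresses module (or gene) expression on a cubic B-spline
basis of latent time with a log link and a negative-binomial mean-variance
relation, each observation weighted by the cell's absorption probability for
one fate.  Because the response is an average of normalized values (and so
continuous), the NB family is used as a quasi-likelihood: only its variance
function and link enter the weighted IRLS fit.  A Gaussian-on-log1p fallback
family is provided.  Intervals are pointwise 95% Wald bands propagated
through the link.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.decomposition import PCA


def _spline_knots(x: np.ndarray, knots: int, degree: int = 3) -> np.ndarray:
    """Full knot vector: ``knots`` interior knots at equally spaced quantiles
    of x, boundary knots at the data range, each repeated degree+1 times."""
    qs = np.linspace(0, 1, knots + 2)[1:-1]
    interior = np.quantile(x, qs)
    lo, hi = float(x.min()), float(x.max())
    interior = np.clip(interior, lo + 1e-12, hi - 1e-12)
    return np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]


def _design(x: np.ndarray, knot_vector: np.ndarray, degree: int = 3) -> np.ndarray:
    return BSpline.design_matrix(x, knot_vector, degree, extrapolate=True).toarray()


@dataclass
class GamFit:
    """Fitted spline GAM: coefficients, their covariance, and the basis."""

    coefficients: np.ndarray
    cov: np.ndarray
    knot_vector: np.ndarray
    degree: int
    family: str  # "nb" or "gaussian"
    weights: np.ndarray
    x_range: tuple[float, float]
    scale: float

    def predict(self, grid) -> np.ndarray:
        return self.predict_with_ci(grid)[0]

    def predict_with_ci(self, grid, level: float = 0.95):
        """Pointwise mean and Wald confidence band on the response scale."""
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.x_range
        if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
            warnings.warn("grid extends beyond the fitted range; extrapolating")
        Z = _design(grid, self.knot_vector, self.degree)
        eta = Z @ self.coefficients
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Z, self.cov, Z), 0.0))
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        if self.family == "nb":
            mean = np.exp(eta)
            lower = np.exp(eta - z * se)
            upper = np.exp(eta + z * se)
        elif self.family == "gaussian":
            mean = np.expm1(eta)
            lower = np.expm1(eta - z * se)
            upper = np.expm1(eta + z * se)
        else:  # identity link (spatial smooths of scaled expression)
            mean, lower, upper = eta, eta - z * se, eta + z * se
        return mean, lower, upper

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame(
            {"coef": self.coefficients, "se": se},
            index=[f"b{j}" for j in range(len(self.coefficients))])


class WeightedSplineGAM:
    """Model object for a fate-weighted cubic-spline GAM.

    Parameters
    ----------
    x : latent-time (or axis) coordinate per cell
    y : non-negative response per cell (module score or gene expression)
    weights : per-cell observation weights (one fate's absorption
        probabilities); zero-weight cells are excluded exactly
    knots : number of interior knots, placed at equally spaced quantiles
    family : "nb" (log link, NB variance, default) or "gaussian"
        (identity fit on log1p(y))
    """

    def __init__(self, x, y, weights=None, knots: int = 4, family: str = "nb",
                 nb_alpha: float = 1.0, degree: int = 3):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if weights is None:
            weights = np.ones_like(x)
        w = np.asarray(weights, dtype=float)
        if not (len(x) == len(y) == len(w)):
            raise ValueError("x, y and weights must be aligned")
        if np.any(w < 0):
            raise ValueError("negative weights")
        if family == "nb" and np.any(y < 0):
            raise ValueError("negative response under the log link")
        keep = w > 0
        if keep.sum() < knots + 2:
            raise ValueError(
                f"need at least knots+2 = {knots + 2} positively weighted cells, "
                f"got {int(keep.sum())}")
        w_kept = w[keep]
        # normalize to mean 1 so uniform weight rescaling cannot interact
        # with the smoothing penalty
        self.x, self.y, self.w = x[keep], y[keep], w_kept / w_kept.mean()
        self.knots = knots
        self.degree = degree
        self.family = family
        self.nb_alpha = nb_alpha

    # candidate smoothing parameters scanned by GCV
    _LAMBDAS = np.geomspace(1e-5, 1e3, 17)

    def _penalty(self, p: int) -> np.ndarray:
        D = np.diff(np.eye(p), n=2, axis=0)  # second-order difference penalty
        return D.T @ D

    def _pirls(self, Z, y, w, lam, P, max_iter=100, tol=1e-10):
        """Penalized IRLS for the log-link quasi-likelihood with NB variance.

        Returns (beta, cov, edf, pearson_scale)."""
        alpha = self.nb_alpha
        mu = np.full_like(y, max(np.average(y, weights=w), 1e-6))
        eta = np.log(mu)
        beta = None
        for _ in range(max_iter):
            V = mu + alpha * mu ** 2
            wk = w * mu ** 2 / V          # working weights (log link)
            z = eta + (y - mu) / mu       # working response
            ZtW = Z.T * wk
            A = ZtW @ Z + lam * P
            new = np.linalg.solve(A, ZtW @ z)
            if beta is not None and np.max(np.abs(new - beta)) < tol:
                beta = new
                break
            beta = new
            eta = np.clip(Z @ beta, -30, 30)
            mu = np.exp(eta)
        V = mu + alpha * mu ** 2
        wk = w * mu ** 2 / V
        ZtW = Z.T * wk
        Ainv = np.linalg.inv(ZtW @ Z + lam * P)
        H = Ainv @ (ZtW @ Z)
        edf = float(np.trace(H))
        pearson = float(np.sum(w * (y - mu) ** 2 / V))
        n = len(y)
        scale = pearson / max(n - edf, 1.0)
        cov = scale * (Ainv @ (ZtW @ Z) @ Ainv)
        return beta, cov, edf, scale, mu, wk

    def fit(self) -> GamFit:
        kv = _spline_knots(self.x, self.knots, self.degree)
        Z = _design(self.x, kv, self.degree)
        P = self._penalty(Z.shape[1])
        if self.family == "nb":
            y = self.y + 1e-9
            best = None
            n = len(y)
            for lam in self._LAMBDAS:
                beta, cov, edf, scale, mu, wk = self._pirls(Z, y, self.w, lam, P)
                # GCV on the weighted Pearson residuals
                pearson = np.sum(self.w * (y - mu) ** 2 / (mu + self.nb_alpha * mu ** 2))
                gcv = n * pearson / max(n - edf, 1e-6) ** 2
                if best is None or gcv < best[0]:
                    best = (gcv, beta, cov, scale)
            _, beta, cov, scale = best
        elif self.family == "gaussian":
            yl = np.log1p(self.y)
            best = None
            n = len(yl)
            for lam in self._LAMBDAS:
                ZtW = Z.T * self.w
                Ainv = np.linalg.inv(ZtW @ Z + lam * P)
                beta = Ainv @ (ZtW @ yl)
                H = Ainv @ (ZtW @ Z)
                edf = float(np.trace(H))
                rss = float(np.sum(self.w * (yl - Z @ beta) ** 2))
                gcv = n * rss / max(n - edf, 1e-6) ** 2
                scale = rss / max(n - edf, 1.0)
                cov = scale * (Ainv @ (ZtW @ Z) @ Ainv)
                if best is None or gcv < best[0]:
                    best = (gcv, beta, cov, scale)
            _, beta, cov, scale = best
        else:
            raise ValueError(f"unknown family {self.family!r}")
        return GamFit(
            coefficients=np.asarray(beta),
            cov=np.asarray(cov),
            knot_vector=kv,
            degree=self.degree,
            family=self.family,
            weights=self.w,
            x_range=(float(self.x.min()), float(self.x.max())),
            scale=float(scale),
        )


def fit_weighted_gam(x, y, weights, knots: int = 4, family: str = "nb",
                     nb_alpha: float = 1.0) -> GamFit:
    """Fate-probability-weighted GAM of expression over latent time."""
    if np.all(np.asarray(weights) == 0):
        raise ValueError("all weights are zero")
    return WeightedSplineGAM(x, y, weights, knots=knots, family=family,
                             nb_alpha=nb_alpha).fit()


def predict_with_ci(fit: GamFit, grid, level: float = 0.95):
    return fit.predict_with_ci(grid, level=level)


# ---------------------------------------------------------------------------
# mediolateral axis
# ---------------------------------------------------------------------------

def ml_axis(scaled: np.ndarray, gene_ids: pd.Index,
            orientation_markers: dict[str, list[str]], seed: int = 42) -> np.ndarray:
    """Mediolateral coordinate: the negated first principal component of the
    stage subset, sign-fixed so that cells scoring high for the lateral
    (non-neural) marker set lie at larger coordinates than cells scoring high
    for the medial (neural) set."""
    if scaled.shape[1] < 2:
        raise ValueError("need at least two cells")
    pca = PCA(n_components=1, random_state=seed)
    coord = -pca.fit_transform(scaled.T).ravel()
    if np.allclose(coord.std(), 0):
        raise ValueError("degenerate PC1: zero variance")

    def set_score(genes):
        present = [g for g in genes if g in gene_ids]
        if not present:
            raise ValueError(f"orientation marker set absent from data: {genes}")
        return scaled[gene_ids.get_indexer(present)].mean(axis=0)

    lat = set_score(orientation_markers["lateral"])
    med = set_score(orientation_markers["medial"])
    hi_lat = lat >= np.quantile(lat, 0.75)
    hi_med = med >= np.quantile(med, 0.75)
    if coord[hi_lat].mean() < coord[hi_med].mean():
        coord = -coord
    return coord


def fit_spatial_gam(y, axis, knots: int = 4) -> GamFit:
    """Unweighted cubic-spline smooth of scaled expression along the axis
    (identity link; scaled values can be negative)."""
    axis = np.asarray(axis, dtype=float)
    if np.ptp(axis) == 0:
        raise ValueError("constant axis")
    y = np.asarray(y, dtype=float)
    kv = _spline_knots(axis, knots)
    Z = _design(axis, kv)
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    dof = max(len(y) - Z.shape[1], 1)
    scale = float(resid @ resid) / dof
    cov = scale * np.linalg.pinv(Z.T @ Z)
    return GamFit(
        coefficients=beta, cov=cov, knot_vector=kv, degree=3,
        family="identity", weights=np.ones_like(axis),
        x_range=(float(axis.min()), float(axis.max())), scale=scale)


# identity-link prediction for spatial fits
def _identity_predict(fit: GamFit, grid, level: float = 0.95):
    grid = np.asarray(grid, dtype=float)
    Z = _design(grid, fit.knot_vector, fit.degree)
    eta = Z @ fit.coefficients
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Z, fit.cov, Z), 0.0))
    from scipy.stats import norm
    z = norm.ppf(0.5 + level / 2)
    return eta, eta - z * se, eta + z * se


def predict_spatial(fit: GamFit, grid, level: float = 0.95):
    if fit.family != "identity":
        raise ValueError("predict_spatial is for identity-link spatial fits")
    return _identity_predict(fit, grid, level)


# ---------------------------------------------------------------------------
# HCR intensity z-scoring
# ---------------------------------------------------------------------------

REGIONS = ("anterior", "intermediate", "posterior")


def zscore_intensity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score of summed HCR intensities across the three
    anteroposterior levels (sample sd over the 3 regions); a zero-variance
    gene becomes all zeros with a warning."""
    missing = [r for r in REGIONS if r not in table.columns]
    if missing:
        raise ValueError(f"missing regions: {missing}")
    vals = table[list(REGIONS)].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite intensity values")
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} genes with zero intensity variance set to 0")
    sd[sd == 0] = 1.0
    z = (vals - mean) / sd
    return pd.DataFrame(z, index=table.index, columns=list(REGIONS))
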