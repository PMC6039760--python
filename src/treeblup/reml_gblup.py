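"""Single-GRM linear mixed model: REML variance components and GBLUP.

Model ``y = X b + Z a + e`` with ``a ~ N(0, sigma2_a * G)`` and
``e ~ N(0, sigma2_e * I)``.  The restricted likelihood is profiled over
the variance ratio on the spectrum of ``Z G Z'`` (one eigendecomposition
per fit, 1-D bounded optimisation on the log-ratio), and the variance
components are recovered in closed form at the optimum.  Standard errors
come from the observed information (numerical Hessian of the restricted
log-likelihood); the heritability SE uses the delta method.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .data_io import GenotypeMatrix, PhenotypeTable, group_design
from .grm import Grm

__all__ = ["MixedModelSpec", "VarianceComponents", "GebvTable",
           "make_spec", "reml_loglik", "fit_reml", "predict_gebv",
           "variance_share"]

_RATIO_BOUNDS = (1e-6, 1e6)
_XTOL = 1e-8


@dataclasses.dataclass
class MixedModelSpec:
    """Observed data and design for one mixed-model fit."""

    y: np.ndarray            # (n_obs,)
    X: np.ndarray            # (n_obs, p) fixed-effect design incl. intercept
    Z: np.ndarray            # (n_obs, n_animals) incidence
    G: Grm
    ridge: float = 0.0       # added to G before fitting (recorded, not hidden)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.y)
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("X/Z row counts do not match y")
        if self.Z.shape[1] != self.G.n:
            raise ValueError("Z column count does not match GRM size")

    def g_matrix(self) -> np.ndarray:
        if self.ridge > 0:
            return self.G.matrix + self.ridge * np.eye(self.G.n)
        return self.G.matrix


@dataclasses.dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    sigma2_p: float
    h2: float
    se_sigma2_a: float
    se_sigma2_e: float
    se_h2: float
    loglik_reml: float
    converged: bool
    boundary: bool = False
    identifiable: bool = True
    n_obs: int = 0

    def to_series(self) -> pd.Series:
        return pd.Series(dataclasses.asdict(self))


@dataclasses.dataclass
class GebvTable:
    animal_ids: list[str]
    gebv: np.ndarray
    reliability: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"animal_id": self.animal_ids, "gebv": self.gebv})
        if self.reliability is not None:
            df["reliability"] = self.reliability
        return df

    def gebv_of(self) -> dict[str, float]:
        return dict(zip(self.animal_ids, self.gebv.tolist()))


def _full_rank_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (QR with
    column pivoting), keeping original order."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    return np.sort(piv[:rank])


def make_spec(G: Grm, pheno: PhenotypeTable, *, use_adjusted: bool = False,
              fixed_effects: tuple[str, ...] = ("contemporary_group", "age_days"),
              mask_ids: set[str] | None = None, ridge: float = 0.0) -> MixedModelSpec:
    """Assemble a :class:`MixedModelSpec` from a GRM and phenotype table.

    By default the raw phenotype is modelled with contemporary group and
    age as fixed effects; ``use_adjusted=True`` instead fits the
    pre-adjusted phenotype on an intercept only.  ``mask_ids`` drops
    those animals' records (they stay in G and still receive GEBVs).
    """
    df = pheno.data.set_index("animal_id")
    obs_ids = [a for a in G.animal_ids if a in df.index
               and not (mask_ids and a in mask_ids)]
    if not obs_ids:
        raise ValueError("no phenotyped animals left in the model")
    sub = df.loc[obs_ids]
    if use_adjusted:
        if "y_adjusted" not in sub.columns:
            raise ValueError("phenotypes not adjusted; run adjust_phenotypes")
        y = sub["y_adjusted"].to_numpy(float)
        X = np.ones((len(y), 1))
    else:
        y = sub["y_raw"].to_numpy(float)
        cols = [np.ones(len(y))]
        if "contemporary_group" in fixed_effects:
            gcols, _ = group_design(sub["contemporary_group"].astype(str))
            if gcols.shape[1]:
                cols.append(gcols)
        if "age_days" in fixed_effects:
            cols.append(sub["age_days"].to_numpy(float).reshape(-1, 1))
        X = np.column_stack(cols)
    X = X[:, _full_rank_columns(X)]
    pos = {a: i for i, a in enumerate(G.animal_ids)}
    Z = np.zeros((len(obs_ids), G.n))
    Z[np.arange(len(obs_ids)), [pos[a] for a in obs_ids]] = 1.0
    return MixedModelSpec(y=y, X=X, Z=Z, G=G, ridge=ridge)


def _eigen_rotate(spec: MixedModelSpec):
    H = spec.Z @ spec.g_matrix() @ spec.Z.T
    d, U = np.linalg.eigh(0.5 * (H + H.T))
    d = np.clip(d, 0.0, None)
    return d, U.T @ spec.y, U.T @ spec.X


def _reml_core(d: np.ndarray, ystar: np.ndarray, Xstar: np.ndarray,
               sigma2_a: float, sigma2_e: float) -> float:
    """Restricted log-likelihood at one parameter point (rotated data)."""
    n, p = Xstar.shape
    w = 1.0 / (sigma2_a * d + sigma2_e)
    Xw = Xstar * w[:, None]
    A = Xstar.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ ystar)
    resid = ystar - Xstar @ beta
    quad = float(np.sum(w * resid * resid))
    _, logdetA = np.linalg.slogdet(A)
    logdetV = float(-np.sum(np.log(w)))
    return -0.5 * ((n - p) * np.log(2.0 * np.pi) + logdetV + logdetA + quad)


def reml_loglik(sigma2_a: float, sigma2_e: float, spec: MixedModelSpec) -> float:
    """Restricted log-likelihood of (sigma2_a, sigma2_e) via the eigen
    path (equals the direct matrix-form REML log-likelihood)."""
    d, ystar, Xstar = _eigen_rotate(spec)
    return _reml_core(d, ystar, Xstar, sigma2_a, sigma2_e)


def _profile_fit(d, ystar, Xstar, lam):
    """Closed-form (sigma2_e, loglik) at a fixed variance ratio lam."""
    n, p = Xstar.shape
    w = 1.0 / (lam * d + 1.0)
    Xw = Xstar * w[:, None]
    A = Xstar.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ ystar)
    resid = ystar - Xstar @ beta
    rss = float(np.sum(w * resid * resid))
    s2e = rss / (n - p)
    _, logdetA = np.linalg.slogdet(A)
    ll = -0.5 * ((n - p) * np.log(2.0 * np.pi) + (n - p) * np.log(s2e)
                 + float(np.sum(np.log(lam * d + 1.0))) + logdetA + (n - p))
    return s2e, ll


def fit_reml(spec: MixedModelSpec) -> VarianceComponents:
    """Estimate (sigma2_a, sigma2_e, h2) by REML.

    The restricted likelihood is profiled over ``lam = sigma2_a/sigma2_e``
    on the log scale within ``[1e-6, 1e6]``; a boundary optimum is
    flagged.  A spectrum of ``Z G Z'`` that is (numerically) constant
    makes only the total variance identifiable; the fit is then flagged
    ``identifiable=False`` with NaN components.
    """
    n, p = spec.X.shape
    if n < p + 2:
        raise ValueError(f"need at least p+2={p + 2} records, got {n}")
    d, ystar, Xstar = _eigen_rotate(spec)

    spread = float(d.max() - d.min())
    if spread <= 1e-9 * max(1.0, float(d.max())):
        # V = (sigma2_a * c + sigma2_e) I: only the total is identified
        s2p, ll = _profile_fit(np.zeros_like(d), ystar, Xstar, 1.0)
        warnings.warn("flat GRM spectrum: variance ratio not identifiable",
                      UserWarning)
        return VarianceComponents(np.nan, np.nan, s2p, np.nan, np.nan, np.nan,
                                  np.nan, ll, converged=True, identifiable=False,
                                  n_obs=n)

    lo, hi = np.log(_RATIO_BOUNDS[0]), np.log(_RATIO_BOUNDS[1])
    res = optimize.minimize_scalar(
        lambda t: -_profile_fit(d, ystar, Xstar, np.exp(t))[1],
        bounds=(lo, hi), method="bounded", options={"xatol": _XTOL})
    lam = float(np.exp(res.x))
    s2e, ll = _profile_fit(d, ystar, Xstar, lam)
    s2a = lam * s2e
    boundary = res.x < lo + 1e-4 or res.x > hi - 1e-4
    if boundary and res.x < lo + 1e-4:
        s2a = 0.0
    s2p = s2a + s2e
    h2 = s2a / s2p

    se_a = se_e = se_h2 = np.nan
    try:
        if boundary:
            raise ValueError("boundary estimate; curvature-based SEs undefined")
        cov = _observed_info_cov(d, ystar, Xstar, s2a, s2e)
        se_a, se_e = np.sqrt(np.diag(cov))
        grad = np.array([s2e, -s2a]) / s2p**2
        se_h2 = float(np.sqrt(grad @ cov @ grad))
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn("information matrix not invertible; SEs unset", UserWarning)
    return VarianceComponents(s2a, s2e, s2p, h2, float(se_a), float(se_e),
                              float(se_h2), ll, converged=bool(res.success),
                              boundary=boundary, n_obs=n)


def _observed_info_cov(d, ystar, Xstar, s2a, s2e) -> np.ndarray:
    """Covariance of (sigma2_a, sigma2_e) from a central-difference
    Hessian of the restricted log-likelihood."""
    theta = np.array([s2a, s2e])
    h = np.maximum(1e-4 * np.abs(theta), 1e-6)
    h = np.minimum(h, np.abs(theta) / 2.0 + 1e-12)  # keep steps inside the domain

    def f(t):
        if t[1] <= 0 or t[0] < 0:
            raise ValueError("Hessian step left the parameter space")
        return _reml_core(d, ystar, Xstar, t[0], t[1])

    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            H[i, j] = (f(theta + ei + ej) - f(theta + ei - ej)
                       - f(theta - ei + ej) + f(theta - ei - ej)) / (4 * h[i] * h[j])
    info = -H
    cov = np.linalg.inv(info)
    if (np.diag(cov) <= 0).any():
        raise np.linalg.LinAlgError("negative variance from information matrix")
    return cov


def predict_gebv(spec: MixedModelSpec, vc: VarianceComponents,
                 compute_reliability: bool = False) -> GebvTable:
    """BLUP of breeding values for every animal in G (phenotyped or not)
    from the observed records in ``spec``:
    ``a_hat = sigma2_a * G Z' V^{-1} (y - X b_hat)``."""
    if not vc.identifiable or not np.isfinite(vc.sigma2_a):
        raise ValueError("variance components not identifiable; cannot BLUP")
    Gm = spec.g_matrix()
    n_obs = len(spec.y)
    if n_obs == 0:
        raise ValueError("no phenotyped records")
    V = vc.sigma2_a * (spec.Z @ Gm @ spec.Z.T) + vc.sigma2_e * np.eye(n_obs)
    Vi = np.linalg.inv(V)
    XtVi = spec.X.T @ Vi
    beta = np.linalg.solve(XtVi @ spec.X, XtVi @ spec.y)
    resid = spec.y - spec.X @ beta
    GZt = Gm @ spec.Z.T
    a_hat = vc.sigma2_a * (GZt @ (Vi @ resid))
    reliability = None
    if compute_reliability:
        P = Vi - XtVi.T @ np.linalg.solve(XtVi @ spec.X, XtVi)
        pev = vc.sigma2_a * np.diag(Gm) - vc.sigma2_a**2 * np.einsum(
            "ij,jk,ik->i", GZt, P, GZt)
        denom = vc.sigma2_a * np.diag(Gm)
        with np.errstate(divide="ignore", invalid="ignore"):
            reliability = np.clip(1.0 - pev / denom, 0.0, 1.0)
            reliability[~np.isfinite(reliability)] = 0.0
    return GebvTable(list(spec.G.animal_ids), a_hat, reliability)


def variance_share(vc_subset: VarianceComponents, vc_all: VarianceComponents) -> float:
    """Subset additive variance as a percentage of the all-SNP additive
    variance fitted on the same cohort."""
    if not np.isfinite(vc_all.sigma2_a) or vc_all.sigma2_a <= 0:
        raise ValueError("all-SNP additive variance is zero/undefined")
    return 100.0 * vc_subset.sigma2_a / vc_all.sigma2_a
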