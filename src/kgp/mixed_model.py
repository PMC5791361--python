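"""Single-trait animal-model REML and gBLUP.

Model
-----
    y = Xβ + g + e,   g ~ N(0, K σ²_g),   e ~ N(0, I σ²_e)

with K either the pedigree numerator relationship matrix A or the
genomic matrix G.  Variance components are estimated by restricted
maximum likelihood.  Because there is a single random effect, the
restricted likelihood can be profiled exactly: one eigendecomposition
K = U D U′ rotates the model to independent residuals, after which the
likelihood is a smooth 1-D function of the ratio λ = σ²_g/σ²_e.  We
maximise that profile by bounded scalar optimisation and evaluate the
average-information matrix only once, at the optimum, for standard
errors.  Heritability is h² = σ²_g/(σ²_g + σ²_e); from a genomic model
this ratio is the "pseudo-heritability".

Breeding values are the BLUP ĝ = σ²_g K V⁻¹(y − Xβ̂) with
V = Kσ²_g + Iσ²_e and β̂ the GLS solution — equivalent to solving
Henderson's mixed-model equations.  Marker (allele substitution)
effects are back-solved from ĝ as α̂ = φ·W′G⁻¹ĝ, which satisfies the
reconstruction identity Wα̂ = ĝ up to the ridge regularisation, and
enable phenotype prediction for new genotypes: ŷ = Xβ̂ + Wα̂.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import GenotypeMatrix, KinshipMatrix, PhenotypeTable
from .kinship import _vanraden
from .marker_stats import allele_frequencies

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "GBLUPFit",
    "GBLUPRegressor",
    "fit_reml",
    "fit_gblup",
    "backsolve_ase",
    "predict_phenotype",
    "predictive_ability",
    "FlatLikelihoodError",
]

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


class FlatLikelihoodError(ValueError):
    """The variance ratio is unidentifiable (e.g. K proportional to I)."""


@dataclass
class ModelSpec:
    """Fixed-effect structure of the animal model.

    ``fixed_effects`` are column names of the phenotype table treated
    as categorical factors (reference-level coded); an intercept is
    always included.
    """

    response: str
    fixed_effects: list[str] = field(default_factory=lambda: ["stock_origin"])


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float | None
    se_sigma2_g: float | None
    se_sigma2_e: float | None
    loglik: float
    n_iter: int
    converged: bool
    boundary: bool = False


@dataclass
class GBLUPFit:
    beta_hat: np.ndarray
    fixed_effect_names: list[str]
    g_hat: np.ndarray
    ids: list[str]
    varcomp: VarianceComponents
    ase: np.ndarray | None = None
    marker_ids: list[str] | None = None

    @property
    def pseudo_h2(self) -> float:
        return self.varcomp.h2


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------


def _design_matrix(
    table: pd.DataFrame, fixed_effects: list[str], levels: dict | None = None
) -> tuple[np.ndarray, list[str], dict]:
    """Intercept + reference-coded factor columns.

    ``levels`` fixes the training factor coding; an unseen level at
    prediction time raises with the offending level named.
    """
    cols = [np.ones(len(table))]
    names = ["intercept"]
    out_levels: dict = {}
    for fe in fixed_effects:
        vals = table[fe].astype(str).to_numpy()
        if levels is None:
            cats = sorted(pd.unique(vals))
        else:
            cats = levels[fe]
            unseen = set(vals) - set(cats)
            if unseen:
                raise ValueError(
                    f"unseen level(s) {sorted(unseen)} for fixed effect {fe!r}"
                )
        out_levels[fe] = cats
        for lev in cats[1:]:  # drop reference level
            cols.append((vals == lev).astype(float))
            names.append(f"{fe}[{lev}]")
    X = np.column_stack(cols)
    if levels is None and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    return X, names, out_levels


# ---------------------------------------------------------------------------
# REML kernel
# ---------------------------------------------------------------------------


def _profile_reml(d, yt, Xt):
    """Return f(log λ) -> (-restricted loglik, beta, s2e)."""
    n, p = Xt.shape

    def parts(log_lam):
        lam = np.exp(log_lam)
        h = d * lam + 1.0
        Xh = Xt / h[:, None]
        XtHX = Xt.T @ Xh
        XtHy = Xh.T @ yt
        beta = linalg.solve(XtHX, XtHy, assume_a="pos")
        r = yt - Xt @ beta
        quad = float(r @ (r / h))
        s2e = quad / (n - p)
        sign, logdet_X = np.linalg.slogdet(XtHX)
        ll = -0.5 * (
            (n - p) * np.log(s2e)
            + np.sum(np.log(h))
            + logdet_X
            + (n - p)
        )
        return ll, beta, s2e

    return parts


def reml_kernel(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    tol: float = 1e-8,
) -> tuple[VarianceComponents, np.ndarray]:
    """Profile-REML for one genetic variance component.

    Returns the variance components and the GLS fixed-effect solution
    at the optimum.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    K = np.asarray(K, dtype=float)
    n = y.size
    p = X.shape[1]
    if n - p < 2:
        raise ValueError("too few residual degrees of freedom")
    d, U = linalg.eigh(K)
    if d.min() < -1e-8:
        raise ValueError(
            "kinship matrix is not positive semi-definite; regularize first"
        )
    d = np.clip(d, 0.0, None)
    if np.ptp(d) < 1e-8 * max(1.0, abs(d).max()):
        raise FlatLikelihoodError(
            "kinship matrix is (numerically) proportional to the identity: "
            "genetic and residual variances are not separable"
        )
    yt = U.T @ y
    Xt = U.T @ X
    parts = _profile_reml(d, yt, Xt)

    # coarse grid then local refinement of the 1-D profile
    grid = np.linspace(*_LOG_LAMBDA_BOUNDS, 49)
    lls = np.array([parts(g)[0] for g in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -parts(t)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    log_lam = float(res.x)
    ll, beta, s2e = parts(log_lam)
    lam = np.exp(log_lam)
    boundary = log_lam <= _LOG_LAMBDA_BOUNDS[0] + 1e-6
    if boundary:
        lam = 0.0
    s2g = lam * s2e
    # floor tiny components
    floor = 1e-10 * float(np.var(y))
    if s2g < floor:
        s2g = 0.0 if boundary else max(s2g, 0.0)
    h2 = s2g / (s2g + s2e)

    se_g = se_e = se_h2 = None
    try:
        cov = _ai_covariance(d, yt, Xt, s2g if s2g > 0 else floor, s2e)
        se_g = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_e = float(np.sqrt(max(cov[1, 1], 0.0)))
        tot = s2g + s2e
        jac = np.array([s2e / tot**2, -s2g / tot**2])
        var_h2 = float(jac @ cov @ jac)
        se_h2 = float(np.sqrt(max(var_h2, 0.0)))
    except linalg.LinAlgError:  # pragma: no cover - degenerate information
        pass

    vc = VarianceComponents(
        sigma2_g=float(s2g),
        sigma2_e=float(s2e),
        h2=float(h2),
        se_h2=se_h2,
        se_sigma2_g=se_g,
        se_sigma2_e=se_e,
        loglik=float(ll),
        n_iter=int(res.nfev) + len(grid),
        converged=bool(res.success),
        boundary=bool(boundary),
    )
    return vc, beta


def _ai_covariance(d, yt, Xt, s2g, s2e):
    """Average-information covariance of (σ²g, σ²e) in the rotated basis."""
    h = d * (s2g / s2e) + 1.0
    vinv = 1.0 / (h * s2e)
    Xv = Xt * vinv[:, None]
    XtVX = Xt.T @ Xv
    XtVX_inv = linalg.inv(XtVX)

    def P(v):
        return vinv * v - Xv @ (XtVX_inv @ (Xv.T @ v))

    w = P(yt)
    kw = d * w
    AI = 0.5 * np.array(
        [
            [float(kw @ P(kw)), float(kw @ P(w))],
            [float(kw @ P(w)), float(w @ P(w))],
        ]
    )
    return linalg.inv(AI)


def fit_reml(
    phenotypes: PhenotypeTable,
    spec: ModelSpec,
    K: KinshipMatrix,
    tol: float = 1e-8,
) -> VarianceComponents:
    """REML variance components for one trait under the animal model."""
    y, X, _, _, Ksub = _align(phenotypes, spec, K)
    vc, _ = reml_kernel(y, X, Ksub, tol=tol)
    return vc


def _align(phenotypes: PhenotypeTable, spec: ModelSpec, K: KinshipMatrix):
    df = phenotypes.data.dropna(subset=[spec.response]).reset_index(drop=True)
    ids = df["id"].tolist()
    missing = set(ids) - set(K.ids)
    if missing:
        raise ValueError(
            f"{len(missing)} phenotyped ids absent from kinship matrix, "
            f"e.g. {sorted(missing)[:3]}"
        )
    Ksub = K.subset(ids)
    y = df[spec.response].to_numpy(dtype=float)
    X, names, levels = _design_matrix(df, spec.fixed_effects)
    return y, X, names, levels, Ksub.values


def gblup_solve(y, X, K, s2g, s2e):
    """GLS fixed effects and BLUP breeding values for known variances.

    Identical to solving Henderson's mixed-model equations; implemented
    via the phenotypic covariance V = Kσ²g + Iσ²e.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    K = np.asarray(K, dtype=float)
    n = y.size
    V = K * s2g + np.eye(n) * s2e
    cho = linalg.cho_factor(V)
    Vy = linalg.cho_solve(cho, y)
    VX = linalg.cho_solve(cho, X)
    beta = linalg.solve(X.T @ VX, X.T @ Vy, assume_a="pos")
    resid = y - X @ beta
    g_hat = s2g * (K @ linalg.cho_solve(cho, resid))
    return beta, g_hat


def fit_gblup(
    phenotypes: PhenotypeTable,
    spec: ModelSpec,
    K: KinshipMatrix,
    varcomp: VarianceComponents | None = None,
) -> GBLUPFit:
    """Fixed-effect solutions and breeding values (BLUP) for one trait."""
    y, X, names, _, Ksub = _align(phenotypes, spec, K)
    if varcomp is None:
        varcomp, _ = reml_kernel(y, X, Ksub)
    beta, g_hat = gblup_solve(y, X, Ksub, varcomp.sigma2_g, varcomp.sigma2_e)
    ids = phenotypes.data.dropna(subset=[spec.response])["id"].tolist()
    return GBLUPFit(
        beta_hat=beta,
        fixed_effect_names=names,
        g_hat=g_hat,
        ids=ids,
        varcomp=varcomp,
    )


def backsolve_ase(
    g_hat: np.ndarray, W: np.ndarray, phi: float, G: np.ndarray | None = None
) -> np.ndarray:
    """Allele substitution effects from breeding values.

    α̂ = φ·W′G⁻¹ĝ with W the centered dosages used to build G.  When G
    is singular a regularized (ridge) inverse is used with a warning.
    Satisfies Wα̂ ≈ ĝ.
    """
    W = np.asarray(W, dtype=float)
    g_hat = np.asarray(g_hat, dtype=float)
    if G is None:
        G = phi * (W @ W.T)
        G = G + np.eye(G.shape[0]) * 1e-6
    try:
        sol = linalg.solve(G, g_hat, assume_a="pos")
    except linalg.LinAlgError:
        warnings.warn("G singular; using regularized inverse for ASE", stacklevel=2)
        sol = linalg.lstsq(G + np.eye(G.shape[0]) * 1e-6, g_hat)[0]
    return phi * (W.T @ sol)


def predict_phenotype(
    beta_hat: np.ndarray,
    ase: np.ndarray,
    X_new: np.ndarray,
    W_new: np.ndarray,
) -> np.ndarray:
    """ŷ = X_new β̂ + W_new α̂ (W_new centered with TRAINING frequencies)."""
    return np.asarray(X_new) @ np.asarray(beta_hat) + np.asarray(W_new) @ np.asarray(ase)


def predictive_ability(
    y_actual,
    y_pred,
    h2: float = 1.0,
) -> dict:
    """Accuracy r(y, ŷ)/√h² plus actual-on-predicted regression stats.

    Returns a dict with keys ``r``, ``accuracy``, ``r2``, ``slope``,
    ``intercept``, ``n``.  The accuracy can exceed 1 for small h² —
    that is a property of the definition, not an error.
    """
    y_actual = np.asarray(y_actual, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_actual.size != y_pred.size or y_actual.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (0 < h2 <= 1):
        raise ValueError("h2 must lie in (0, 1]")
    if np.std(y_actual) == 0 or np.std(y_pred) == 0:
        return {
            "r": np.nan,
            "accuracy": np.nan,
            "r2": np.nan,
            "slope": np.nan,
            "intercept": np.nan,
            "n": int(y_actual.size),
            "defined": False,
        }
    reg = stats.linregress(y_pred, y_actual)  # actual on predicted
    r = float(stats.pearsonr(y_actual, y_pred)[0])
    return {
        "r": r,
        "accuracy": r / np.sqrt(h2),
        "r2": float(reg.rvalue**2),
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
        "n": int(y_actual.size),
        "defined": True,
    }


# ---------------------------------------------------------------------------
# sklearn estimator
# ---------------------------------------------------------------------------


class GBLUPRegressor(RegressorMixin, BaseEstimator):
    """Genomic BLUP as a scikit-learn regressor.

    ``fit(X, y)`` takes a NaN-coded dosage matrix (individuals ×
    markers), builds the VanRaden genomic relationship matrix from the
    training allele frequencies, estimates σ²g/σ²e by profile REML
    (unless ``h2`` is fixed), solves for fixed effects and breeding
    values, and back-solves per-marker allele substitution effects.
    ``predict(X_new)`` centers new dosages with the *training*
    frequencies and returns ŷ = X_newβ̂ + W_newα̂.

    Parameters
    ----------
    h2 : float, optional
        Fix the heritability instead of estimating it by REML.
    covariate_effects : bool
        If True, a ``covariates`` array of factor labels passed to
        ``fit``/``predict`` enters as reference-coded fixed effects.
    ridge : float
        Diagonal regularization added to G.

    Attributes
    ----------
    allele_freq_ : counted-allele frequencies used for centering
    phi_ : VanRaden normalisation constant
    varcomp_ : VarianceComponents (pseudo-heritability = ``h2_``)
    beta_ : fixed-effect solutions; g_hat_ : breeding values
    ase_ : allele substitution effects (0 for monomorphic markers)
    """

    def __init__(self, h2: float | None = None, ridge: float = 1e-6):
        self.h2 = h2
        self.ridge = ridge

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_individuals, n_markers) matching y")
        self.allele_freq_ = allele_frequencies(X)
        G, phi, poly, W = _vanraden(X, freqs=self.allele_freq_, ridge=self.ridge)
        self.phi_ = phi
        self._poly = poly
        Xf, levels = self._fixed_design(y.size, covariates, None)
        self._levels = levels
        if self.h2 is None:
            vc, _ = reml_kernel(y, Xf, G)
        else:
            vy = float(np.var(y, ddof=1))
            vc = VarianceComponents(
                sigma2_g=self.h2 * vy,
                sigma2_e=(1 - self.h2) * vy,
                h2=self.h2,
                se_h2=None,
                se_sigma2_g=None,
                se_sigma2_e=None,
                loglik=np.nan,
                n_iter=0,
                converged=True,
            )
        self.varcomp_ = vc
        self.h2_ = vc.h2
        beta, g_hat = gblup_solve(y, Xf, G, vc.sigma2_g, vc.sigma2_e)
        self.beta_ = beta
        self.g_hat_ = g_hat
        ase = np.zeros(X.shape[1])
        ase[poly] = backsolve_ase(g_hat, W, phi, G=G)
        self.ase_ = ase
        self.n_features_in_ = X.shape[1]
        return self

    def _fixed_design(self, n, covariates, levels):
        if covariates is None:
            return np.ones((n, 1)), {}
        df = pd.DataFrame({"cov": np.asarray(covariates).astype(str)})
        Xf, _, lv = _design_matrix(
            df, ["cov"], levels={"cov": levels["cov"]} if levels else None
        )
        return Xf, lv

    def predict(self, X, covariates=None):
        check_is_fitted(self, "ase_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("marker count differs from training data")
        p = self.allele_freq_
        Xi = np.where(np.isnan(X), 2.0 * p, X)
        W = Xi - 2.0 * np.where(np.isnan(p), 0.0, p)
        if covariates is None:
            Xf = np.ones((X.shape[0], 1))
            if self.beta_.size != 1:
                raise ValueError("model was fitted with covariates; pass them")
        else:
            Xf, _ = self._fixed_design(X.shape[0], covariates, self._levels)
        return predict_phenotype(self.beta_, self.ase_, Xf, W)

    def _more_tags(self):  # pragma: no cover
        return {"allow_nan": True}
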