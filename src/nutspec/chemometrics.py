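"""Multivariate calibration of nutrient content against NIR spectra.

Implements PLS1 (sequential NIPALS with deflation) and principal component
regression on mean-centred data, prediction through a single regression
vector, and the full validation metric suite used to judge NIR calibrations:

* RMSEC / SEC / R2C on the calibration set,
* RMSECV / SECV / R2CV under cross-validation of the calibration set,
* RMSEP / SEP / R2P on a held-out prediction set,
* RPD = sd(holdout reference) / SEP, with qualitative banding.

Conventions (documented so reports are unambiguous): RMSE-type statistics use
divisor n on raw residuals; SE-type statistics are the bias-corrected spread,
sqrt(sum((r - mean(r))^2) / (n - 1)), i.e. the sd of the residuals after
removing mean bias. R2 is 1 - SS_res/SS_tot. X is centred but not autoscaled
(SNV pretreatment already normalises scans); y is centred only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import SpectraSet


@dataclass
class CalibrationModel:
    """A fitted PLS or PCR calibration reduced to a regression vector.

    Prediction is always ``yhat = (X - x_mean) @ coefficients + y_mean``;
    the latent-variable internals (weights/loadings for PLS, loadings for PCR)
    are retained for diagnostics.
    """

    method: str                       # "pls" | "pcr"
    n_components: int
    x_mean: np.ndarray                # (p,)
    y_mean: float
    coefficients: np.ndarray          # (p,), nutrient % per absorbance unit
    wavelengths: np.ndarray           # grid the model was fit on
    weights: np.ndarray | None = None     # PLS W (p, k)
    x_loadings: np.ndarray | None = None  # PLS P or PCR V (p, k)
    y_loadings: np.ndarray | None = None  # PLS q (k,)
    singular_values: np.ndarray | None = None  # PCR (k,)

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.coefficients.shape != self.wavelengths.shape:
            raise ValueError("coefficients must have one entry per wavelength")


@dataclass
class ValidationReport:
    """The calibration/cross-validation/prediction metric suite for one model."""

    method: str
    nutrient: str
    n_components: int
    rmsec: float
    sec: float
    r2c: float
    rmsecv: float
    secv: float
    r2cv: float
    rmsep: float
    sep: float
    r2p: float
    rpd: float
    n_cal: int
    n_val: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SplitSpec:
    """How samples are split for validation.

    ``n_holdout`` samples (chosen at random under ``seed``) form the
    prediction set; cross-validation statistics come from ``scheme`` applied
    to the remaining calibration samples (``k_fold`` with ``n_folds`` folds,
    or ``leave_one_out``).
    """

    n_holdout: int
    seed: int
    scheme: str = "k_fold"
    n_folds: int = 10

    def __post_init__(self) -> None:
        if self.n_holdout < 1:
            raise ValueError("n_holdout must be positive")
        if self.scheme not in ("k_fold", "leave_one_out", "random_holdout"):
            raise ValueError(f"unknown split scheme {self.scheme!r}")


# ---------------------------------------------------------------------------
# residual statistics


def rmse(residuals: np.ndarray) -> float:
    r = np.asarray(residuals, dtype=float)
    return float(np.sqrt(np.mean(r**2)))


def standard_error(residuals: np.ndarray) -> float:
    """Bias-corrected residual spread: sd of residuals about their mean (n-1)."""
    r = np.asarray(residuals, dtype=float)
    if r.size < 2:
        raise ValueError("standard error requires at least 2 residuals")
    return float(np.sqrt(np.sum((r - r.mean()) ** 2) / (r.size - 1)))


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R^2 undefined: reference values are constant")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


# ---------------------------------------------------------------------------
# model fitting


def _check_xy(X: SpectraSet | np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(X, SpectraSet):
        wl, M = X.wavelengths, X.absorbance
    else:
        M = np.atleast_2d(np.asarray(X, dtype=float))
        wl = np.arange(M.shape[1], dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if M.shape[0] != y.size:
        raise ValueError(f"X has {M.shape[0]} scans but y has {y.size} values")
    if k > min(M.shape[0] - 1, M.shape[1]):
        raise ValueError(
            f"k={k} exceeds min(n_samples-1, n_wavelengths)="
            f"{min(M.shape[0] - 1, M.shape[1])}"
        )
    if M.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} components")
    return wl, M, y


def fit_pls(X: SpectraSet | np.ndarray, y: np.ndarray, k: int) -> CalibrationModel:
    """PLS1 by sequential NIPALS: extract latent variables maximising the
    covariance between spectra and the reference values, deflating X (and y)
    after each component. The returned regression vector reproduces the
    scores-path prediction exactly: B = W (P'W)^(-1) q. Extraction stops early
    (recording a smaller n_components) once the response is fit to machine
    precision — closure-constrained mixture data is rank-deficient and can
    exhaust its information before k components.
    """
    wl, M, y = _check_xy(X, y, k)
    x_mean = M.mean(axis=0)
    y_mean = float(y.mean())
    Xc = M - x_mean
    yc = y - y_mean
    n, p = Xc.shape
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    q = np.zeros(k)
    Xd, yd = Xc.copy(), yc.copy()
    y_scale = max(1.0, float(np.linalg.norm(yc)))
    k_eff = k
    for a in range(k):
        if np.linalg.norm(yd) <= 1e-12 * y_scale:
            k_eff = a  # response already fit exactly; later LVs carry nothing
            break
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12 * max(1.0, np.linalg.norm(Xd)):
            raise ValueError(
                f"k={k} exceeds the effective rank of the problem (component {a + 1})"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-28:
            raise ValueError(f"degenerate score vector at component {a + 1}")
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t / tt)
        Xd -= np.outer(t, p_a)
        yd -= q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
    if k_eff == 0:
        raise ValueError("response is constant; nothing to calibrate")
    W, P, q = W[:, :k_eff], P[:, :k_eff], q[:k_eff]
    beta = W @ np.linalg.solve(P.T @ W, q)
    return CalibrationModel(
        method="pls", n_components=k_eff, x_mean=x_mean, y_mean=y_mean,
        coefficients=beta, wavelengths=wl, weights=W, x_loadings=P, y_loadings=q,
    )


def fit_pcr(X: SpectraSet | np.ndarray, y: np.ndarray, k: int) -> CalibrationModel:
    """Principal component regression: regress y on the first k principal
    component scores of centred X. Components are ordered by decreasing
    explained variance with a deterministic sign convention (largest-magnitude
    loading element positive).
    """
    wl, M, y = _check_xy(X, y, k)
    x_mean = M.mean(axis=0)
    y_mean = float(y.mean())
    Xc = M - x_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * max(s[0], 1.0)))
    if rank == 0:
        raise ValueError("X has no variance; nothing to calibrate")
    if k > rank:
        # closure-constrained mixtures are rank-deficient; regress on what exists
        warnings.warn(
            f"k={k} exceeds the effective rank {rank} of X; using {rank} components",
            stacklevel=2,
        )
        k = rank
    # sign convention for reproducibility
    for a in range(k):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] *= -1.0
            U[:, a] *= -1.0
    Vk = Vt[:k].T
    gamma = (U[:, :k].T @ (y - y_mean)) / s[:k]
    beta = Vk @ gamma
    return CalibrationModel(
        method="pcr", n_components=k, x_mean=x_mean, y_mean=y_mean,
        coefficients=beta, wavelengths=wl, x_loadings=Vk, singular_values=s[:k].copy(),
    )


def predict(model: CalibrationModel, X: SpectraSet | np.ndarray) -> np.ndarray:
    """Predict nutrient content (%): yhat = (X - x_mean) @ B + y_mean."""
    if isinstance(X, SpectraSet):
        if X.wavelengths.size != model.wavelengths.size or not np.allclose(
            X.wavelengths, model.wavelengths
        ):
            raise ValueError("spectra are not on the model's wavelength grid")
        M = X.absorbance
    else:
        M = np.atleast_2d(np.asarray(X, dtype=float))
        if M.shape[1] != model.wavelengths.size:
            raise ValueError("spectra are not on the model's wavelength grid")
    return (M - model.x_mean) @ model.coefficients + model.y_mean


_FITTERS = {"pls": fit_pls, "pcr": fit_pcr}


def _cv_residuals(M: np.ndarray, y: np.ndarray, method: str, k: int, split: SplitSpec) -> np.ndarray:
    """Pooled out-of-fold residuals on the calibration set."""
    n = y.size
    if split.scheme == "leave_one_out":
        folds = [np.array([i]) for i in range(n)]
    else:
        n_folds = min(split.n_folds, n)
        rng = np.random.default_rng(split.seed + 1)
        perm = rng.permutation(n)
        folds = [perm[i::n_folds] for i in range(n_folds)]
    fit = _FITTERS[method]
    resid = np.empty(n)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        m = fit(M[mask], y[mask], k)
        resid[fold] = y[fold] - predict(m, M[fold])
    return resid


def validate(
    method: str,
    X: SpectraSet | np.ndarray,
    y: np.ndarray,
    split: SplitSpec,
    n_components: int,
    nutrient: str = "",
) -> tuple[CalibrationModel, ValidationReport]:
    """Fit on the calibration subset and compute the full metric suite.

    The ``split.n_holdout`` randomly selected samples are the prediction set
    (RMSEP/SEP/R2P and RPD = sd of their reference values / SEP); RMSECV/SECV/
    R2CV come from cross-validation within the calibration subset.
    """
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}; expected 'pls' or 'pcr'")
    wl, M, y = _check_xy(X, y, n_components)
    n = y.size
    if not 0 < split.n_holdout < n:
        raise ValueError(f"n_holdout={split.n_holdout} infeasible for {n} samples")
    if split.n_holdout < 2:
        raise ValueError("holdout too small to estimate a reference sd")
    rng = np.random.default_rng(split.seed)
    hold = np.sort(rng.choice(n, size=split.n_holdout, replace=False))
    cal = np.setdiff1d(np.arange(n), hold)

    Mc, yc = M[cal], y[cal]
    Mh, yh = M[hold], y[hold]
    model = _FITTERS[method](Mc, yc, n_components)
    model.wavelengths = wl

    res_c = yc - predict(model, Mc)
    res_cv = _cv_residuals(Mc, yc, method, n_components, split)
    res_p = yh - predict(model, Mh)

    sep = standard_error(res_p)
    sd_hold = float(np.std(yh, ddof=1))
    report = ValidationReport(
        method=method, nutrient=nutrient, n_components=n_components,
        rmsec=rmse(res_c), sec=standard_error(res_c), r2c=r_squared(yc, yc - res_c),
        rmsecv=rmse(res_cv), secv=standard_error(res_cv),
        r2cv=r_squared(yc, yc - res_cv),
        rmsep=rmse(res_p), sep=sep, r2p=r_squared(yh, yh - res_p),
        rpd=(np.inf if sep == 0 else sd_hold / sep),
        n_cal=int(cal.size), n_val=int(hold.size),
    )
    return model, report


def select_components(
    X: SpectraSet | np.ndarray,
    y: np.ndarray,
    split: SplitSpec,
    k_max: int,
    method: str = "pls",
) -> int:
    """Choose the number of latent variables minimising RMSECV.

    Ties (within 1e-12) break toward the smaller k, preferring the more
    parsimonious model.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    wl, M, y = _check_xy(X, y, 1)
    n = y.size
    rng = np.random.default_rng(split.seed)
    hold = np.sort(rng.choice(n, size=split.n_holdout, replace=False))
    cal = np.setdiff1d(np.arange(n), hold)
    Mc, yc = M[cal], y[cal]
    best_k, best = 1, np.inf
    for k in range(1, k_max + 1):
        try:
            val = rmse(_cv_residuals(Mc, yc, method, k, split))
        except ValueError:
            break  # rank exhausted
        if val < best - 1e-12:
            best_k, best = k, val
    return best_k


#: Default RPD bands. The field's customary labels; boundaries are half-open
#: [low, high). Configurable because published band limits disagree.
DEFAULT_RPD_BANDS: tuple[tuple[float, str], ...] = (
    (3.0, "excellent"),
    (2.0, "very reliable"),
    (1.5, "limited"),
    (0.0, "unreliable"),
)


def classify_rpd(rpd: float, bands: tuple[tuple[float, str], ...] = DEFAULT_RPD_BANDS) -> str:
    """Map an RPD value to its qualitative reliability label."""
    if rpd < 0:
        raise ValueError(f"RPD must be non-negative, got {rpd}")
    for lo, label in bands:
        if rpd >= lo:
            return label
    return bands[-1][1]
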