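"""Partial least squares regression (PLS1) with LOOCV, VIP, and band
interval extraction.

The fitting routine is a NIPALS-style sequential extraction for a single
response: each latent variable's weight vector maximizes the covariance
between the X-score and the current response residual.  Predictors are
autoscaled (centred, unit variance) by default, the chemometrics convention
for reflectance matrices whose bands differ widely in variance.  Weight
vectors are sign-normalized (largest-magnitude element positive) so fits are
reproducible across linear-algebra backends.

Model selection follows the cumulative predicted variance Q2cum from
leave-one-out cross-validation: the optimal number of latent variables
(ONLV) is the smallest count whose Q2cum comes within 1% of the curve's
maximum, and a model is flagged acceptable when Q2cum exceeds 0.5.

Wavelength importance combines the variable importance in projection,

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),

whose squared values average to exactly 1, with the per-LV loading weights:
a band is retained when VIP > 1 and its absolute loading weight reaches the
75th percentile on at least one latent variable.  Contiguous retained bands
(gaps up to 5 nm bridged) form the reported sensitive band intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PLSRModel:
    n_lv: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, a) unit-norm weight vectors
    loadings: np.ndarray  # (p, a) X loadings
    y_loadings: np.ndarray  # (a,)
    scores: np.ndarray  # (n, a) training scores
    ssy_per_lv: np.ndarray  # (a,) response SS explained per LV
    r2y_cum: np.ndarray  # (a,)
    r2x_cum: np.ndarray  # (a,)
    kept: np.ndarray  # boolean column mask (constant columns dropped)
    scaled: bool = True

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients on the original predictor scale (p,)."""
        return self.coefficients_at(self.n_lv)

    def coefficients_at(self, n_lv: int) -> np.ndarray:
        W = self.weights[:, :n_lv]
        P = self.loadings[:, :n_lv]
        Q = self.y_loadings[:n_lv]
        b_scaled = W @ np.linalg.solve(P.T @ W, Q)
        beta = np.zeros(self.kept.size)
        beta[self.kept] = b_scaled / self.x_scale
        return beta

    @property
    def intercept(self) -> float:
        beta = self.coefficients[self.kept]
        full_mean = np.zeros(self.kept.size)
        full_mean[self.kept] = self.x_mean
        return float(self.y_mean - full_mean[self.kept] @ beta)

    def predict(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        return self.predict_path(X)[:, (n_lv or self.n_lv) - 1]

    def predict_path(self, X: np.ndarray) -> np.ndarray:
        """Cumulative predictions for every LV count: (n, n_lv)."""
        X = np.asarray(X, dtype=float)[:, self.kept]
        Xd = (X - self.x_mean) / self.x_scale
        n = X.shape[0]
        preds = np.empty((n, self.n_lv))
        yhat = np.full(n, self.y_mean)
        for a in range(self.n_lv):
            t = Xd @ self.weights[:, a]
            Xd = Xd - np.outer(t, self.loadings[:, a])
            yhat = yhat + self.y_loadings[a] * t
            preds[:, a] = yhat
        return preds


def fit_plsr(
    X: np.ndarray, y: np.ndarray, n_lv: int, scale: bool = True
) -> PLSRModel:
    """Fit a PLS1 model with ``n_lv`` latent variables."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p_all = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on sample count")
    sd = X.std(axis=0, ddof=1) if n > 1 else np.zeros(p_all)
    kept = sd > 0
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} constant predictor column(s)",
            stacklevel=2,
        )
    Xk = X[:, kept]
    p = Xk.shape[1]
    max_rank = min(n - 1, p)
    if n_lv < 1 or n_lv > max_rank:
        raise ValueError(f"n_lv must be in [1, {max_rank}]")

    x_mean = Xk.mean(axis=0)
    x_scale = sd[kept] if scale else np.ones(p)
    Xd = (Xk - x_mean) / x_scale
    y_mean = float(y.mean())
    yd = y - y_mean
    ssy_total = float(yd @ yd)
    ssx_total = float((Xd**2).sum())

    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    Q = np.empty(n_lv)
    T = np.empty((n, n_lv))
    ssy_lv = np.empty(n_lv)
    ssx_lv = np.empty(n_lv)
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError(
                f"response residual orthogonal to predictors at LV {a + 1}"
            )
        w /= nw
        # sign convention: largest-magnitude weight positive
        s = np.sign(w[np.argmax(np.abs(w))]) or 1.0
        w *= s
        t = Xd @ w
        tt = float(t @ t)
        pvec = (Xd.T @ t) / tt
        q = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pvec)
        yd = yd - q * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, pvec, q, t
        ssy_lv[a] = q * q * tt
        ssx_lv[a] = tt * float(pvec @ pvec)

    r2y_cum = np.cumsum(ssy_lv) / ssy_total if ssy_total > 0 else np.zeros(n_lv)
    r2x_cum = np.cumsum(ssx_lv) / ssx_total if ssx_total > 0 else np.zeros(n_lv)
    return PLSRModel(
        n_lv=n_lv,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=Q,
        scores=T,
        ssy_per_lv=ssy_lv,
        r2y_cum=r2y_cum,
        r2x_cum=r2x_cum,
        kept=kept,
        scaled=scale,
    )


def vip(model: PLSRModel, n_lv: int | None = None) -> np.ndarray:
    """Variable importance in projection over the first ``n_lv`` LVs.

    mean(VIP^2) = 1 exactly since the weight vectors have unit norm.
    Dropped (constant) columns get VIP 0.
    """
    a = n_lv or model.n_lv
    W = model.weights[:, :a]
    ssy = model.ssy_per_lv[:a]
    p = W.shape[0]
    scores = p * (W**2 @ ssy) / ssy.sum()
    out = np.zeros(model.kept.size)
    out[model.kept] = np.sqrt(scores)
    return out


@dataclass
class CrossValidationCurve:
    q2_cum: np.ndarray  # per LV count 1..max_lv
    press: np.ndarray
    ss_total: float

    @property
    def max_lv(self) -> int:
        return len(self.q2_cum)


@dataclass
class ONLVSelection:
    n_lv: int
    acceptable: bool  # Q2cum at the ONLV exceeds 0.5
    curve: CrossValidationCurve

    @property
    def q2(self) -> float:
        return float(self.curve.q2_cum[self.n_lv - 1])


def loocv_curve(X: np.ndarray, y: np.ndarray, max_lv: int, scale: bool = True) -> CrossValidationCurve:
    """Leave-one-out Q2cum for LV counts 1..max_lv."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    max_lv = min(max_lv, n - 2, X.shape[1])
    press = np.zeros(max_lv)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_plsr(X[mask], y[mask], max_lv, scale=scale)
        preds = model.predict_path(X[i : i + 1])[0]
        press += (y[i] - preds) ** 2
    ss_total = float(((y - y.mean()) ** 2).sum())
    return CrossValidationCurve(q2_cum=1.0 - press / ss_total, press=press, ss_total=ss_total)


def select_onlv(curve: CrossValidationCurve, tolerance: float = 0.01) -> ONLVSelection:
    """Smallest LV count within ``tolerance`` (relative) of the Q2cum maximum."""
    q2 = curve.q2_cum
    if not np.all(np.isfinite(q2)):
        raise ValueError("Q2 curve contains non-finite values")
    qmax = float(q2.max())
    cut = qmax - tolerance * abs(qmax)
    n_lv = int(np.argmax(q2 >= cut)) + 1
    return ONLVSelection(n_lv=n_lv, acceptable=bool(q2[n_lv - 1] > 0.5), curve=curve)


@dataclass
class BandInterval:
    start: int  # nm, inclusive
    end: int  # nm, inclusive
    mean_vip: float
    trait: str = ""
    scope: str = ""


def extract_band_intervals(
    vip_values: np.ndarray,
    loading_weights: np.ndarray,
    wavelengths: np.ndarray,
    vip_threshold: float = 1.0,
    weight_quantile: float = 0.75,
    merge_gap: int = 5,
    trait: str = "",
    scope: str = "",
) -> list[BandInterval]:
    """Sensitive band intervals: VIP above threshold and high loading weight.

    A wavelength passes when its VIP exceeds ``vip_threshold`` and its
    absolute loading weight reaches the ``weight_quantile`` of that LV's
    absolute weights on at least one latent variable.  Contiguous passers
    are merged, bridging gaps of at most ``merge_gap`` nm.
    """
    wavelengths = np.asarray(wavelengths)
    vip_values = np.asarray(vip_values, dtype=float)
    W = np.abs(np.asarray(loading_weights, dtype=float))
    if W.ndim == 1:
        W = W[:, None]
    cuts = np.quantile(W, weight_quantile, axis=0)
    high_weight = (W >= cuts[None, :]).any(axis=1)
    passing = (vip_values > vip_threshold) & high_weight

    intervals: list[BandInterval] = []
    idx = np.flatnonzero(passing)
    if idx.size == 0:
        return intervals
    start = prev = idx[0]
    members = [idx[0]]
    for k in idx[1:]:
        if wavelengths[k] - wavelengths[prev] <= merge_gap:
            members.append(k)
            prev = k
        else:
            intervals.append(
                BandInterval(
                    start=int(wavelengths[start]),
                    end=int(wavelengths[prev]),
                    mean_vip=float(vip_values[members].mean()),
                    trait=trait,
                    scope=scope,
                )
            )
            start = prev = k
            members = [k]
    intervals.append(
        BandInterval(
            start=int(wavelengths[start]),
            end=int(wavelengths[prev]),
            mean_vip=float(vip_values[members].mean()),
            trait=trait,
            scope=scope,
        )
    )
    return intervals


@dataclass
class EvaluationMetrics:
    r2: float
    rmse: float
    re_pct: float
    n: int


def evaluate_predictions(observed: np.ndarray, predicted: np.ndarray) -> EvaluationMetrics:
    """R2 (squared Pearson), RMSE, and relative error vs the observed mean."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    resid = observed - predicted
    rmse = float(np.sqrt(np.mean(resid**2)))
    obs_mean = float(observed.mean())
    oc = observed - obs_mean
    pc = predicted - predicted.mean()
    denom = np.sqrt(float(oc @ oc) * float(pc @ pc))
    r2 = float((oc @ pc) / denom) ** 2 if denom > 0 else np.nan
    re = 100.0 * rmse / obs_mean if obs_mean != 0 else np.nan
    return EvaluationMetrics(r2=r2, rmse=rmse, re_pct=re, n=len(observed))


@dataclass
class CalibrationValidation:
    model: PLSRModel
    onlv: ONLVSelection
    calibration: EvaluationMetrics
    validation: EvaluationMetrics
    train_idx: np.ndarray = field(repr=False, default=None)
    test_idx: np.ndarray = field(repr=False, default=None)


def calibrate_validate(
    X: np.ndarray,
    y: np.ndarray,
    validation_fraction: float = 0.25,
    seed: int = 0,
    max_lv: int = 10,
    scale: bool = True,
) -> CalibrationValidation:
    """Random calibration/validation split with LOOCV-chosen ONLV.

    The split is drawn from ``seed``; the ONLV is selected by LOOCV on the
    calibration set only, and both sets are scored with R2, RMSE, and the
    relative error RE = 100 * RMSE / mean(observed in that set).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    n_val = int(round(validation_fraction * n))
    if n_val < 1 or n - n_val < 3:
        raise ValueError("both calibration and validation sets must be usable")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_val])
    train_idx = np.sort(perm[n_val:])
    curve = loocv_curve(X[train_idx], y[train_idx], max_lv, scale=scale)
    sel = select_onlv(curve)
    model = fit_plsr(X[train_idx], y[train_idx], sel.n_lv, scale=scale)
    cal = evaluate_predictions(y[train_idx], model.predict(X[train_idx]))
    val = evaluate_predictions(y[test_idx], model.predict(X[test_idx]))
    return CalibrationValidation(
        model=model, onlv=sel, calibration=cal, validation=val,
        train_idx=train_idx, test_idx=test_idx,
    )


@dataclass
class FeatureModelResult:
    model: PLSRModel
    onlv: ONLVSelection
    metrics: EvaluationMetrics
    observed: np.ndarray
    predicted: np.ndarray


def plsr_on_features(
    features: np.ndarray, y: np.ndarray, max_lv: int = 10, scale: bool = True
) -> FeatureModelResult:
    """PLSR on a reduced feature set (selected wavelengths or an SRI table)."""
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    max_lv = min(max_lv, features.shape[1], len(y) - 2)
    curve = loocv_curve(features, y, max_lv, scale=scale)
    sel = select_onlv(curve)
    model = fit_plsr(features, y, sel.n_lv, scale=scale)
    predicted = model.predict(features)
    return FeatureModelResult(
        model=model,
        onlv=sel,
        metrics=evaluate_predictions(y, predicted),
        observed=y,
        predicted=predicted,
    )
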