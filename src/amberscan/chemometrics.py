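"""NIR -> cannabinoid regression: preprocessing, splitting, PLS, and metrics.

The modeling recipe is the standard handheld-NIR chemometrics stack:

* per-spectrum preprocessing — polynomial detrend, Savitzky-Golay derivative,
  standard normal variate (SNV) — followed by mean centering fitted on
  calibration rows only;
* a deterministic Kennard-Stone 75/25 calibration/validation split;
* single-response partial least squares regression (NIPALS, via
  scikit-learn's ``PLSRegression``) with a fixed latent-variable count;
* venetian-blinds cross-validation (10 interleaved splits, thickness 1);
* the RMSEC / RMSECV / RMSEP, R² triplet, prediction bias and RPD metric
  suite, plus y-shuffling permutation tests (empirical p together with
  Wilcoxon, sign and randomization-t paired tests on residuals).

Preprocessing steps other than centering are strictly per-spectrum, so only
the centering means can leak information across samples; they are refit
inside every cross-validation fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin, clone
from sklearn.cross_decomposition import PLSRegression

DEFAULT_WAVELENGTHS = np.linspace(950.0, 1650.0, 128)


@dataclass
class SpectraMatrix:
    """n samples x p channels of NIR reflectance/absorbance values."""

    values: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"expected 2-D spectra matrix, got shape {self.values.shape}")
        if self.values.shape[1] != self.wavelengths.shape[0]:
            raise ValueError("channel count does not match wavelength grid")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain non-finite values")


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectraMatrix):
        return X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected 2-D spectra matrix, got shape {X.shape}")
    return X


# ---------------------------------------------------------------------------
# Preprocessing transformers (sklearn-compatible)
# ---------------------------------------------------------------------------


class Detrend(TransformerMixin, BaseEstimator):
    """Subtract a per-spectrum least-squares polynomial trend in wavelength."""

    def __init__(self, order: int = 1):
        self.order = order

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = _as_matrix(X)
        p = X.shape[1]
        if self.order < 0 or self.order >= p:
            raise ValueError(f"detrend order must satisfy 0 <= order < {p}, got {self.order}")
        t = np.linspace(-1.0, 1.0, p)
        basis = np.vander(t, self.order + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(basis, X.T, rcond=None)
        return X - (basis @ coef).T


class SavGolDerivative(TransformerMixin, BaseEstimator):
    """Savitzky-Golay smoothing derivative per spectrum.

    The toolbox shorthand "2, 2, 5" reads polynomial order 2, derivative
    order 2, 5-point window.  Ends are handled by polynomial interpolation
    (a least-squares fit to the terminal window evaluated at the end
    positions), so the derivative is exact for polynomials up to ``poly``
    over the whole spectrum.  An even window is widened to the next odd size
    (and to at least ``poly + 1``) with a note.
    """

    def __init__(self, poly: int = 2, deriv: int = 2, window: int = 5):
        self.poly = poly
        self.deriv = deriv
        self.window = window

    def _effective_window(self) -> int:
        w = int(self.window)
        if w % 2 == 0:
            w += 1
        while w < self.poly + 1:
            w += 2
        if w != self.window:
            import warnings

            warnings.warn(f"savgol window widened from {self.window} to {w}")
        return w

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = _as_matrix(X)
        if self.deriv > self.poly:
            raise ValueError(f"derivative order {self.deriv} exceeds polynomial order {self.poly}")
        w = self._effective_window()
        return signal.savgol_filter(X, window_length=w, polyorder=self.poly,
                                    deriv=self.deriv, delta=1.0, axis=1, mode="interp")


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: standardize each spectrum to mean 0, sd 1."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = _as_matrix(X)
        sd = X.std(axis=1, ddof=1)
        bad = np.nonzero(sd == 0)[0]
        if bad.size:
            raise ValueError(f"SNV undefined for zero-variance spectra at rows {bad.tolist()}")
        return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


class MeanCenter(TransformerMixin, BaseEstimator):
    """Column mean centering fitted on calibration rows only (no leakage)."""

    def fit(self, X, y=None):
        X = _as_matrix(X)
        self.means_ = X.mean(axis=0)
        return self

    def transform(self, X):
        X = _as_matrix(X)
        if not hasattr(self, "means_"):
            raise RuntimeError("MeanCenter is not fitted")
        if X.shape[1] != self.means_.shape[0]:
            raise ValueError("dimension mismatch with fitted means")
        return X - self.means_


#: Default preprocessing: detrend -> 2nd-derivative SavGol -> SNV -> centering.
DEFAULT_PREPROCESS = "detrend:1,savgol:2:2:5,snv,mc"


def parse_preprocess(spec: str) -> list[tuple[str, BaseEstimator]]:
    """Parse a compact step string like ``"detrend:1,savgol:2:2:5,snv,mc"``.

    ``mc`` (mean centering), if present, must be the final step.
    """
    steps: list[tuple[str, BaseEstimator]] = []
    parts = [p.strip() for p in spec.split(",") if p.strip()]
    for i, part in enumerate(parts):
        name, *args = part.split(":")
        if name == "detrend":
            steps.append(("detrend", Detrend(order=int(args[0]) if args else 1)))
        elif name == "savgol":
            poly, deriv, window = (int(a) for a in args) if args else (2, 2, 5)
            steps.append(("savgol", SavGolDerivative(poly=poly, deriv=deriv, window=window)))
        elif name == "snv":
            steps.append(("snv", SNV()))
        elif name in ("mc", "mean_center"):
            if i != len(parts) - 1:
                raise ValueError("mean centering must be the final preprocessing step")
            steps.append(("mc", MeanCenter()))
        else:
            raise ValueError(f"unknown preprocessing step {name!r}")
    return steps


def apply_rowwise(steps, X) -> np.ndarray:
    """Apply only the per-spectrum (stateless) steps — used e.g. before
    Kennard-Stone selection, where pooled statistics must not enter."""
    X = _as_matrix(X)
    for name, step in steps:
        if name != "mc":
            X = step.transform(X)
    return X


# ---------------------------------------------------------------------------
# Sample selection and cross-validation plans
# ---------------------------------------------------------------------------


def kennard_stone(X, n_cal: int) -> tuple[np.ndarray, np.ndarray]:
    """Kennard-Stone max-min calibration subset selection.

    Starts from the two mutually most distant samples, then repeatedly adds
    the candidate whose minimum Euclidean distance to the selected set is
    largest.  Fully deterministic; distance ties break to the lowest index.
    Returns (calibration_indices, validation_indices), both sorted.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    if not 2 <= n_cal < n:
        raise ValueError(f"n_cal must satisfy 2 <= n_cal < {n}, got {n_cal}")
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    # farthest pair, lowest indices on ties
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(n) if k not in selected]
    min_d = np.minimum(d2[remaining, selected[0]], d2[remaining, selected[1]])
    while len(selected) < n_cal:
        pick = int(np.argmax(min_d))  # argmax takes the first (lowest index) on ties
        selected.append(remaining[pick])
        last = remaining[pick]
        del remaining[pick]
        min_d = np.delete(min_d, pick)
        min_d = np.minimum(min_d, d2[remaining, last])
    cal = np.sort(np.array(selected))
    val = np.sort(np.array([k for k in range(n) if k not in set(selected)]))
    return cal, val


@dataclass
class SplitPlan:
    calibration: np.ndarray
    validation: np.ndarray
    method: str = "kennard-stone"


def make_split(X, cal_fraction: float = 0.75, preprocess: str = DEFAULT_PREPROCESS) -> SplitPlan:
    """75/25 Kennard-Stone split on per-spectrum-preprocessed spectra.

    Selection runs on the row-wise preprocessed spectra (centering excluded —
    it would require pooled statistics before the split exists).
    """
    X = _as_matrix(X)
    n_cal = int(round(cal_fraction * X.shape[0]))
    Xp = apply_rowwise(parse_preprocess(preprocess), X)
    cal, val = kennard_stone(Xp, n_cal)
    return SplitPlan(calibration=cal, validation=val)


def venetian_blinds(n: int, splits: int = 10, thickness: int = 1):
    """Interleaved cross-validation folds: sample i -> fold (i // thickness) % splits.

    Returns a list of (train_indices, test_indices) pairs, one per fold.
    """
    if splits < 2:
        raise ValueError(f"splits must be >= 2, got {splits}")
    if n < splits:
        raise ValueError(f"need at least {splits} samples, got {n}")
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    idx = np.arange(n)
    fold_of = (idx // thickness) % splits
    plan = []
    for f in range(splits):
        test = idx[fold_of == f]
        train = idx[fold_of != f]
        if train.size < 2:
            raise ValueError(f"fold {f}: fewer than 2 training samples")
        plan.append((train, test))
    return plan


# ---------------------------------------------------------------------------
# PLS model
# ---------------------------------------------------------------------------


class NIRPLSRegressor(RegressorMixin, BaseEstimator):
    """Single-response PLS regression over a preprocessing chain.

    Per-spectrum steps are stateless; the centering means (X columns and y)
    are fitted on the training rows only.  The underlying factorization is
    scikit-learn's NIPALS ``PLSRegression`` with scaling disabled, so the
    model is fully deterministic.

    Attributes (after fit): ``coef_`` (p-vector), ``x_mean_``, ``y_mean_``,
    ``n_lv_``.  Prediction is ``(x_preprocessed - x_mean_) @ coef_ + y_mean_``.
    """

    def __init__(self, n_lv: int = 6, preprocess: str = DEFAULT_PREPROCESS):
        self.n_lv = n_lv
        self.preprocess = preprocess

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different sample counts")
        if np.std(y) == 0:
            raise ValueError("no variance to model: y is constant")
        n, p = X.shape
        if not 1 <= self.n_lv <= min(n - 1, p):
            raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}], got {self.n_lv}")
        self._steps = parse_preprocess(self.preprocess)
        Xp = apply_rowwise(self._steps, X)
        self.x_mean_ = Xp.mean(axis=0)
        self.y_mean_ = float(y.mean())
        self._pls = PLSRegression(n_components=self.n_lv, scale=False)
        self._pls.fit(Xp - self.x_mean_, y - self.y_mean_)
        self.coef_ = self._pls.coef_.reshape(-1)
        self.n_lv_ = self.n_lv
        return self

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        Xp = apply_rowwise(self._steps, _as_matrix(X))
        return (Xp - self.x_mean_) @ self.coef_ + self.y_mean_


# ---------------------------------------------------------------------------
# Metric suite
# ---------------------------------------------------------------------------


@dataclass
class ModelMetrics:
    rmsec: float | None = None
    r2_cal: float | None = None
    rmsecv: float | None = None
    r2_cv: float | None = None
    rmsep: float | None = None
    pred_bias: float | None = None
    r2_pred: float | None = None      # squared Pearson r, measured vs predicted
    r2_pred_sse: float | None = None  # 1 - SSE/SST alternative
    rpd: float | None = None


def _rmse(y, yhat) -> float:
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def _r2_sse(y, yhat) -> float:
    y = np.asarray(y, float)
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((np.asarray(yhat, float) - y) ** 2).sum())
    return 1.0 - sse / sst if sst > 0 else float("nan")


def cross_validate(model: NIRPLSRegressor, X, y, cv_plan=None) -> tuple[float, float]:
    """RMSECV and R²_CV with the whole chain refit inside each fold.

    ``cv_plan`` defaults to venetian blinds with 10 splits, thickness 1.
    Held-out predictions are concatenated before computing the error.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).reshape(-1)
    if cv_plan is None:
        cv_plan = venetian_blinds(X.shape[0])
    pred = np.full_like(y, np.nan)
    for train, test in cv_plan:
        if test.size < 1:
            raise ValueError("empty test fold")
        m = clone(model).fit(X[train], y[train])
        pred[test] = m.predict(X[test])
    if np.isnan(pred).any():
        raise ValueError("cv_plan does not cover all samples")
    return _rmse(y, pred), _r2_sse(y, pred)


def evaluate(model: NIRPLSRegressor, X_val, y_val) -> ModelMetrics:
    """Validation metrics: RMSEP, prediction bias, R² (Pearson² and SSE), RPD.

    RPD is the standard deviation (n-1 denominator) of the validation
    reference values divided by RMSEP; perfect predictions yield RPD = inf.
    """
    y_val = np.asarray(y_val, dtype=float).reshape(-1)
    if y_val.size == 0:
        raise ValueError("empty validation set")
    sd = float(y_val.std(ddof=1)) if y_val.size > 1 else 0.0
    if sd == 0:
        raise ValueError("validation y has zero variance: RPD undefined")
    pred = model.predict(X_val)
    rmsep = _rmse(y_val, pred)
    r = np.corrcoef(y_val, pred)[0, 1] if np.std(pred) > 0 else np.nan
    return ModelMetrics(
        rmsep=rmsep,
        pred_bias=float(np.mean(pred - y_val)),
        r2_pred=float(r**2) if np.isfinite(r) else float("nan"),
        r2_pred_sse=_r2_sse(y_val, pred),
        rpd=sd / rmsep if rmsep > 0 else float("inf"),
    )


def fit_and_evaluate(
    X,
    y,
    n_lv: int = 6,
    preprocess: str = DEFAULT_PREPROCESS,
    split: SplitPlan | None = None,
    cv_splits: int = 10,
    cv_thickness: int = 1,
) -> tuple[NIRPLSRegressor, ModelMetrics, SplitPlan]:
    """Full modeling recipe for one analyte: split, fit, CV, validate."""
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).reshape(-1)
    if split is None:
        split = make_split(X, preprocess=preprocess)
    cal, val = split.calibration, split.validation
    model = NIRPLSRegressor(n_lv=n_lv, preprocess=preprocess).fit(X[cal], y[cal])
    pred_cal = model.predict(X[cal])
    rmsecv, r2_cv = cross_validate(
        model, X[cal], y[cal], venetian_blinds(cal.size, cv_splits, cv_thickness)
    )
    metrics = evaluate(model, X[val], y[val])
    metrics.rmsec = _rmse(y[cal], pred_cal)
    metrics.r2_cal = _r2_sse(y[cal], pred_cal)
    metrics.rmsecv = rmsecv
    metrics.r2_cv = r2_cv
    return model, metrics, split


# ---------------------------------------------------------------------------
# Permutation testing
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    n_perm: int
    actual_rmsecv: float
    permuted_rmsecv: np.ndarray
    p_empirical: float
    p_wilcoxon: float
    p_sign: float
    p_rand_t: float


def permutation_test(
    X,
    y,
    n_lv: int = 6,
    preprocess: str = DEFAULT_PREPROCESS,
    n_perm: int = 200,
    seed: int | None = None,
    cv_splits: int = 10,
    cv_thickness: int = 1,
) -> PermutationResult:
    """y-shuffling permutation test of a cross-validated PLS model.

    The response is shuffled ``n_perm`` times and the cross-validated error
    recomputed for each shuffle.  Reported are (a) the empirical p-value
    ``(1 + #{permuted RMSECV <= actual}) / (n_perm + 1)`` and (b) paired
    Wilcoxon signed-rank, sign and randomization-t tests comparing each
    sample's actual absolute CV residual against its mean absolute residual
    across the permuted models (alternative: permuted residuals are larger).
    The seed is mandatory for reproducibility.
    """
    if seed is None:
        raise ValueError("seed is mandatory for permutation_test")
    if n_perm < 20:
        raise ValueError(f"n_perm must be >= 20, got {n_perm}")
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).reshape(-1)
    rng = np.random.default_rng(seed)
    cv_plan = venetian_blinds(X.shape[0], cv_splits, cv_thickness)
    model = NIRPLSRegressor(n_lv=n_lv, preprocess=preprocess)

    def cv_pred(yy):
        pred = np.empty_like(yy)
        for train, test in cv_plan:
            m = clone(model).fit(X[train], yy[train])
            pred[test] = m.predict(X[test])
        return pred

    actual_pred = cv_pred(y)
    actual_rmsecv = _rmse(y, actual_pred)
    actual_abs = np.abs(actual_pred - y)

    permuted_rmsecv = np.empty(n_perm)
    perm_abs_sum = np.zeros_like(y)
    for k in range(n_perm):
        yp = rng.permutation(y)
        pp = cv_pred(yp)
        permuted_rmsecv[k] = _rmse(yp, pp)
        perm_abs_sum += np.abs(pp - yp)
    perm_abs_mean = perm_abs_sum / n_perm

    p_emp = (1 + int((permuted_rmsecv <= actual_rmsecv).sum())) / (n_perm + 1)

    diff = perm_abs_mean - actual_abs
    if np.allclose(diff, 0):
        p_wil, p_sign, p_rt = 1.0, 1.0, 1.0
    else:
        p_wil = float(stats.wilcoxon(diff, alternative="greater").pvalue)
        nz = diff != 0
        p_sign = float(
            stats.binomtest(int((diff[nz] > 0).sum()), int(nz.sum()), 0.5, alternative="greater").pvalue
        )
        rt = stats.permutation_test(
            (perm_abs_mean, actual_abs),
            lambda a, b: np.mean(a - b),
            permutation_type="samples",
            alternative="greater",
            n_resamples=2000,
            rng=np.random.default_rng(seed + 1),
        )
        p_rt = float(rt.pvalue)

    return PermutationResult(
        n_perm=n_perm,
        actual_rmsecv=actual_rmsecv,
        permuted_rmsecv=permuted_rmsecv,
        p_empirical=p_emp,
        p_wilcoxon=min(max(p_wil, 1e-300), 1.0),
        p_sign=min(max(p_sign, 1e-300), 1.0),
        p_rand_t=min(max(p_rt, 1e-300), 1.0),
    )
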