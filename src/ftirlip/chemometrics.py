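"""Multivariate calibration: PCA of the fatty-acid region and PLS
regression of fatty-acid reference values on preprocessed spectra.

The modelling interface follows the statsmodels convention: a
:class:`PLSCalibration` model object is built from data, its
:meth:`~PLSCalibration.fit` / :meth:`~PLSCalibration.fit_with_cv` methods
return a :class:`PLSCalibrationResults` object carrying the regression
vector, the RMSECV curve, R-squared and a ``summary()`` table.

The PLS algorithm is univariate-response PLS1 by NIPALS: per factor, the
weight vector is the covariance direction between centred X and y, scores
and loadings are extracted and both blocks deflated; the regression vector
is assembled as ``W (P'W)^-1 q``.  With as many factors as the centred-X
rank it reproduces ordinary least squares.  "Full cross-validation" is
leave-one-out over calibration samples; RMSECV(f) is the root mean squared
error of the held-out predictions at f factors, and R-squared the squared
Pearson correlation between held-out predictions and the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import SpectraSet

logger = logging.getLogger(__name__)

FATTY_ACID_TARGETS = ("SAT", "MUFA", "PUFA")
FATTY_ACID_REGION = (3200.0, 2800.0)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Mean-centred PCA of a spectral region.

    ``scores`` is (n_samples, n_components), ``loadings`` is
    (n_wavenumbers, n_components) with orthonormal columns;
    ``explained_variance_ratio`` sums to at most 1.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    wavenumbers: np.ndarray
    region: tuple[float, float]
    sample_ids: list[str]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        df = pd.DataFrame(self.scores, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def pca_region(spectra: SpectraSet,
               region: tuple[float, float] = FATTY_ACID_REGION,
               n_components: int = 2) -> PCAResult:
    """PCA by SVD of the mean-centred region sub-matrix.

    The sign of each component is fixed so that its largest-magnitude
    loading element is positive, making the decomposition deterministic.
    """
    if len(spectra) < 2:
        raise ValueError("PCA needs at least 2 samples")
    sub = spectra.restrict(*region)
    X = sub.absorbance
    n_max = min(X.shape[0] - 1, X.shape[1])
    if n_components > n_max:
        raise ValueError(f"n_components {n_components} exceeds limit {n_max}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    signs = np.sign(Vt[np.arange(Vt.shape[0]),
                       np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    var = s ** 2 / max(X.shape[0] - 1, 1)
    ratio = var / Xc.var(axis=0, ddof=1).sum() if Xc.any() else var * 0
    return PCAResult(
        scores=(U * s)[:, :n_components],
        loadings=Vt[:n_components].T,
        explained_variance_ratio=ratio[:n_components],
        mean=mean, wavenumbers=sub.wavenumbers, region=region,
        sample_ids=sub.ids)


# ---------------------------------------------------------------------------
# PLS1 core
# ---------------------------------------------------------------------------

def _pls1_components(Xc: np.ndarray, yc: np.ndarray, n_factors: int):
    """NIPALS extraction of up to ``n_factors`` PLS1 components.

    Returns (W, P, q, k) where k <= n_factors components were extracted
    (extraction stops early once y is exhausted, i.e. the weight norm
    underflows).
    """
    n, p = Xc.shape
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    X = Xc.copy()
    y = yc.copy()
    scale = max(np.linalg.norm(Xc) * np.linalg.norm(yc), 1.0)
    for k in range(n_factors):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * scale:
            return W[:, :k], P[:, :k], q[:k], k
        w /= nw
        t = X @ w
        tt = t @ t
        if tt <= 0:
            return W[:, :k], P[:, :k], q[:k], k
        pl = X.T @ t / tt
        qk = (y @ t) / tt
        X = X - np.outer(t, pl)
        y = y - qk * t
        W[:, k], P[:, k], q[k] = w, pl, qk
    return W, P, q, n_factors


def _pls1_coef_path(W: np.ndarray, P: np.ndarray, q: np.ndarray
                    ) -> np.ndarray:
    """Regression vectors B(:, f) for every factor count f = 1..k."""
    k = W.shape[1]
    coefs = np.zeros((W.shape[0], k))
    R = np.linalg.solve(P.T @ W, np.eye(k))  # (P'W)^-1 (upper triangular)
    WR = W @ R
    for f in range(k):
        coefs[:, f] = WR[:, :f + 1] @ q[:f + 1]
    return coefs


def pls1_prediction_path(X_train: np.ndarray, y_train: np.ndarray,
                         X_test: np.ndarray, max_factors: int) -> np.ndarray:
    """Held-out predictions at 1..max_factors factors.

    If extraction stops early (y exhausted), the last available model is
    carried forward to the remaining factor counts.
    """
    xm = X_train.mean(axis=0)
    ym = y_train.mean()
    W, P, q, k = _pls1_components(X_train - xm, y_train - ym, max_factors)
    out = np.full((X_test.shape[0], max_factors), ym)
    if k == 0:
        return out
    coefs = _pls1_coef_path(W, P, q)
    pred = ym + (X_test - xm) @ coefs
    out[:, :k] = pred
    if k < max_factors:
        out[:, k:] = pred[:, [k - 1]]
    return out


# ---------------------------------------------------------------------------
# Factor selection
# ---------------------------------------------------------------------------

def select_n_factors(rmsecv_curve: np.ndarray, rule: str = "margin",
                     margin: float = 0.02, alpha: float = 0.05,
                     n_samples: int | None = None) -> int:
    """Pick the factor count from an RMSECV curve.

    ``margin`` (default): the smallest f whose RMSECV is within
    ``(1 + margin)`` of the curve minimum — the parsimonious model whose
    error is not meaningfully above the best.  ``f-test``: Haaland-Thomas
    style ratio test of squared CV residual sums against the minimum;
    the smallest f whose PRESS ratio is not significant at ``alpha``
    (requires ``n_samples``).
    """
    curve = np.asarray(rmsecv_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty RMSECV curve")
    if rule == "margin":
        cut = (1.0 + margin) * curve.min()
        return int(np.nonzero(curve <= cut)[0][0]) + 1
    if rule == "f-test":
        if n_samples is None:
            raise ValueError("f-test rule needs n_samples")
        best = int(np.argmin(curve))
        press = curve ** 2 * n_samples
        ratio = press / press[best]
        fcrit = stats.f.ppf(1.0 - alpha, n_samples, n_samples)
        ok = ratio < fcrit
        return int(np.nonzero(ok)[0][0]) + 1
    raise ValueError(f"unknown selection rule {rule!r}")


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PLSCalibration:
    """PLS1 calibration model of one fatty-acid parameter on spectra.

    Parameters
    ----------
    X : (n_samples, n_variables) array
        Preprocessed spectral matrix (typically EMSC-corrected second
        derivatives on the 3050-700 cm^-1 region).
    y : (n_samples,) array
        Reference values (% of total fatty acids) from GC.
    target : str
        Name of the response (SAT, MUFA or PUFA).
    sample_ids : list of str, optional
    provenance : dict, optional
        Preprocessing provenance (grid, Savitzky-Golay settings, EMSC
        region/order) stored with the fit so that prediction-time spectra
        can be checked against it.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, target: str = "y",
                 sample_ids: list[str] | None = None,
                 provenance: dict | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X and y are misaligned")
        if np.ptp(y) == 0:
            raise ValueError("zero-variance response y")
        self.X = X
        self.y = y
        self.target = target
        self.sample_ids = (list(sample_ids) if sample_ids is not None
                           else [f"s{i}" for i in range(y.size)])
        self.provenance = dict(provenance or {})

    @classmethod
    def from_spectra(cls, spectra: SpectraSet, reference: pd.DataFrame,
                     target: str, provenance: dict | None = None
                     ) -> "PLSCalibration":
        """Align a preprocessed SpectraSet with a reference table by
        sample_id and build the model for one target column."""
        if target not in reference.columns:
            raise ValueError(f"reference table lacks column {target!r}")
        meta_ids = [str(m) for m in spectra.metadata.get(
            "sample_id", pd.Series(spectra.ids))]
        ref = reference.copy()
        ref["sample_id"] = ref["sample_id"].astype(str)
        lookup = ref.set_index("sample_id")[target]
        missing = [i for i in meta_ids if i not in lookup.index]
        if missing:
            raise ValueError(
                f"reference values missing for samples {missing[:5]}"
                + ("..." if len(missing) > 5 else ""))
        y = lookup.loc[meta_ids].to_numpy(float)
        return cls(spectra.absorbance, y, target=target,
                   sample_ids=meta_ids, provenance=provenance)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X - self.X.mean(axis=0)))

    def fit(self, n_factors: int) -> "PLSCalibrationResults":
        """Final PLS1 fit on all samples at a fixed factor count."""
        n = self.y.size
        if n < n_factors + 1:
            raise ValueError(f"n_factors={n_factors} needs at least "
                             f"{n_factors + 1} samples, have {n}")
        xm = self.X.mean(axis=0)
        ym = self.y.mean()
        W, P, q, k = _pls1_components(self.X - xm, self.y - ym, n_factors)
        if k < n_factors:
            raise ValueError(
                f"requested {n_factors} factors but X supports only {k}")
        coef = _pls1_coef_path(W, P, q)[:, n_factors - 1]
        fitted = ym + (self.X - xm) @ coef
        return PLSCalibrationResults(
            model=self, target=self.target, n_samples=n,
            provenance=dict(self.provenance),
            n_factors=n_factors, coef=coef, x_mean=xm,
            y_mean=ym, weights=W, x_loadings=P, y_loadings=q,
            fitted_values=fitted)

    def cross_validate(self, max_factors: int, cv: str = "loo",
                       groups=None):
        """Leave-one-out (or leave-group-out) cross-validation.

        Returns ``(rmsecv_curve, r_squared_curve, cv_predictions)`` with
        one entry per factor count 1..max_factors.
        """
        n = self.y.size
        if n < 3:
            raise ValueError("cross-validation needs at least 3 samples")
        if max_factors > n - 2:
            raise ValueError(f"max_factors={max_factors} exceeds "
                             f"n_samples - 2 = {n - 2}")
        if cv == "loo":
            folds = [[i] for i in range(n)]
        elif cv == "group":
            if groups is None:
                raise ValueError("cv='group' needs groups")
            groups = np.asarray(groups)
            folds = [list(np.nonzero(groups == g)[0])
                     for g in pd.unique(groups)]
        else:
            raise ValueError(f"unknown cv mode {cv!r}")
        preds = np.zeros((n, max_factors))
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            preds[fold] = pls1_prediction_path(
                self.X[mask], self.y[mask], self.X[fold], max_factors)
        resid = preds - self.y[:, None]
        rmsecv = np.sqrt(np.mean(resid ** 2, axis=0))
        # R^2 is the squared Pearson correlation of held-out predictions
        # vs reference.  A negative correlation is reported as 0: under
        # leave-one-out, a no-signal model predicts the training-fold mean
        # (n*ybar - y_i)/(n-1), which anti-correlates with y_i, and the
        # square alone would dress that artifact up as predictive skill.
        r = np.array([
            stats.pearsonr(preds[:, f], self.y)[0]
            if np.ptp(preds[:, f]) > 0 else 0.0
            for f in range(max_factors)])
        r2 = np.where(r > 0, r ** 2, 0.0)
        return rmsecv, r2, preds

    def fit_with_cv(self, max_factors: int = 15, cv: str = "loo",
                    groups=None, rule: str = "margin", margin: float = 0.02,
                    alpha: float = 0.05) -> "PLSCalibrationResults":
        """Cross-validate, select the factor count, refit on all samples."""
        max_factors = min(max_factors, self.y.size - 2, self.rank)
        rmsecv, r2, preds = self.cross_validate(max_factors, cv=cv,
                                                groups=groups)
        nf = select_n_factors(rmsecv, rule=rule, margin=margin, alpha=alpha,
                              n_samples=self.y.size)
        res = self.fit(nf)
        res.rmsecv_curve = rmsecv
        res.r_squared_curve = r2
        res.cv_predictions = preds[:, nf - 1]
        res.selection_rule = rule
        res.cv_mode = cv
        return res


@dataclass
class PLSCalibrationResults:
    """Fitted PLS1 calibration with cross-validation diagnostics."""

    model: PLSCalibration | None = field(default=None, repr=False)
    target: str = ""
    n_samples: int = 0
    provenance: dict = field(default_factory=dict)
    n_factors: int = 0
    coef: np.ndarray = field(default=None, repr=False)
    x_mean: np.ndarray = field(default=None, repr=False)
    y_mean: float = 0.0
    weights: np.ndarray = field(default=None, repr=False)
    x_loadings: np.ndarray = field(default=None, repr=False)
    y_loadings: np.ndarray = field(default=None, repr=False)
    fitted_values: np.ndarray = field(default=None, repr=False)
    rmsecv_curve: np.ndarray = field(default=None, repr=False)
    r_squared_curve: np.ndarray = field(default=None, repr=False)
    cv_predictions: np.ndarray = field(default=None, repr=False)
    selection_rule: str = ""
    cv_mode: str = ""

    @property
    def rmsecv(self) -> float:
        """RMSECV at the chosen factor count (% of total fat)."""
        if self.rmsecv_curve is None:
            return float("nan")
        return float(self.rmsecv_curve[self.n_factors - 1])

    @property
    def r_squared(self) -> float:
        """Squared Pearson correlation of CV predictions vs reference."""
        if self.r_squared_curve is None:
            return float("nan")
        return float(self.r_squared_curve[self.n_factors - 1])

    def predict(self, X_new, provenance: dict | None = None) -> np.ndarray:
        """Predict the response for new, identically preprocessed spectra.

        ``X_new`` may be a SpectraSet or a bare matrix.  When the model
        carries preprocessing provenance, a mismatching ``provenance``
        (or a SpectraSet on a different grid) is refused, naming the
        differing setting.
        """
        stored = self.provenance
        if isinstance(X_new, SpectraSet):
            if stored.get("n_variables") not in (None,
                                                 X_new.wavenumbers.size):
                raise ValueError(
                    "grid mismatch: model was calibrated on "
                    f"{stored['n_variables']} points, got "
                    f"{X_new.wavenumbers.size}")
            X = X_new.absorbance
        else:
            X = np.asarray(X_new, dtype=float)
        if provenance is not None and stored:
            for key, val in stored.items():
                if key in provenance and provenance[key] != val:
                    raise ValueError(
                        f"preprocessing provenance mismatch for {key!r}: "
                        f"model has {val!r}, new data has "
                        f"{provenance[key]!r}")
        if X.shape[1] != self.coef.size:
            raise ValueError(
                f"grid mismatch: model has {self.coef.size} variables, "
                f"X_new has {X.shape[1]}")
        return self.y_mean + (X - self.x_mean) @ self.coef

    def summary(self) -> str:
        lines = [
            f"PLS1 calibration: {self.target}",
            "=" * 40,
            f"samples:            {self.n_samples}",
            f"variables:          {self.coef.size}",
            f"factors:            {self.n_factors}"
            + (f"  (rule: {self.selection_rule})" if self.selection_rule
               else ""),
            f"cross-validation:   {self.cv_mode or 'none'}",
            f"RMSECV:             {self.rmsecv:.3f} % of total fat",
            f"R^2 (CV):           {self.r_squared:.3f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Model serialization (self-describing portable JSON)
# ---------------------------------------------------------------------------

def save_calibration(results: PLSCalibrationResults, path) -> None:
    """Serialize a fitted calibration to JSON (vectors as plain lists)."""
    import json

    payload = {
        "format": "ftirlip-pls1-calibration",
        "version": 1,
        "target": results.target,
        "n_samples": results.n_samples,
        "n_factors": results.n_factors,
        "coef": results.coef.tolist(),
        "x_mean": results.x_mean.tolist(),
        "y_mean": results.y_mean,
        "provenance": results.provenance,
        "selection_rule": results.selection_rule,
        "cv_mode": results.cv_mode,
        "rmsecv_curve": (results.rmsecv_curve.tolist()
                         if results.rmsecv_curve is not None else None),
        "r_squared_curve": (results.r_squared_curve.tolist()
                            if results.r_squared_curve is not None else None),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_calibration(path) -> PLSCalibrationResults:
    """Load a calibration saved by :func:`save_calibration`."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "ftirlip-pls1-calibration":
        raise ValueError(f"{path} is not a serialized calibration model")
    res = PLSCalibrationResults(
        model=None, target=payload["target"],
        n_samples=payload["n_samples"],
        provenance=payload.get("provenance") or {},
        n_factors=payload["n_factors"],
        coef=np.asarray(payload["coef"], dtype=float),
        x_mean=np.asarray(payload["x_mean"], dtype=float),
        y_mean=float(payload["y_mean"]),
        selection_rule=payload.get("selection_rule", ""),
        cv_mode=payload.get("cv_mode", ""))
    if payload.get("rmsecv_curve") is not None:
        res.rmsecv_curve = np.asarray(payload["rmsecv_curve"], dtype=float)
    if payload.get("r_squared_curve") is not None:
        res.r_squared_curve = np.asarray(payload["r_squared_curve"],
                                         dtype=float)
    return res


# ---------------------------------------------------------------------------
# Multi-target calibration report
# ---------------------------------------------------------------------------

def calibrate(spectra: SpectraSet, reference: pd.DataFrame,
              targets=FATTY_ACID_TARGETS, max_factors: int = 15,
              cv: str = "loo", rule: str = "margin", margin: float = 0.02,
              provenance: dict | None = None):
    """Fit one PLS1 calibration per fatty-acid parameter.

    Returns ``(results, report)``: a dict of
    :class:`PLSCalibrationResults` keyed by target, and a report table
    with columns (Fatty acid, RMSECV, R2, Factors).
    """
    results: dict[str, PLSCalibrationResults] = {}
    rows = []
    for target in targets:
        model = PLSCalibration.from_spectra(spectra, reference, target,
                                            provenance=provenance)
        res = model.fit_with_cv(max_factors=max_factors, cv=cv, rule=rule,
                                margin=margin)
        results[target] = res
        rows.append({"Fatty acid": target,
                     "RMSECV": res.rmsecv,
                     "R2": res.r_squared,
                     "Factors": res.n_factors})
    report = pd.DataFrame(rows)
    return results, report
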