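"""Spectral preprocessing: replicate averaging, Savitzky-Golay second
derivatives and extended multiplicative signal correction (EMSC).

The pipeline order is: average technical replicates, differentiate twice
(nine-point Savitzky-Golay), then EMSC-normalize the derivative spectra on
the 3050-700 cm^-1 region.  EMSC models each spectrum as

    x(v) ~ a + b * m(v) + sum_k d_k * P_k(u(v))

with m a reference spectrum (by default the set mean), P_k Legendre
polynomials on u in [-1, 1], and returns (x - a - sum d_k P_k) / b, which
removes additive offsets, polynomial baselines and multiplicative scatter
in one least-squares step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectraSet

logger = logging.getLogger(__name__)

REPLICATE_KEY = ("sample_id", "run", "well")


def average_technical_replicates(spectra: SpectraSet,
                                 expected_groups=None) -> SpectraSet:
    """Pointwise mean of technical replicates per (sample_id, run, well).

    Output has one spectrum per distinct group, in first-appearance order;
    the ``replicate`` metadata column is dropped and ``spectrum_id`` becomes
    the group's sample id.  If ``expected_groups`` is given, groups absent
    from the input (all replicates removed by QC) are warned about by name.
    """
    meta = spectra.metadata
    key_cols = [c for c in REPLICATE_KEY if c in meta.columns]
    if not key_cols:
        raise ValueError("metadata lacks replicate grouping columns "
                         f"{REPLICATE_KEY}")
    keys = meta[key_cols].astype(str).agg("|".join, axis=1)
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(i)
    if expected_groups is not None:
        missing = [g for g in expected_groups if str(g) not in groups]
        for g in missing:
            logger.warning("replicate group %s has no surviving spectra; "
                           "dropped", g)
    rows = []
    meta_rows = []
    for k in order:
        idx = groups[k]
        rows.append(spectra.absorbance[idx].mean(axis=0))
        md = dict(meta.iloc[idx[0]])
        md.pop("replicate", None)
        md["spectrum_id"] = str(md.get("sample_id", k))
        md["n_replicates_averaged"] = len(idx)
        meta_rows.append(md)
    return SpectraSet(spectra.wavenumbers, np.vstack(rows),
                      pd.DataFrame(meta_rows))


# ---------------------------------------------------------------------------
# Savitzky-Golay derivative
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SavGolSettings:
    """Savitzky-Golay smoothing-derivative settings.

    Nine points at cubic order is the chemometrics default for second
    derivatives; the derivative is taken with respect to wavenumber
    (units absorbance * cm^2), so results are grid-spacing independent.
    """

    window_points: int = 9
    poly_order: int = 3
    deriv_order: int = 2

    def __post_init__(self) -> None:
        if self.window_points % 2 != 1:
            raise ValueError("window_points must be odd")
        if self.poly_order >= self.window_points:
            raise ValueError("poly_order must be < window_points")
        if self.deriv_order > self.poly_order:
            raise ValueError("deriv_order must be <= poly_order")


def savgol_second_derivative(spectra: SpectraSet,
                             settings: SavGolSettings = SavGolSettings()
                             ) -> SpectraSet:
    """Savitzky-Golay derivative of every spectrum w.r.t. wavenumber.

    Edge points are handled by evaluating the boundary-window polynomial
    fit, so the grid length is preserved.
    """
    n = spectra.wavenumbers.size
    if settings.window_points > n:
        raise ValueError(
            f"window of {settings.window_points} points exceeds spectrum "
            f"length {n}")
    # even derivative orders are orientation-independent; odd ones need the
    # sign flipped because the stored grid descends
    deriv = savgol_filter(spectra.absorbance, settings.window_points,
                          settings.poly_order, deriv=settings.deriv_order,
                          delta=spectra.spacing, axis=1, mode="interp")
    if settings.deriv_order % 2 == 1:
        deriv = -deriv
    return SpectraSet(spectra.wavenumbers, deriv, spectra.metadata)


# ---------------------------------------------------------------------------
# EMSC
# ---------------------------------------------------------------------------

@dataclass
class EMSCSettings:
    """EMSC normalization settings.

    ``region`` is the (high, low) wavenumber interval the correction is
    fitted and applied on; endpoints snap to the nearest grid points.
    ``reference`` is a Spectrum, a bare array on the region sub-grid, or
    the string ``"mean-of-set"`` (the default: the mean of the corrected
    set, stored afterwards so new spectra are corrected against the same
    reference).  ``polynomial_order`` 2 gives the basic EMSC model with
    constant, linear and quadratic baseline terms.
    """

    region: tuple[float, float] = (3050.0, 700.0)
    reference: object = "mean-of-set"
    polynomial_order: int = 2

    def __post_init__(self) -> None:
        if self.polynomial_order < 0:
            raise ValueError("polynomial_order must be >= 0")


@dataclass
class EMSCResult:
    """EMSC-corrected spectra plus per-spectrum model parameters.

    ``parameters`` has one row per spectrum: offset ``a``, multiplicative
    scale ``b``, polynomial coefficients ``d1..dp`` and the residual RMS of
    the fit.  Spectra fitted with non-positive ``b`` are flagged.
    """

    corrected: SpectraSet
    parameters: pd.DataFrame
    reference: np.ndarray
    settings: EMSCSettings = field(repr=False)


def _legendre_basis(n_points: int, order: int) -> np.ndarray:
    """Columns P_0..P_order evaluated on n equispaced points of [-1, 1]."""
    u = np.linspace(-1.0, 1.0, n_points)
    cols = []
    for k in range(order + 1):
        c = np.zeros(k + 1)
        c[k] = 1.0
        cols.append(legendre.legval(u, c))
    return np.column_stack(cols)


def emsc(spectra: SpectraSet,
         settings: EMSCSettings | None = None) -> EMSCResult:
    """Fit and apply EMSC to every spectrum on the region sub-grid."""
    if settings is None:
        settings = EMSCSettings()
    sub = spectra.restrict(*settings.region)
    lo, hi = sub.wavenumbers[-1], sub.wavenumbers[0]
    logger.info("EMSC region snapped to %g-%g cm^-1 (%d points)",
                hi, lo, sub.wavenumbers.size)
    ref = settings.reference
    if isinstance(ref, str):
        if ref != "mean-of-set":
            raise ValueError(f"unknown reference spec {ref!r}")
        m = sub.absorbance.mean(axis=0)
    elif isinstance(ref, Spectrum):
        mask = (ref.wavenumbers <= settings.region[0] + 1e-9) \
            & (ref.wavenumbers >= settings.region[1] - 1e-9)
        m = ref.absorbance[mask] if mask.sum() == sub.wavenumbers.size \
            else np.interp(sub.wavenumbers[::-1], ref.wavenumbers[::-1],
                           ref.absorbance[::-1])[::-1]
    else:
        m = np.asarray(ref, dtype=float)
        if m.size != sub.wavenumbers.size:
            raise ValueError(
                f"reference length {m.size} != region grid length "
                f"{sub.wavenumbers.size}")

    p = settings.polynomial_order
    basis = _legendre_basis(sub.wavenumbers.size, p)
    design = np.column_stack([basis, m])
    # reference must add information beyond the baseline polynomials
    if np.linalg.matrix_rank(design, tol=None) < design.shape[1]:
        raise ValueError("degenerate reference: reference spectrum is "
                         "collinear with the baseline polynomials")

    coef, _, _, _ = np.linalg.lstsq(design, sub.absorbance.T, rcond=None)
    coef = coef.T  # (n_spectra, p + 2): a, d1..dp, b
    a = coef[:, 0]
    d = coef[:, 1:p + 1]
    b = coef[:, p + 1]
    baseline = coef[:, :p + 1] @ basis.T
    residual = sub.absorbance - baseline - np.outer(b, m)
    rms = np.sqrt(np.mean(residual ** 2, axis=1))
    bad = b <= 0
    if bad.any():
        logger.warning("EMSC: %d spectra fitted with non-positive "
                       "multiplicative scale b; flagged", int(bad.sum()))
    b_safe = np.where(bad, np.nan, b)
    corrected = (sub.absorbance - baseline) / b_safe[:, None]
    params = pd.DataFrame({"spectrum_id": sub.ids, "a": a, "b": b})
    for k in range(1, p + 1):
        params[f"d{k}"] = d[:, k - 1]
    params["residual_rms"] = rms
    params["flagged_nonpositive_b"] = bad
    out = SpectraSet(sub.wavenumbers, corrected, sub.metadata)
    stored = EMSCSettings(region=settings.region, reference=m.copy(),
                          polynomial_order=p)
    return EMSCResult(out, params, m.copy(), stored)


def apply_emsc(spectra: SpectraSet, fitted: EMSCResult) -> SpectraSet:
    """Correct new spectra against a previously fitted EMSC reference."""
    res = emsc(spectra, fitted.settings)
    return res.corrected
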