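"""Assay kinetics: Michaelis-Menten, dose-response, FP binding, NADH, qPCR.

All fitters follow the same deterministic contract: a coarse log-grid
initialisation over the nonlinear parameter with closed-form linear
parameters at each grid point, followed by bounded nonlinear
least-squares refinement at fixed tolerances.  No randomised restarts;
identical data always yields identical fits.  Non-convergence is a
flagged result, never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

XTOL = 1e-14
FTOL = 1e-14
GTOL = 1e-14


def _covariance_se(res, n_obs: int) -> np.ndarray:
    """Asymptotic standard errors from the least-squares Jacobian."""
    dof = max(n_obs - res.x.size, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(res.x.size, np.nan)


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten fit: v = V_max * S / (K_m + S)."""

    V_max: float
    K_m: float
    k_cat: float | None
    sse: float
    converged: bool
    se: dict = field(default_factory=dict)

    def specificity_constant(self) -> float:
        """k_cat / K_m (per s per µM), requires E0-calibrated k_cat."""
        if self.k_cat is None:
            raise ValueError("k_cat requires E0 at fit time")
        return self.k_cat / self.K_m


def _mm_vmax_closed_form(S: np.ndarray, v: np.ndarray, km: float) -> float:
    f = S / (km + S)
    denom = float((f * f).sum())
    return float((v * f).sum() / denom) if denom > 0 else 0.0


def mm_grid_search(S: np.ndarray, v: np.ndarray, n_grid: int = 60,
                   span: float = 100.0) -> tuple[float, float, float]:
    """Best (K_m, V_max, sse) over a log grid with closed-form V_max."""
    lo, hi = S[S > 0].min() / span, S.max() * span
    best = (np.nan, np.nan, np.inf)
    for km in np.geomspace(lo, hi, n_grid):
        vmax = _mm_vmax_closed_form(S, v, km)
        sse = float(((v - vmax * S / (km + S)) ** 2).sum())
        if sse < best[2]:
            best = (km, vmax, sse)
    return best


def fit_michaelis_menten(S, v, E0: float | None = None) -> MMFit:
    """Least-squares Michaelis-Menten fit with log-grid initialisation.

    S in µM, v in any consistent rate unit; with E0 (µM) supplied,
    k_cat = V_max / E0.  Negative rates raise; a failed refinement
    returns converged=False.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if S.shape != v.shape or S.size < 4:
        raise ValueError("need >= 4 paired (S, v) observations")
    if np.any(v < 0):
        raise ValueError("negative rates are not valid Michaelis-Menten data")
    km0, vmax0, _ = mm_grid_search(S, v)

    def resid(p):
        vmax, km = p
        return vmax * S / (km + S) - v

    res = least_squares(resid, x0=[max(vmax0, 1e-12), max(km0, 1e-12)],
                        bounds=([0, 1e-12], [np.inf, np.inf]), xtol=XTOL, ftol=FTOL, gtol=GTOL, x_scale="jac")
    vmax, km = res.x
    se = _covariance_se(res, S.size)
    return MMFit(
        V_max=float(vmax), K_m=float(km),
        k_cat=float(vmax / E0) if E0 else None,
        sse=float((resid(res.x) ** 2).sum()),
        converged=bool(res.success and np.isfinite(res.x).all()),
        se={"V_max": float(se[0]), "K_m": float(se[1])},
    )


# ---------------------------------------------------------------------------
# Four-parameter logistic (IC50)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseFit:
    """4-parameter logistic: y = bottom + (top - bottom)/(1 + (I/IC50)^h)."""

    IC50: float
    h: float
    top: float
    bottom: float
    sse: float
    converged: bool
    se: dict = field(default_factory=dict)


H_BOUNDS = (0.3, 5.0)


def _logistic4p(I, top, bottom, ic50, h):
    return bottom + (top - bottom) / (1.0 + np.power(I / ic50, h))


def ic50_grid_search(I: np.ndarray, y: np.ndarray, n_ic50: int = 80,
                     n_h: int = 12) -> tuple[float, float, float, float, float]:
    """Best (ic50, h, top, bottom, sse) over a log/lin grid with linear
    closed-form top/bottom at each grid point."""
    Ipos = I[I > 0]
    lo, hi = Ipos.min() / 30.0, Ipos.max() * 30.0
    best = (np.nan, 1.0, np.nan, np.nan, np.inf)
    for ic50 in np.geomspace(lo, hi, n_ic50):
        for h in np.linspace(H_BOUNDS[0], H_BOUNDS[1], n_h):
            f = 1.0 / (1.0 + np.power(I / ic50, h))
            # y = bottom + (top-bottom) f  -> linear in (bottom, span)
            A = np.column_stack([np.ones_like(f), f])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            bottom, span = coef
            sse = float(((A @ coef - y) ** 2).sum())
            if sse < best[4]:
                best = (float(ic50), float(h), float(bottom + span), float(bottom), sse)
    return best


def fit_ic50(I, y) -> DoseResponseFit:
    """Fit a 4-parameter logistic dose-response curve (Hill slope fitted,
    bounded to [0.3, 5]).  Flat data returns a non-converged flag."""
    I = np.asarray(I, dtype=float)
    y = np.asarray(y, dtype=float)
    if I.shape != y.shape or I.size < 5:
        raise ValueError("need >= 5 paired (I, y) observations")
    span = y.max() - y.min()
    if span <= 0 or span < 1e-12 * max(abs(y).max(), 1.0):
        return DoseResponseFit(IC50=np.nan, h=np.nan, top=float(y.max()),
                               bottom=float(y.min()), sse=0.0, converged=False)
    ic0, h0, top0, bot0, _ = ic50_grid_search(I, y)

    def resid(p):
        top, bottom, ic50, h = p
        return _logistic4p(I, top, bottom, ic50, h) - y

    res = least_squares(
        resid, x0=[top0, bot0, max(ic0, 1e-12), h0],
        bounds=([-np.inf, -np.inf, 1e-12, H_BOUNDS[0]], [np.inf, np.inf, np.inf, H_BOUNDS[1]]),
        xtol=XTOL, ftol=FTOL, gtol=GTOL, x_scale="jac",
    )
    top, bottom, ic50, h = res.x
    se = _covariance_se(res, I.size)
    converged = bool(res.success and np.isfinite(res.x).all() and bottom <= top)
    return DoseResponseFit(
        IC50=float(ic50), h=float(h), top=float(top), bottom=float(bottom),
        sse=float((resid(res.x) ** 2).sum()), converged=converged,
        se={"top": float(se[0]), "bottom": float(se[1]), "IC50": float(se[2]), "h": float(se[3])},
    )


# ---------------------------------------------------------------------------
# Fluorescence-polarization binding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingFit:
    """Hyperbolic FP isotherm: r = r_f + (r_b - r_f) * P / (P + K_d)."""

    K_d: float
    r_f: float
    r_b: float
    sse: float
    converged: bool
    se: dict = field(default_factory=dict)


def fp_grid_search(P: np.ndarray, r: np.ndarray, n_grid: int = 200,
                   span: float = 100.0) -> tuple[float, float, float, float]:
    """Best (kd, r_f, r_b, sse) over a log grid with linear closed-form
    endpoints at each K_d grid point."""
    lo, hi = P[P > 0].min() / span, P.max() * span
    best = (np.nan, np.nan, np.nan, np.inf)
    for kd in np.geomspace(lo, hi, n_grid):
        f = P / (P + kd)
        A = np.column_stack([np.ones_like(f), f])
        coef, *_ = np.linalg.lstsq(A, r, rcond=None)
        rf, span_r = coef
        sse = float(((A @ coef - r) ** 2).sum())
        if sse < best[3]:
            best = (float(kd), float(rf), float(rf + span_r), sse)
    return best


def fit_fp_binding(P, r) -> BindingFit:
    """Fit the tracer-dilute hyperbolic binding isotherm to anisotropy data."""
    P = np.asarray(P, dtype=float)
    r = np.asarray(r, dtype=float)
    if P.shape != r.shape or P.size < 5:
        raise ValueError("need >= 5 paired (P, r) observations")
    kd0, rf0, rb0, _ = fp_grid_search(P, r)

    def resid(p):
        rf, rb, kd = p
        return rf + (rb - rf) * P / (P + kd) - r

    res = least_squares(resid, x0=[rf0, rb0, max(kd0, 1e-12)],
                        bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                        xtol=XTOL, ftol=FTOL, gtol=GTOL, x_scale="jac")
    rf, rb, kd = res.x
    se = _covariance_se(res, P.size)
    return BindingFit(
        K_d=float(kd), r_f=float(rf), r_b=float(rb),
        sse=float((resid(res.x) ** 2).sum()),
        converged=bool(res.success and np.isfinite(res.x).all()),
        se={"r_f": float(se[0]), "r_b": float(se[1]), "K_d": float(se[2])},
    )


# ---------------------------------------------------------------------------
# NADH-coupled assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NadhParams:
    """Beer-Lambert constants for NADH at 340 nm."""

    epsilon: float = 6220.0  # M^-1 cm^-1
    pathlength: float = 1.0  # cm

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.pathlength <= 0:
            raise ValueError("epsilon and pathlength must be positive")


def nadh_rate_and_equivalents(t, A340, params: NadhParams,
                              compound_conc_uM: float) -> dict:
    """ADP production rate and total equivalents from an A340 progress trace.

    In the coupled assay each ADP regenerates by oxidising one NADH, so
    -dA340/dt / (eps*l) is the molar ADP production rate.  rate (µM/s)
    comes from a least-squares line over the trace; total_ADP (µM) from
    the start-to-end absorbance drop; equivalents = total_ADP /
    compound concentration, which separates single-turnover
    phosphotransfer (~1) from ATPase activation (>> 1).
    A clearly increasing absorbance trend is an error.
    """
    t = np.asarray(t, dtype=float)
    A = np.asarray(A340, dtype=float)
    if t.shape != A.shape or t.size < 3:
        raise ValueError("need >= 3 paired (t, A340) observations")
    if compound_conc_uM <= 0:
        raise ValueError("compound concentration must be positive")
    slope, intercept = np.polyfit(t, A, 1)
    resid = A - (slope * t + intercept)
    se_slope = np.sqrt(
        (resid**2).sum() / max(t.size - 2, 1) / ((t - t.mean()) ** 2).sum()
    )
    if slope > 0 and slope > 2 * se_slope:
        raise ValueError("absorbance increases over time: not an NADH consumption trace")
    scale = params.epsilon * params.pathlength
    rate_uM_s = max(-slope, 0.0) / scale * 1e6
    total_adp_uM = max(A[0] - A[-1], 0.0) / scale * 1e6
    return {
        "rate_uM_s": float(rate_uM_s),
        "total_ADP_uM": float(total_adp_uM),
        "equivalents": float(total_adp_uM / compound_conc_uM),
    }


# ---------------------------------------------------------------------------
# Specificity constants and qPCR quantification
# ---------------------------------------------------------------------------

def specificity_ratio(fit_a: MMFit, fit_b: MMFit) -> dict:
    """Ratio of specificity constants (k_cat/K_m) and the within-10-fold call
    (boundary inclusive)."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    ratio = fit_a.specificity_constant() / fit_b.specificity_constant()
    return {"ratio": float(ratio), "within_10fold": bool(0.1 <= ratio <= 10.0)}


def qpcr_quantify(ct: float, curve) -> float:
    """Invert a qPCR standard curve: copies = 10^((Ct - intercept)/slope)."""
    if curve.slope >= 0:
        raise ValueError("curve slope must be negative")
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def qpcr_enrichment(ct_target_pre: float, ct_ctrl_pre: float,
                    ct_target_post: float, ct_ctrl_post: float,
                    slope: float = -3.321928094887362) -> float:
    """Control-normalised fold enrichment from four Ct values.

    ddCt = (Ct_target,pre - Ct_target,post) - (Ct_ctrl,pre - Ct_ctrl,post);
    enrichment = 10^(-ddCt/slope), which reduces to 2^ddCt at 100%
    amplification efficiency (slope = -log2 10).
    """
    if slope >= 0:
        raise ValueError("slope must be negative")
    ddct = (ct_target_pre - ct_target_post) - (ct_ctrl_pre - ct_ctrl_post)
    return float(10.0 ** (-ddct / slope))
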