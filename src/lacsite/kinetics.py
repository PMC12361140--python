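"""Smoothed-Monod kinetic model and window-scan slope estimation for ONPG curves.

A beta-galactosidase (LacS) assay tracks o-nitrophenol release at OD410 over
time.  The initial slope of the conversion curve is the activity readout, but
raw curves carry a lag phase and a substrate-depletion plateau.  Both are
captured by a Monod-type saturation model applied to a smoothed ramp of time:

    OD410(t) = sl * dt * m / (sl * dt + m)
    dt       = [ (t - t_off) + sqrt((t - t_off)^2 + d^2) ] / 2

where ``sl`` is the initial conversion rate (OD410/min), ``m`` the plateau
absorbance, ``t_off`` the lag offset (min) and ``d`` the width (min) of the
smooth transition around the offset.  ``dt`` is a smoothed hinge: it tends to
max(0, t - t_off) as d -> 0 and grows with unit rate for t >> t_off, so the
model's early-time behaviour is exactly ``sl * (t - t_off)``.

Slope estimation fits this model to every prefix window of the curve (points
0..k for k = 5 .. N-1), locates local minima of the residual standard error
across window lengths, and among those picks the fit whose slope has the
smallest standard error.  Inadequate free fits are retried with the smoothing
width ``d`` fixed to the mean fitted ``d`` of sibling replicates.  Replicate
slopes are combined as a geometric mean with a geometric standard error,
escalated to the per-fit or technical-replicate error when one of those is
larger.

Plateau anchoring: in an endpoint ONPG assay the absorbance at complete
substrate conversion is an assay constant (substrate load times the
o-nitrophenol extinction), not free biology.  When a fit window never
approaches that plateau (max OD below ``sat_fraction * m_nominal``) the data
carry no information about ``m``, and leaving it free lets ``m`` trade off
against ``sl`` along a likelihood ridge, inflating the slope estimate.  Such
windows are therefore fit with ``m`` held at the nominal complete-conversion
absorbance; in this near-linear regime the slope is insensitive to the exact
anchor value (second-order in observed OD / m), so a rough nominal suffices.
Windows that do reach the plateau fit ``m`` freely, where it is identified.
Set ``m_nominal=None`` to disable anchoring and always fit all four
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticCurve",
    "MonodFitParams",
    "WindowFit",
    "FitScan",
    "SlopeEstimate",
    "ActivitySummary",
    "AdequacyRules",
    "smoothed_time",
    "eval_model",
    "initial_guess",
    "fit_window",
    "scan_and_select",
    "estimate_slope",
    "aggregate_activity",
    "process_plate",
]

SL_FLOOR = 1e-8  # OD410/min; initial-guess floor for flat/degenerate curves
# residual SEs below this (in OD410) are indistinguishable from an exact fit;
# treating them as zero makes noiseless curves tie across windows, so the
# selection's larger-window preference resolves them deterministically
ZERO_ERROR_FLOOR = 1e-12


@dataclass(frozen=True)
class KineticCurve:
    """One replicate's OD410 time series (times in minutes, strictly increasing)."""

    strain_id: str
    condition: str
    bio_rep: int
    tech_rep: int
    times: np.ndarray
    od410: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od410, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and od410 must be 1-D and equal length")
        if len(t) < 6:
            raise ValueError("a kinetic curve needs at least 6 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od410", y)

    @property
    def key(self) -> tuple:
        return (self.strain_id, self.condition, self.bio_rep, self.tech_rep)


@dataclass(frozen=True)
class MonodFitParams:
    """Parameters of the smoothed-Monod conversion model."""

    sl: float  # initial conversion rate, OD410/min
    m: float  # plateau OD410
    t_off: float  # lag offset, min
    d: float  # transition smoothing width, min


@dataclass
class WindowFit:
    """Fit of the model to the prefix window 0..end_index of a curve."""

    end_index: int
    params: MonodFitParams
    param_se: dict
    fit_error: float  # residual standard error sqrt(SSE / (n - n_free))
    converged: bool
    adequate: bool
    d_was_fixed: bool
    m_was_fixed: bool = False


@dataclass
class FitScan:
    """All prefix-window fits of one curve, plus the error-profile selection."""

    window_fits: list
    local_min_indices: list
    selected: Optional[WindowFit]


@dataclass
class SlopeEstimate:
    strain_id: str
    condition: str
    bio_rep: int
    tech_rep: int
    slope: Optional[float]
    slope_se: Optional[float]
    fit_error: Optional[float]
    end_index: Optional[int]
    provenance: str  # free_fit | d_fixed | failed


@dataclass
class ActivitySummary:
    strain_id: str
    condition: str
    geo_mean_slope: float
    geo_se: float  # multiplicative standard error, >= 1
    reported_error: float  # log-scale error after escalation
    n_replicates: int


@dataclass(frozen=True)
class AdequacyRules:
    """Thresholds deciding whether a converged fit is usable.

    A fit is adequate when it converged, sl and m are positive, the relative
    standard error of the slope does not exceed ``max_rel_se_sl`` and the
    fitted lag offset lies in [t_0 - t_off_slack, t_k].

    ``m_nominal``/``sat_fraction`` control plateau anchoring (see module
    docstring): windows whose maximum OD stays below sat_fraction * m_nominal
    are fit with the plateau held at m_nominal.  m_nominal=None disables it.
    """

    max_rel_se_sl: float = 0.5
    t_off_slack: float = 30.0  # min before the first sample the lag may start
    m_nominal: Optional[float] = 1.0  # nominal complete-conversion OD410
    sat_fraction: float = 0.5


def smoothed_time(t: float, t_off: float, d: float):
    """Smoothed elapsed time dt = [(t - t_off) + sqrt((t - t_off)^2 + d^2)] / 2.

    Total, non-negative, non-decreasing in t; equals d/2 at t = t_off and
    converges to the hinge max(0, t - t_off) as d -> 0.
    """
    x = np.asarray(t, dtype=float) - t_off
    # clamp guards underflow of x*x for subnormal x; dt is mathematically >= 0
    return np.maximum(0.0, 0.5 * (x + np.sqrt(x * x + d * d)))


def eval_model(params: MonodFitParams, t):
    """OD410(t) = sl*dt*m / (sl*dt + m) for the smoothed elapsed time dt."""
    dt = smoothed_time(t, params.t_off, params.d)
    num = params.sl * dt * params.m
    den = params.sl * dt + params.m
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out if np.ndim(t) else float(out)


def _steepest_run_slope(t: np.ndarray, y: np.ndarray) -> float:
    """OLS slope of the steepest consecutive 3-point run; floor for flat input."""
    best = -np.inf
    for i in range(len(t) - 2):
        tt, yy = t[i : i + 3], y[i : i + 3]
        sxx = np.sum((tt - tt.mean()) ** 2)
        if sxx == 0:
            continue
        best = max(best, float(np.sum((tt - tt.mean()) * (yy - yy.mean())) / sxx))
    if not np.isfinite(best) or best <= 0:
        return SL_FLOOR
    return best


def initial_guess(curve: KineticCurve, end_index: int) -> MonodFitParams:
    """Heuristic starting point for the window fit.

    sl: steepest 3-point OLS slope (floored at a small positive value for flat
    curves); m: 1.5x the window maximum; t_off: first time the signal exceeds
    the baseline (first 3 points) by 3 sigma, else t_0; d: sampling interval.
    """
    if end_index < 5:
        raise ValueError("end_index must be >= 5")
    t = curve.times[: end_index + 1]
    y = curve.od410[: end_index + 1]
    sl0 = _steepest_run_slope(t, y)
    ymax = float(np.max(y))
    m0 = max(1.5 * ymax, 1.1 * ymax) if ymax > 0 else 0.1
    base = y[:3]
    thresh = float(base.mean() + 3.0 * max(base.std(), 1e-6))
    above = np.nonzero(y > thresh)[0]
    t_off0 = float(t[above[0]]) if len(above) else float(t[0])
    d0 = float(np.median(np.diff(t)))
    return MonodFitParams(sl=sl0, m=m0, t_off=t_off0, d=d0)


def _check_adequate(fit: WindowFit, t0: float, t_end: float, rules: AdequacyRules) -> bool:
    if not fit.converged:
        return False
    p = fit.params
    if not (p.sl > 0 and p.m > 0):
        return False
    se_sl = fit.param_se.get("sl", np.inf)
    if not np.isfinite(se_sl) or se_sl / p.sl > rules.max_rel_se_sl:
        return False
    return (t0 - rules.t_off_slack) <= p.t_off <= t_end


def fit_window(
    curve: KineticCurve,
    end_index: int,
    fixed_d: Optional[float] = None,
    rules: AdequacyRules = AdequacyRules(),
    start: Optional[MonodFitParams] = None,
) -> WindowFit:
    """Bounded least-squares fit of the model to points 0..end_index.

    With ``fixed_d`` the smoothing width is held constant and three parameters
    are free.  Windows that never approach the nominal plateau additionally
    hold ``m`` at ``rules.m_nominal`` (plateau anchoring, module docstring).
    Non-convergence is encoded in the result, never raised.  The fit error is
    the residual standard error sqrt(SSE / (n_points - n_free)).
    """
    n_points = end_index + 1
    if not (5 <= end_index <= len(curve.times) - 1):
        raise ValueError("end_index out of range")
    t = curve.times[:n_points]
    y = curve.od410[:n_points]
    g = start if start is not None else initial_guess(curve, end_index)

    fix_m = rules.m_nominal is not None and float(np.max(y)) < rules.sat_fraction * rules.m_nominal
    names, x0, lo, hi = ["sl"], [g.sl], [1e-12], [np.inf]
    if not fix_m:
        names.append("m"); x0.append(g.m); lo.append(1e-12); hi.append(np.inf)
    names.append("t_off"); x0.append(g.t_off); lo.append(-np.inf); hi.append(np.inf)
    if fixed_d is None:
        names.append("d"); x0.append(g.d); lo.append(0.0); hi.append(np.inf)

    def unpack(x):
        vals = dict(zip(names, x))
        return MonodFitParams(
            sl=vals["sl"],
            m=vals.get("m", rules.m_nominal),
            t_off=vals["t_off"],
            d=vals.get("d", fixed_d),
        )

    n_free = len(names)
    if n_points <= n_free:
        raise ValueError("window has no residual degrees of freedom")

    def resid(x):
        return eval_model(unpack(x), t) - y

    def jac(x):
        p = unpack(x)
        xt = t - p.t_off
        root = np.sqrt(xt * xt + p.d * p.d)
        dt = 0.5 * (xt + root)
        u = p.sl * dt
        den2 = (u + p.m) ** 2
        cols = {
            "sl": p.m**2 * dt / den2,
            "m": u**2 / den2,
            "t_off": (p.m**2 * p.sl / den2) * (-0.5) * (1.0 + np.divide(
                xt, root, out=np.sign(xt), where=root > 0)),
            "d": (p.m**2 * p.sl / den2) * 0.5 * np.divide(
                p.d, root, out=np.zeros_like(root), where=root > 0),
        }
        return np.column_stack([cols[n] for n in names])

    x0 = np.clip(x0, lo, hi)
    try:
        res = least_squares(
            resid, x0, jac=jac, bounds=(lo, hi), method="trf", ftol=1e-10,
            xtol=1e-12, gtol=1e-12, max_nfev=2000,
        )
        converged = res.status > 0
    except Exception:
        return WindowFit(end_index, unpack(x0), {}, np.inf, False, False,
                         fixed_d is not None, fix_m)

    params = unpack(res.x)
    dof = n_points - n_free
    sse = float(np.sum(res.fun**2))
    fit_error = math.sqrt(sse / dof)
    if fit_error < ZERO_ERROR_FLOOR:  # numerically exact fit
        fit_error = 0.0

    # parameter SEs from the Gauss-Newton curvature at the optimum
    try:
        _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
        s = np.where(s > s[0] * 1e-12, s, np.inf) if len(s) else s
        cov = (vt.T / s**2) @ vt * fit_error**2
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
        param_se = dict(zip(names, ses.tolist()))
    except np.linalg.LinAlgError:
        param_se = {k: np.inf for k in names}
        converged = False

    fit = WindowFit(
        end_index=end_index,
        params=params,
        param_se=param_se,
        fit_error=fit_error,
        converged=converged,
        adequate=False,
        d_was_fixed=fixed_d is not None,
        m_was_fixed=fix_m,
    )
    fit.adequate = _check_adequate(fit, float(t[0]), float(t[-1]), rules)
    return fit


def _local_minima(errors: Sequence[float]) -> list:
    """Indices of non-strict local minima; endpoints qualify via one neighbor."""
    idx = []
    n = len(errors)
    for i in range(n):
        left_ok = i == 0 or errors[i] <= errors[i - 1]
        right_ok = i == n - 1 or errors[i] <= errors[i + 1]
        if left_ok and right_ok:
            idx.append(i)
    return idx


def scan_and_select(
    curve: KineticCurve,
    fixed_d: Optional[float] = None,
    rules: AdequacyRules = AdequacyRules(),
) -> FitScan:
    """Fit every prefix window t_0..t_k for k = 5..N-1 and select a slope.

    Local minima of the fit-error profile over window length are located
    (non-strict; endpoints count; ties resolve toward longer windows at the
    selection stage), and among the converged, adequate local-minimum fits the
    one with the smallest slope standard error wins.

    Successive windows are solved by continuation: each fit warm-starts from
    the previous window's converged solution, which both speeds the scan and
    keeps the optimizer tracking one solution branch as the window grows.
    """
    n = len(curve.times)
    fits = []
    prev: Optional[MonodFitParams] = None
    for k in range(5, n):
        f = fit_window(curve, k, fixed_d=fixed_d, rules=rules, start=prev)
        if f.converged:
            prev = f.params
        fits.append(f)
    errors = [f.fit_error if np.isfinite(f.fit_error) else np.inf for f in fits]
    min_pos = _local_minima(errors)
    local_min_indices = [fits[i].end_index for i in min_pos]

    candidates = [fits[i] for i in min_pos if fits[i].converged and fits[i].adequate]
    selected = None
    if candidates:
        # smallest SE(sl); ties toward larger end_index (more data)
        selected = min(candidates, key=lambda f: (f.param_se.get("sl", np.inf), -f.end_index))
    return FitScan(window_fits=fits, local_min_indices=local_min_indices, selected=selected)


def _scan_d(scan: Optional[FitScan]) -> Optional[float]:
    if scan is not None and scan.selected is not None and not scan.selected.d_was_fixed:
        return scan.selected.params.d
    return None


def estimate_slope(
    curve: KineticCurve,
    scan: FitScan,
    cohort_tech: Sequence[FitScan] = (),
    cohort_bio: Sequence[FitScan] = (),
    rules: AdequacyRules = AdequacyRules(),
) -> SlopeEstimate:
    """Turn a scan into a slope estimate, with the fixed-d fallback.

    If the free scan selected nothing, ``d`` is fixed to the mean fitted ``d``
    of sibling technical replicates (preferred) or, failing that, biological
    replicates, and the scan is rerun.  Remaining failure is encoded in
    ``provenance``.
    """
    chosen, provenance = scan.selected, "free_fit"
    if chosen is None:
        ds = [v for v in (_scan_d(s) for s in cohort_tech) if v is not None]
        if not ds:
            ds = [v for v in (_scan_d(s) for s in cohort_bio) if v is not None]
        if ds:
            refit = scan_and_select(curve, fixed_d=float(np.mean(ds)), rules=rules)
            chosen, provenance = refit.selected, "d_fixed"
    if chosen is None:
        return SlopeEstimate(*curve.key, slope=None, slope_se=None, fit_error=None,
                             end_index=None, provenance="failed")
    return SlopeEstimate(
        *curve.key,
        slope=chosen.params.sl,
        slope_se=chosen.param_se.get("sl"),
        fit_error=chosen.fit_error,
        end_index=chosen.end_index,
        provenance=provenance,
    )


def aggregate_activity(estimates: Sequence[SlopeEstimate]) -> ActivitySummary:
    """Geometric-mean slope with escalated error for one strain/condition.

    reported_error is the largest, on the natural-log (relative) scale, of the
    geometric standard error, the mean relative per-fit slope SE, and the
    scatter of log slopes within technical-replicate groups.
    """
    ok = [e for e in estimates if e.provenance != "failed" and e.slope]
    if not ok:
        raise ValueError("no successful slope estimate to aggregate")
    strain = ok[0].strain_id
    condition = ok[0].condition
    logs = np.log([e.slope for e in ok])
    n = len(logs)
    geo_mean = float(np.exp(logs.mean()))
    sd = float(np.std(logs, ddof=1)) if n > 1 else 0.0
    geo_se = float(np.exp(sd / math.sqrt(n)))

    rel_fit_se = float(np.mean([e.slope_se / e.slope for e in ok if e.slope_se is not None] or [0.0]))
    # scatter among technical replicates, per biological replicate
    tech_sds = []
    for b in {e.bio_rep for e in ok}:
        grp = np.log([e.slope for e in ok if e.bio_rep == b])
        if len(grp) > 1:
            tech_sds.append(float(np.std(grp, ddof=1)))
    tech_term = float(np.mean(tech_sds)) if tech_sds else 0.0

    reported = max(math.log(geo_se), rel_fit_se, tech_term)
    return ActivitySummary(
        strain_id=strain, condition=condition, geo_mean_slope=geo_mean,
        geo_se=geo_se, reported_error=reported, n_replicates=n,
    )


def process_plate(
    curves: Sequence[KineticCurve], rules: AdequacyRules = AdequacyRules()
) -> tuple[list, list]:
    """Run the full slope pipeline on a plate of curves.

    Returns (per-curve SlopeEstimates, per strain/condition ActivitySummaries).
    Sibling replicates supply the fixed-d fallback: technical replicates of the
    same biological replicate first, then other replicates of the strain.
    """
    scans = {c.key: scan_and_select(c, rules=rules) for c in curves}
    estimates = []
    for c in curves:
        tech = [scans[o.key] for o in curves
                if o.key != c.key and o.strain_id == c.strain_id
                and o.condition == c.condition and o.bio_rep == c.bio_rep]
        bio = [scans[o.key] for o in curves
               if o.strain_id == c.strain_id and o.condition == c.condition
               and o.bio_rep != c.bio_rep]
        estimates.append(estimate_slope(c, scans[c.key], tech, bio, rules=rules))

    summaries = []
    for key in sorted({(e.strain_id, e.condition) for e in estimates}):
        grp = [e for e in estimates if (e.strain_id, e.condition) == key
               and e.provenance != "failed"]
        if grp:
            summaries.append(aggregate_activity(grp))
    return estimates, summaries
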