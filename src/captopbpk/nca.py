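"""Non-compartmental analysis of concentration-time profiles.

Standard model-free PK parameter estimation: Cmax/Tmax read off the
profile, the terminal rate constant lambda_z by log-linear regression over
the best terminal window (maximum adjusted R-squared over all contiguous
terminal windows of >= 3 positive concentrations, excluding Cmax for
extravascular routes; ties favour more points), AUC by linear trapezoids
with a ``Clast / lambda_z`` tail, and clearance as ``dose / AUC0-inf``.

For iv-bolus profiles whose first sample is after dosing (the clinical
situation: blood draws start minutes post-dose), C0 is back-extrapolated
log-linearly from the first two positive concentrations and used for the
initial AUC segment only -- Cmax remains the maximum *observed* value, the
usual iv-bolus reporting convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError
from .pbpk_simulator import ConcentrationProfile

__all__ = [
    "NCAResult",
    "estimate_lambda_z",
    "compute_auc",
    "compute_clearance",
    "run_nca",
    "nca_table",
]

EXTRAPOLATION_WARN_FRACTION = 0.2


@dataclass(frozen=True)
class NCAResult:
    """PK parameters for one profile.

    ``cl_over_f`` is ``dose / AUC0-inf`` in L/h: the systemic clearance for
    an iv dose, the apparent oral clearance CL/F otherwise.  Fields tied to
    the terminal phase are ``None`` when lambda_z is not estimable.
    """

    subject_id: int
    trial_id: int
    dose_mg: float
    route: str
    auc_0_t: float  # ng/mL.h
    auc_0_inf: float | None
    extrapolated_fraction: float | None
    cmax: float  # ng/mL
    tmax: float  # h
    lambda_z: float | None  # 1/h
    n_lambda_points: int
    r2_adj: float | None
    cl_over_f: float | None  # L/h


def _adjusted_r2(log_c: np.ndarray, t: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and adjusted R-squared of a log-linear fit."""
    n = len(t)
    slope, intercept = np.polyfit(t, log_c, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((log_c - fitted) ** 2))
    ss_tot = float(np.sum((log_c - log_c.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, intercept, r2_adj


def estimate_lambda_z(
    t: Sequence[float],
    c: Sequence[float],
    exclude_tmax: bool = False,
) -> tuple[float | None, int, float | None]:
    """Terminal slope by best-window log-linear regression.

    Returns ``(lambda_z, n_points, r2_adj)``; ``(None, 0, None)`` when
    fewer than 3 usable points exist or no window yields a negative slope.
    Zero concentrations are excluded from the regression; with
    ``exclude_tmax`` (oral) only points strictly after Tmax are candidates.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if exclude_tmax and c.size:
        tmax_idx = int(np.argmax(c))
        t, c = t[tmax_idx + 1 :], c[tmax_idx + 1 :]
    keep = c > 0
    t, c = t[keep], c[keep]
    if t.size < 3:
        return None, 0, None
    log_c = np.log(c)
    best: tuple[float, int, float] | None = None  # (r2_adj, n, lambda)
    for k in range(3, t.size + 1):
        slope, _, r2_adj = _adjusted_r2(log_c[-k:], t[-k:])
        if slope >= 0:
            continue
        # ties (to within regression noise) favour the longer window
        if best is None or r2_adj > best[0] + 1e-12 or abs(r2_adj - best[0]) <= 1e-12:
            best = (r2_adj, k, -slope)
    if best is None:
        return None, 0, None
    r2_adj, n_points, lam = best
    return lam, n_points, r2_adj


def _backextrapolate_c0(t: np.ndarray, c: np.ndarray) -> float:
    """Log-linear back-extrapolation of C(0) from the first two positive
    concentrations (iv bolus); falls back to the first value if the early
    profile is not declining."""
    pos = c > 0
    tp, cp = t[pos], c[pos]
    if tp.size < 2 or cp[1] >= cp[0]:
        return float(cp[0]) if tp.size else 0.0
    slope = (math.log(cp[1]) - math.log(cp[0])) / (tp[1] - tp[0])
    return float(cp[0] * math.exp(-slope * tp[0]))


def compute_auc(
    t: Sequence[float],
    c: Sequence[float],
    lambda_z: float | None,
    iv_back_extrapolate: bool = False,
) -> tuple[float, float | None, float | None]:
    """Linear-trapezoid ``AUC0-t`` plus the ``Clast/lambda_z`` tail.

    Zero (below-quantitation) concentrations are kept as zeros in the
    trapezoid.  With ``iv_back_extrapolate`` and a first sample after t=0,
    a back-extrapolated C0 closes the initial segment.  Returns
    ``(auc_0_t, auc_0_inf, extrapolated_fraction)`` with the latter two
    ``None`` when lambda_z is missing; the tail is zero when the profile
    ends at zero concentration.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if t.size != c.size or t.size < 2:
        raise DomainError("profile needs matching t/c arrays of length >= 2")
    if not (c > 0).any():
        raise DomainError("profile has no positive concentrations")
    tt, cc = t, c
    if iv_back_extrapolate and tt[0] > 0:
        c0 = _backextrapolate_c0(tt, cc)
        tt = np.concatenate(([0.0], tt))
        cc = np.concatenate(([c0], cc))
    auc_0_t = float(np.trapezoid(cc, tt))
    if auc_0_t <= 0:
        raise DomainError("AUC0-t must be positive")
    if lambda_z is None:
        return auc_0_t, None, None
    tail = float(cc[-1] / lambda_z) if cc[-1] > 0 else 0.0
    auc_inf = auc_0_t + tail
    frac = tail / auc_inf
    if frac > EXTRAPOLATION_WARN_FRACTION:
        warnings.warn(
            f"extrapolated AUC fraction {frac:.2f} exceeds "
            f"{EXTRAPOLATION_WARN_FRACTION}; the schedule may be too short",
            stacklevel=2,
        )
    return auc_0_t, auc_inf, frac


def compute_clearance(dose_mg: float, auc_0_inf: float) -> float:
    """``CL (L/h) = dose * 1e6 ng / AUC (ng/mL.h) / 1e3 mL/L``."""
    if auc_0_inf is None or auc_0_inf <= 0:
        raise DomainError("AUC0-inf must be positive to compute clearance")
    if dose_mg <= 0:
        raise DomainError("dose must be positive")
    return dose_mg * 1e6 / auc_0_inf / 1e3


def run_nca(profile: ConcentrationProfile) -> NCAResult:
    """Full NCA for one profile; route conventions applied automatically.

    iv-bolus profiles whose record starts with a zero pre-dose sample have
    that point dropped and C0 back-extrapolated for the AUC.
    """
    t = profile.t.copy()
    c = profile.c.copy()
    route = profile.dose.route
    is_iv = route == "iv_bolus"
    if is_iv and t.size and t[0] == 0.0 and c[0] == 0.0:
        t, c = t[1:], c[1:]  # pre-dose draw, not part of the iv decay
    lam, n_pts, r2 = estimate_lambda_z(t, c, exclude_tmax=not is_iv)
    auc_0_t, auc_inf, frac = compute_auc(
        t, c, lam, iv_back_extrapolate=is_iv and t[0] > 0
    )
    cmax_idx = int(np.argmax(c))
    cl = compute_clearance(profile.dose.amount, auc_inf) if auc_inf else None
    return NCAResult(
        subject_id=profile.subject_id,
        trial_id=profile.trial_id,
        dose_mg=profile.dose.amount,
        route=route,
        auc_0_t=auc_0_t,
        auc_0_inf=auc_inf,
        extrapolated_fraction=frac,
        cmax=float(c[cmax_idx]),
        tmax=float(t[cmax_idx]),
        lambda_z=lam,
        n_lambda_points=n_pts,
        r2_adj=r2,
        cl_over_f=cl,
    )


def nca_table(profiles: Sequence[ConcentrationProfile]):
    """One NCA row per profile as a DataFrame."""
    import pandas as pd
    from dataclasses import asdict

    return pd.DataFrame([asdict(run_nca(p)) for p in profiles])
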