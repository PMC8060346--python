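"""Observed-vs-predicted evaluation statistics.

The model-evaluation toolkit used in PBPK reporting: the
observed/predicted ratio R = obs/pred per PK parameter, the fold-error
(textually the same formula; both names are kept for traceability), the
average fold error ``AFE = 10**(mean log10 fold-error)`` (the geometric
mean of the ratios, a measure of prediction bias), the arithmetic mean
ratio with a Student-t 95 % confidence interval, the twofold criterion
(ratio within the closed interval [0.5, 2]), and per-timepoint visual
predictive check (VPC) summaries of simulated concentration profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, DomainError
from .pbpk_simulator import ConcentrationProfile

__all__ = [
    "ObsPredPair",
    "EvaluationSummary",
    "ratio_obs_pred",
    "fold_error",
    "average_fold_error",
    "mean_ratio_ci",
    "twofold_assessment",
    "summarize_pairs",
    "vpc_summary",
]

TWOFOLD_LOW, TWOFOLD_HIGH = 0.5, 2.0


@dataclass(frozen=True)
class ObsPredPair:
    """One observed/predicted PK-parameter pair."""

    study_ref: str
    population: str
    route: str
    dose: float  # mg
    parameter: str  # AUC0_inf | Cmax | CL
    observed: float
    predicted: float

    def __post_init__(self) -> None:
        if self.observed <= 0 or self.predicted <= 0:
            raise DomainError(
                f"{self.study_ref}/{self.parameter}: observed and predicted "
                "values must be positive"
            )

    @property
    def ratio(self) -> float:
        return self.observed / self.predicted


@dataclass(frozen=True)
class EvaluationSummary:
    """Aggregate statistics for one set of pairs."""

    n: int
    mean_ratio: float
    ci_low: float | None
    ci_high: float | None
    afe: float
    fraction_within_twofold: float


def ratio_obs_pred(pair: ObsPredPair) -> float:
    """Observed/predicted ratio (computed unrounded; round for display)."""
    return pair.ratio


def fold_error(pair: ObsPredPair) -> float:
    """Fold-error; the same obs/pred quotient as :func:`ratio_obs_pred`
    (the two published formulas coincide)."""
    return pair.ratio


def average_fold_error(pairs: Sequence[ObsPredPair]) -> float:
    """``AFE = 10**(sum(log10 fold-error) / N)`` -- the geometric mean of
    the signed ratios, not an absolute fold error."""
    if len(pairs) == 0:
        raise DomainError("AFE requires at least one pair")
    mean_log = sum(math.log10(fold_error(p)) for p in pairs) / len(pairs)
    return 10.0 ** mean_log


def mean_ratio_ci(
    pairs: Sequence[ObsPredPair], confidence: float = 0.95
) -> tuple[float, float | None, float | None]:
    """Arithmetic mean ratio with a Student-t confidence interval.

    ``mean +/- t(1-(1-confidence)/2, N-1) * sd / sqrt(N)`` on the unrounded
    ratios; with a single pair the CI is unavailable (``None`` bounds).
    """
    if len(pairs) == 0:
        raise DomainError("mean ratio requires at least one pair")
    ratios = np.array([p.ratio for p in pairs])
    mean = float(ratios.mean())
    if ratios.size < 2:
        return mean, None, None
    sd = float(ratios.std(ddof=1))
    tq = float(stats.t.ppf(0.5 + confidence / 2.0, ratios.size - 1))
    half = tq * sd / math.sqrt(ratios.size)
    return mean, mean - half, mean + half


def twofold_assessment(pairs: Sequence[ObsPredPair]) -> tuple[float, list[bool]]:
    """Fraction (and per-pair flags) of ratios within the closed twofold
    interval [0.5, 2]."""
    flags = [TWOFOLD_LOW <= p.ratio <= TWOFOLD_HIGH for p in pairs]
    fraction = sum(flags) / len(flags) if flags else float("nan")
    return fraction, flags


def summarize_pairs(pairs: Sequence[ObsPredPair]) -> EvaluationSummary:
    """All evaluation statistics for one group of pairs."""
    mean, lo, hi = mean_ratio_ci(pairs)
    fraction, _ = twofold_assessment(pairs)
    return EvaluationSummary(
        n=len(pairs),
        mean_ratio=mean,
        ci_low=lo,
        ci_high=hi,
        afe=average_fold_error(pairs),
        fraction_within_twofold=fraction,
    )


def summary_table(groups: dict[str, Sequence[ObsPredPair]]) -> pd.DataFrame:
    """Mean-ratio/AFE table over named groups (one row per group)."""
    rows = []
    for name, pairs in groups.items():
        s = summarize_pairs(pairs)
        rows.append(
            {
                "group": name,
                "n": s.n,
                "mean_ratio": s.mean_ratio,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "afe": s.afe,
                "fraction_within_twofold": s.fraction_within_twofold,
            }
        )
    return pd.DataFrame(rows)


def vpc_summary(profiles: Iterable[ConcentrationProfile]) -> pd.DataFrame:
    """Per-timepoint mean, 5th/95th percentiles, min and max (ng/mL).

    All profiles must share one sampling schedule; percentiles use the
    linear-interpolation convention.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise AlignmentError("a VPC summary needs at least 2 profiles")
    t0 = profiles[0].timepoints
    for p in profiles[1:]:
        if p.timepoints != t0:
            raise AlignmentError(
                f"profile {p.subject_id} is not on the common sampling schedule"
            )
    mat = np.array([p.concentrations for p in profiles])
    return pd.DataFrame(
        {
            "time_h": t0,
            "mean": mat.mean(axis=0),
            "p5": np.percentile(mat, 5, axis=0),
            "p95": np.percentile(mat, 95, axis=0),
            "min": mat.min(axis=0),
            "max": mat.max(axis=0),
        }
    )
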