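"""Virtual subjects and disease scaling.

Populations are described by :class:`PopulationSpec` (demographic ranges,
renal-function band, disease scaling factors and inter-individual
variability).  Sampling draws demographics uniformly within the study
ranges and applies median-preserving lognormal variability to clearances,
distribution volume and the absorption rate constant; a single clearance
multiplier is shared by the hepatic and renal components so the total
clearance carries exactly the configured coefficient of variation.

Disease physiology is applied to an already-sampled healthy-physiology
subject:

* chronic kidney disease — hepatic (non-renal) clearance is multiplied by a
  severity scaling factor (0.80 mild / 0.55 moderate / 0.35 severe), renal
  clearance scales proportionally with the sampled GFR relative to the
  healthy reference 120 mL/min, and Vss (with its Kp's) is multiplied by
  2.51;
* chronic heart failure — hepatic blood flow is reduced to the
  severity-specific fraction of normal (0.54 moderate / 0.46 severe),
  hepatic clearance is multiplied by 0.55, and the renal/peripheral flow
  fractions are recorded for reporting (renal clearance is left unscaled by
  default);
* geriatric — GFR and cardiac output (hence hepatic flow) decline linearly
  by 1 %/year above age 40 with a floor at 50 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .drug_model import DrugParameters, hepatic_availability
from .errors import ConfigurationError, ValidationError

__all__ = [
    "PopulationSpec",
    "VirtualSubject",
    "Variability",
    "builtin_specs",
    "get_spec",
    "sample_subject",
    "sample_population",
    "apply_ckd_scaling",
    "apply_chf_scaling",
    "apply_geriatric_scaling",
    "realize_subject",
    "GFR_REFERENCE",
    "CKD_HEPATIC_SF",
    "CKD_VSS_SF",
    "CHF_HEPATIC_SF",
    "CHF_FLOW_FRACTIONS",
]

#: Healthy-adult reference glomerular filtration rate, mL/min.
GFR_REFERENCE = 120.0

#: Hepatic (non-renal) clearance scaling factors by CKD severity.
CKD_HEPATIC_SF = {"mild": 0.80, "moderate": 0.55, "severe": 0.35}
#: Vss (and Kp) multiplier applied in all CKD severities.
CKD_VSS_SF = 2.51
#: GFR bands, mL/min (mild inferred from standard staging; moderate and
#: severe mirror the 30-60 and <30 renal-impairment populations).
CKD_GFR_BANDS = {"mild": (60.0, 90.0), "moderate": (30.0, 60.0), "severe": (15.0, 30.0)}

#: Hepatic clearance scaling factor in CHF.
CHF_HEPATIC_SF = 0.55
#: Organ blood-flow fractions of normal by CHF severity.
CHF_FLOW_FRACTIONS = {
    "mild": {"hepatic": 0.76, "renal": 0.78, "peripheral": 0.57},
    "moderate": {"hepatic": 0.54, "renal": 0.55, "peripheral": 0.44},
    "severe": {"hepatic": 0.46, "renal": 0.63, "peripheral": 0.28},
}

#: Geriatric decline: fraction lost per year above this age, with a floor.
GERIATRIC_ANCHOR_AGE = 40.0
GERIATRIC_DECLINE_PER_YEAR = 0.01
GERIATRIC_FLOOR = 0.50

#: Hepatic extraction ceiling: a sampled empirical clearance cannot exceed
#: what the liver blood flow can deliver, so cl_h is clamped below q_h.
MAX_HEPATIC_EXTRACTION = 0.95


def _cap_hepatic_clearance(cl_h: float, q_h: float) -> float:
    return min(cl_h, MAX_HEPATIC_EXTRACTION * q_h)


@dataclass(frozen=True)
class Variability:
    """Lognormal inter-individual coefficients of variation.

    Medians equal the typical values; ``cv_fa`` applies to the absorbed
    fraction with a cap at 1.  ``cv_q_h`` is the spread of hepatic blood
    flow around its typical value.
    """

    cv_clearance: float = 0.30
    cv_volume: float = 0.25
    cv_ka: float = 0.30
    cv_fa: float = 0.30
    cv_q_h: float = 0.15

    def sigma(self, cv: float) -> float:
        return math.sqrt(math.log1p(cv * cv))


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: demographics, renal function, disease
    scaling and variability."""

    name: str
    age_range: tuple[float, float] = (20.0, 50.0)
    weight_range: tuple[float, float] = (60.0, 85.0)
    fraction_female: float = 0.0
    gfr_range: tuple[float, float] = (100.0, 140.0)
    hepatic_sf: float = 1.0
    vss_sf: float = 1.0
    flow_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    severity_mix: dict[str, float] = field(default_factory=dict)
    q_h_typical: float = 90.0  # L/h, healthy hepatic blood flow
    variability: Variability = field(default_factory=Variability)
    scale_chf_renal_flow: bool = False  # propagate renal-flow fraction to CL_R

    def __post_init__(self) -> None:
        for rng_name in ("age_range", "weight_range", "gfr_range"):
            lo, hi = getattr(self, rng_name)
            if not (lo <= hi):
                raise ConfigurationError(f"{self.name}: degenerate {rng_name} ({lo} > {hi})")
        if not (0.0 <= self.fraction_female <= 1.0):
            raise ConfigurationError(f"{self.name}: fraction_female outside [0, 1]")
        if not (0.0 < self.hepatic_sf <= 1.0):
            raise ConfigurationError(f"{self.name}: hepatic_sf outside (0, 1]")
        if self.gfr_range[0] <= 0:
            raise ConfigurationError(f"{self.name}: gfr_range must be positive")

    def with_(self, **changes) -> "PopulationSpec":
        return replace(self, **changes)


def builtin_specs() -> dict[str, PopulationSpec]:
    """Registry of the built-in study populations."""
    return {
        "healthy": PopulationSpec(name="healthy"),
        "geriatric": PopulationSpec(name="geriatric", age_range=(65.0, 80.0)),
        "ckd_mild": PopulationSpec(
            name="ckd_mild", gfr_range=CKD_GFR_BANDS["mild"],
            hepatic_sf=CKD_HEPATIC_SF["mild"], vss_sf=CKD_VSS_SF,
        ),
        "ckd_moderate": PopulationSpec(
            name="ckd_moderate", gfr_range=CKD_GFR_BANDS["moderate"],
            hepatic_sf=CKD_HEPATIC_SF["moderate"], vss_sf=CKD_VSS_SF,
        ),
        "ckd_severe": PopulationSpec(
            name="ckd_severe", gfr_range=CKD_GFR_BANDS["severe"],
            hepatic_sf=CKD_HEPATIC_SF["severe"], vss_sf=CKD_VSS_SF,
        ),
        "chf": PopulationSpec(
            name="chf", age_range=(47.0, 71.0),
            hepatic_sf=CHF_HEPATIC_SF,
            flow_fractions=dict(CHF_FLOW_FRACTIONS),
            severity_mix={"moderate": 0.5, "severe": 0.5},
        ),
    }


def get_spec(name: str) -> PopulationSpec:
    specs = builtin_specs()
    try:
        return specs[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown population {name!r}; expected one of {sorted(specs)}"
        ) from None


@dataclass
class VirtualSubject:
    """One sampled individual: physiology plus individualized drug
    parameters (all clearances L/h, volumes L, flows L/h)."""

    subject_id: int
    trial_id: int
    age: float
    sex: str
    weight: float
    gfr: float  # mL/min
    q_h: float
    cl_h: float
    cl_r: float
    vss_per_kg: float
    ka_i: float
    fa_i: float
    severity_tag: str | None = None
    scaling_applied: str | None = None
    flow_fractions: dict[str, float] = field(default_factory=dict)
    kin: float = 0.25
    kout: float = 0.25

    def __post_init__(self) -> None:
        if self.cl_h + self.cl_r <= 0:
            raise ValidationError(f"subject {self.subject_id}: total clearance must be positive")
        if self.gfr <= 0:
            raise ValidationError(f"subject {self.subject_id}: gfr must be positive")
        if self.q_h <= self.cl_h:
            raise ValidationError(
                f"subject {self.subject_id}: hepatic flow ({self.q_h:.3g} L/h) must "
                f"exceed hepatic clearance ({self.cl_h:.3g} L/h) under the "
                "well-stirred contract"
            )
        if self.vss_per_kg <= 0 or self.weight <= 0:
            raise ValidationError(f"subject {self.subject_id}: volumes must be positive")

    @property
    def cl_total(self) -> float:
        return self.cl_h + self.cl_r

    @property
    def vss_total(self) -> float:
        return self.vss_per_kg * self.weight

    @property
    def vc(self) -> float:
        """Central volume from steady-state amount partitioning
        ``Vsac/Vc = kin/kout``."""
        return self.vss_total / (1.0 + self.kin / self.kout)

    @property
    def fh(self) -> float:
        return hepatic_availability(self.cl_h, self.q_h)

    @property
    def f_oral(self) -> float:
        """Per-subject oral bioavailability ``fa * Fh``."""
        return self.fa_i * self.fh


def _uniform(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    lo, hi = lo_hi
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _lognormal_mult(rng: np.random.Generator, sigma: float) -> float:
    # median-preserving: multiplier has median 1 and sample CV matching sigma
    return float(math.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0


def sample_subject(
    spec: PopulationSpec,
    drug: DrugParameters,
    rng: np.random.Generator,
    subject_id: int = 0,
    trial_id: int = 0,
) -> VirtualSubject:
    """Draw one healthy-physiology subject from a population spec.

    Demographics and GFR are uniform within the spec ranges; clearances,
    Vss, ka, fa and hepatic flow get lognormal variability (one shared
    multiplier for the two clearance components).  Disease scaling is NOT
    applied here; see :func:`realize_subject`.
    """
    v = spec.variability
    age = _uniform(rng, spec.age_range)
    sex = "F" if rng.uniform() < spec.fraction_female else "M"
    weight = _uniform(rng, spec.weight_range)
    gfr = _uniform(rng, spec.gfr_range)
    cl_mult = _lognormal_mult(rng, v.sigma(v.cv_clearance))
    vss_mult = _lognormal_mult(rng, v.sigma(v.cv_volume))
    ka_mult = _lognormal_mult(rng, v.sigma(v.cv_ka))
    fa_mult = _lognormal_mult(rng, v.sigma(v.cv_fa))
    qh_mult = _lognormal_mult(rng, v.sigma(v.cv_q_h))
    q_h = spec.q_h_typical * qh_mult
    return VirtualSubject(
        subject_id=subject_id,
        trial_id=trial_id,
        age=age,
        sex=sex,
        weight=weight,
        gfr=gfr,
        q_h=q_h,
        cl_h=_cap_hepatic_clearance(drug.cl_h * cl_mult, q_h),
        cl_r=drug.cl_r * cl_mult,
        vss_per_kg=drug.vss_per_kg * vss_mult,
        ka_i=drug.ka * ka_mult,
        fa_i=min(1.0, drug.fa * fa_mult),
        kin=drug.kin,
        kout=drug.kout,
    )


def _require_unscaled(subject: VirtualSubject) -> None:
    if subject.scaling_applied is not None:
        raise ValidationError(
            f"subject {subject.subject_id} already carries "
            f"{subject.scaling_applied!r} scaling; disease scaling is not "
            "idempotent and may be applied once"
        )


def apply_ckd_scaling(
    subject: VirtualSubject,
    severity: str,
    drug: DrugParameters,
    gfr_reference: float = GFR_REFERENCE,
) -> VirtualSubject:
    """Chronic-kidney-disease scaling of one subject.

    ``cl_h x SF(severity)``, ``cl_r x gfr/gfr_reference``, ``vss x 2.51``.
    The subject's GFR must lie in the severity band.
    """
    _require_unscaled(subject)
    if severity not in CKD_HEPATIC_SF:
        raise ValidationError(f"unknown CKD severity {severity!r}")
    lo, hi = CKD_GFR_BANDS[severity]
    if not (lo <= subject.gfr <= hi):
        raise ValidationError(
            f"subject {subject.subject_id}: GFR {subject.gfr:.1f} mL/min outside "
            f"the {severity} band [{lo}, {hi}]"
        )
    out = replace(
        subject,
        cl_h=subject.cl_h * CKD_HEPATIC_SF[severity],
        cl_r=subject.cl_r * (subject.gfr / gfr_reference),
        vss_per_kg=subject.vss_per_kg * CKD_VSS_SF,
        severity_tag=severity,
        scaling_applied=f"ckd_{severity}",
    )
    return out


def apply_chf_scaling(
    subject: VirtualSubject,
    severity: str,
    drug: DrugParameters,
    scale_renal_flow: bool = False,
) -> VirtualSubject:
    """Chronic-heart-failure scaling of one subject.

    Hepatic flow is reduced to the severity fraction of normal and hepatic
    clearance multiplied by 0.55.  The renal and peripheral flow fractions
    are recorded; renal clearance is only scaled when ``scale_renal_flow``
    is set (off by default).
    """
    _require_unscaled(subject)
    if severity not in CHF_FLOW_FRACTIONS:
        raise ValidationError(f"unknown CHF severity {severity!r}")
    fractions = CHF_FLOW_FRACTIONS[severity]
    cl_r = subject.cl_r * fractions["renal"] if scale_renal_flow else subject.cl_r
    q_h = subject.q_h * fractions["hepatic"]
    return replace(
        subject,
        q_h=q_h,
        cl_h=_cap_hepatic_clearance(subject.cl_h * CHF_HEPATIC_SF, q_h),
        cl_r=cl_r,
        severity_tag=severity,
        scaling_applied=f"chf_{severity}",
        flow_fractions=dict(fractions),
    )


def apply_geriatric_scaling(subject: VirtualSubject, drug: DrugParameters) -> VirtualSubject:
    """Age-related decline: GFR, metabolic organ clearances (hepatic and
    renal) and cardiac output (hence hepatic flow) all fall 1 %/year above
    age 40 with a floor at 50 %.  Flow and hepatic clearance scale together,
    so first-pass availability is age-invariant while CL/F falls."""
    _require_unscaled(subject)
    decline = max(
        GERIATRIC_FLOOR,
        1.0 - GERIATRIC_DECLINE_PER_YEAR * max(0.0, subject.age - GERIATRIC_ANCHOR_AGE),
    )
    q_h = subject.q_h * decline
    return replace(
        subject,
        gfr=subject.gfr * decline,
        cl_r=subject.cl_r * decline,
        q_h=q_h,
        cl_h=_cap_hepatic_clearance(subject.cl_h * decline, q_h),
        severity_tag="geriatric",
        scaling_applied="geriatric",
    )


def realize_subject(
    spec: PopulationSpec,
    drug: DrugParameters,
    rng: np.random.Generator,
    subject_id: int = 0,
    trial_id: int = 0,
) -> VirtualSubject:
    """Sample a subject and apply the scaling its population requires."""
    subject = sample_subject(spec, drug, rng, subject_id, trial_id)
    if spec.name.startswith("ckd_"):
        severity = spec.name.removeprefix("ckd_")
        return apply_ckd_scaling(subject, severity, drug)
    if spec.name == "chf":
        severities = sorted(spec.severity_mix)
        weights = np.array([spec.severity_mix[s] for s in severities], dtype=float)
        severity = str(rng.choice(severities, p=weights / weights.sum()))
        return apply_chf_scaling(subject, severity, drug, spec.scale_chf_renal_flow)
    if spec.name == "geriatric":
        return apply_geriatric_scaling(subject, drug)
    return subject


def sample_population(
    spec: PopulationSpec,
    drug: DrugParameters,
    n_trials: int,
    n_per_trial: int,
    seed: int,
) -> list[VirtualSubject]:
    """Deterministically sample ``n_trials x n_per_trial`` subjects."""
    if n_trials < 1 or n_per_trial < 1:
        raise ConfigurationError("trial design must use positive integers")
    rng = np.random.default_rng(seed)
    subjects = []
    sid = 0
    for trial in range(n_trials):
        for _ in range(n_per_trial):
            subjects.append(realize_subject(spec, drug, rng, subject_id=sid, trial_id=trial))
            sid += 1
    return subjects


def median_oral_bioavailability(subjects: Iterable[VirtualSubject]) -> float:
    """Population median of per-subject oral bioavailability."""
    return float(np.median([s.f_oral for s in subjects]))
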