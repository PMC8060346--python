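"""Drug parameterization, tissue partitioning and hepatic first-pass loss.

The captopril model is driven by a small set of physicochemical and
empirical parameters (:class:`DrugParameters`).  Steady-state distribution
is predicted mechanistically with the Rodgers-Rowland tissue-composition
method (the acids / very weak bases / neutrals branch, often called
"method 2"): each tissue-to-plasma partition coefficient Kp combines
ionization-corrected water partitioning, neutral-lipid and phospholipid
partitioning via the octanol-water partition coefficient, and albumin-type
protein binding inferred from the plasma unbound fraction.  Oral
bioavailability follows the well-stirred liver contract
``F = fa * (1 - CLh/Qh)`` with gut availability fixed at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError, DomainError, ValidationError

__all__ = [
    "DrugParameters",
    "TissueCompositionTable",
    "PartitionResult",
    "load_captopril_parameters",
    "load_tissue_composition",
    "compute_kp_rodgers_rowland",
    "compute_vss",
    "predict_partition",
    "erythrocyte_to_plasma_ratio",
    "hepatic_availability",
    "oral_bioavailability",
    "PLASMA_VOLUME_FRACTION",
    "ERYTHROCYTE_VOLUME_FRACTION",
    "PLASMA_PH",
    "INTRACELLULAR_PH",
]

#: Plasma and erythrocyte volumes per kg body weight (L/kg, reference adult).
PLASMA_VOLUME_FRACTION = 0.0424
ERYTHROCYTE_VOLUME_FRACTION = 0.0347

PLASMA_PH = 7.4
INTRACELLULAR_PH = 7.0

#: Neutral lipid / neutral phospholipid volume fractions of plasma.
PLASMA_NEUTRAL_LIPID_FRACTION = 0.0023
PLASMA_NEUTRAL_PHOSPHOLIPID_FRACTION = 0.0013

IONIZATION_CLASSES = {"monoprotic_acid", "monoprotic_base", "neutral"}


@dataclass(frozen=True)
class DrugParameters:
    """Drug-specific model inputs (units noted per field).

    ``cl_iv`` is the total systemic plasma clearance and ``cl_r`` its renal
    component; the hepatic (non-renal) part is ``cl_h = cl_iv - cl_r``.
    """

    molecular_weight: float  # g/mol
    logP: float
    pKa: float
    ionization_class: str
    ka: float  # 1/h
    tlag: float  # h
    fa: float
    kin: float  # 1/h
    kout: float  # 1/h
    bp_ratio: float
    fu: float
    vss_per_kg: float  # L/kg
    cl_iv: float  # L/h
    cl_r: float  # L/h

    def __post_init__(self) -> None:
        if self.ionization_class not in IONIZATION_CLASSES:
            raise ValidationError(
                f"unknown ionization_class {self.ionization_class!r}; "
                f"expected one of {sorted(IONIZATION_CLASSES)}"
            )
        checks = {
            "fa": 0.0 < self.fa <= 1.0,
            "fu": 0.0 < self.fu <= 1.0,
            "bp_ratio": self.bp_ratio > 0.0,
            "ka": self.ka > 0.0,
            "kin": self.kin > 0.0,
            "kout": self.kout > 0.0,
            "tlag": self.tlag >= 0.0,
            "vss_per_kg": self.vss_per_kg > 0.0,
            "cl_iv": self.cl_iv > 0.0,
            "cl_r": self.cl_r >= 0.0,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValidationError(f"invalid drug parameter(s): {', '.join(bad)}")
        if self.cl_r > self.cl_iv:
            raise ValidationError(
                "renal clearance exceeds total clearance "
                f"(cl_r={self.cl_r} > cl_iv={self.cl_iv}); hepatic clearance "
                "would be negative"
            )

    @property
    def cl_h(self) -> float:
        """Hepatic (non-renal) plasma clearance, L/h."""
        return self.cl_iv - self.cl_r

    @classmethod
    def from_dict(cls, values: Mapping[str, object]) -> "DrugParameters":
        names = {f for f in cls.__dataclass_fields__}
        unknown = set(values) - names
        if unknown:
            raise ConfigurationError(f"unknown drug parameter keys: {sorted(unknown)}")
        missing = names - set(values)
        if missing:
            raise ConfigurationError(f"missing drug parameter keys: {sorted(missing)}")
        kwargs = {k: (v if k == "ionization_class" else float(v)) for k, v in values.items()}  # type: ignore[arg-type]
        return cls(**kwargs)  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path) -> "DrugParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"drug parameter file {path} is not a mapping")
        return cls.from_dict(data)

    def with_(self, **changes) -> "DrugParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class TissueCompositionTable:
    """Per-tissue composition used by the partitioning method.

    Columns: fractional volumes of extracellular water (``f_ew``),
    intracellular water (``f_iw``), neutral lipid (``f_nl``) and neutral
    phospholipid (``f_np``); the albumin tissue:plasma concentration ratio
    (``albumin_ratio``); and the tissue volume per kg body weight
    (``volume_frac``, L/kg).
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("f_ew", "f_iw", "f_nl", "f_np", "albumin_ratio", "volume_frac")

    def __post_init__(self) -> None:
        df = self.table
        if "tissue" in df.columns:
            df = df.set_index("tissue")
            object.__setattr__(self, "table", df)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ConfigurationError(f"tissue table missing column(s): {missing}")
        if df.isna().any().any():
            raise ConfigurationError("tissue table contains missing values")
        frac_cols = ["f_ew", "f_iw", "f_nl", "f_np", "volume_frac"]
        if ((df[frac_cols] < 0) | (df[frac_cols] > 1)).any().any():
            raise ConfigurationError("tissue fractions must lie in [0, 1]")
        if (df["albumin_ratio"] < 0).any():
            raise ConfigurationError("albumin ratios must be non-negative")
        if df["volume_frac"].sum() >= 1.0:
            raise ConfigurationError(
                "per-tissue body-volume fractions must sum to < 1 "
                "(remainder is plasma and erythrocytes)"
            )

    @property
    def tissues(self) -> list[str]:
        return list(self.table.index)

    def row(self, tissue: str) -> pd.Series:
        try:
            return self.table.loc[tissue]
        except KeyError:
            raise ConfigurationError(f"tissue composition row missing: {tissue!r}") from None

    @classmethod
    def from_csv(cls, path) -> "TissueCompositionTable":
        return cls(pd.read_csv(path, comment="#"))


@dataclass(frozen=True)
class PartitionResult:
    """Tissue-to-plasma partition coefficients and the Vss they imply."""

    kp_per_tissue: dict[str, float]
    vss_per_kg: float  # L/kg

    def __post_init__(self) -> None:
        if any(not (kp > 0 and math.isfinite(kp)) for kp in self.kp_per_tissue.values()):
            raise ValidationError("all Kp values must be finite and positive")
        if self.vss_per_kg < PLASMA_VOLUME_FRACTION:
            raise ValidationError(
                "Vss cannot fall below the plasma volume fraction "
                f"({PLASMA_VOLUME_FRACTION} L/kg)"
            )


def _data_path(name: str):
    return resources.files("captopbpk.data").joinpath(name)


def load_captopril_parameters() -> DrugParameters:
    """Packaged captopril parameter set."""
    with resources.as_file(_data_path("captopril.yaml")) as path:
        return DrugParameters.from_yaml(path)


def load_tissue_composition() -> TissueCompositionTable:
    """Packaged tissue-composition constants."""
    with resources.as_file(_data_path("tissue_composition.csv")) as path:
        return TissueCompositionTable.from_csv(path)


def _ionization_terms(drug: DrugParameters) -> tuple[float, float]:
    """Return (X, Y): intracellular-to-plasma total:unbound-water ratio and
    the plasma neutral fraction 1/(1 + ionized:neutral).

    For a monoprotic acid the ionized:neutral ratio at pH is
    ``10**(pH - pKa)``; neutrals carry no ionization correction.
    """
    if drug.ionization_class == "monoprotic_acid":
        ion_plasma = 10.0 ** (PLASMA_PH - drug.pKa)
        ion_cell = 10.0 ** (INTRACELLULAR_PH - drug.pKa)
        x = (1.0 + ion_cell) / (1.0 + ion_plasma)
        y = 1.0 / (1.0 + ion_plasma)
        return x, y
    if drug.ionization_class == "neutral":
        return 1.0, 1.0
    raise DomainError(
        "the partitioning method is implemented for the acids/neutrals "
        f"branch only; got ionization_class={drug.ionization_class!r}"
    )


def compute_kp_rodgers_rowland(
    drug: DrugParameters,
    tissues: TissueCompositionTable,
    *,
    plasma_f_nl: float = PLASMA_NEUTRAL_LIPID_FRACTION,
    plasma_f_np: float = PLASMA_NEUTRAL_PHOSPHOLIPID_FRACTION,
) -> dict[str, float]:
    """Tissue-to-plasma partition coefficients, acids/neutrals branch.

    Per tissue ``t`` the unbound partition coefficient is::

        Kpu_t = f_ew + X * f_iw
              + Y * (P * f_nl + (0.3 P + 0.7) * f_np)
              + KaPR * albumin_ratio_t

    with ``P = 10**logP``, ``X`` the intracellular:plasma total-drug water
    ratio, ``Y`` the neutral fraction in plasma, and the albumin association
    constant recovered from the plasma unbound fraction::

        KaPR = 1/fu - 1 - Y * (P * f_nl,p + (0.3 P + 0.7) * f_np,p)

    The reported ``Kp_t = fu * Kpu_t``.
    """
    if not (0.0 < drug.fu <= 1.0):
        raise DomainError("fraction unbound in plasma must lie in (0, 1]")
    x, y = _ionization_terms(drug)
    p = 10.0 ** drug.logP
    plasma_lipid = y * (p * plasma_f_nl + (0.3 * p + 0.7) * plasma_f_np)
    ka_pr = 1.0 / drug.fu - 1.0 - plasma_lipid
    kp: dict[str, float] = {}
    for tissue in tissues.tissues:
        row = tissues.row(tissue)
        kpu = (
            row["f_ew"]
            + x * row["f_iw"]
            + y * (p * row["f_nl"] + (0.3 * p + 0.7) * row["f_np"])
            + ka_pr * row["albumin_ratio"]
        )
        kp[tissue] = drug.fu * kpu
    return kp


def compute_vss(
    kp_per_tissue: Mapping[str, float],
    tissues: TissueCompositionTable,
    erythrocyte_partition: float,
    hematocrit: float = 0.45,
) -> float:
    """Steady-state volume of distribution per kg body weight.

    ``Vss = Vplasma + VE * (E:P) + sum_t Vt * Kp_t`` with all volumes in
    L/kg.  Strictly increasing in every Kp.
    """
    if erythrocyte_partition < 0:
        raise DomainError("erythrocyte:plasma partition must be >= 0")
    if not 0 < hematocrit < 1:
        raise DomainError("hematocrit must lie in (0, 1)")
    missing = [t for t in tissues.tissues if t not in kp_per_tissue]
    if missing:
        raise ConfigurationError(f"Kp missing for tissue(s): {missing}")
    tissue_sum = sum(
        tissues.row(t)["volume_frac"] * kp_per_tissue[t] for t in tissues.tissues
    )
    return (
        PLASMA_VOLUME_FRACTION
        + ERYTHROCYTE_VOLUME_FRACTION * erythrocyte_partition
        + tissue_sum
    )


def erythrocyte_to_plasma_ratio(bp_ratio: float, hematocrit: float = 0.45) -> float:
    """Erythrocyte:plasma concentration ratio implied by B/P and hematocrit:
    ``E:P = (B/P - (1 - Hct)) / Hct`` (equals 1 when B/P = 1)."""
    if not 0 < hematocrit < 1:
        raise DomainError("hematocrit must lie in (0, 1)")
    ep = (bp_ratio - (1.0 - hematocrit)) / hematocrit
    if ep < 0:
        raise DomainError(
            f"B/P={bp_ratio} with hematocrit {hematocrit} implies a negative "
            "erythrocyte partition"
        )
    return ep


def predict_partition(
    drug: DrugParameters,
    tissues: TissueCompositionTable | None = None,
    hematocrit: float = 0.45,
) -> PartitionResult:
    """Kp per tissue and the resulting Vss (L/kg) for one drug."""
    if tissues is None:
        tissues = load_tissue_composition()
    kp = compute_kp_rodgers_rowland(drug, tissues)
    ep = erythrocyte_to_plasma_ratio(drug.bp_ratio, hematocrit)
    vss = compute_vss(kp, tissues, ep, hematocrit)
    return PartitionResult(kp_per_tissue=kp, vss_per_kg=vss)


def hepatic_availability(cl_h_blood: float, q_h: float) -> float:
    """Well-stirred hepatic availability ``Fh = 1 - CLh/Qh``.

    ``cl_h_blood`` is hepatic blood clearance (equals plasma clearance here
    since B/P = 1) and ``q_h`` hepatic blood flow, both L/h.
    """
    if q_h <= 0:
        raise DomainError("hepatic blood flow must be positive")
    if cl_h_blood < 0:
        raise DomainError("hepatic clearance must be non-negative")
    if cl_h_blood >= q_h:
        raise DomainError(
            f"hepatic clearance ({cl_h_blood} L/h) must be below hepatic "
            f"blood flow ({q_h} L/h): extraction cannot exceed flow"
        )
    return 1.0 - cl_h_blood / q_h


def oral_bioavailability(drug: DrugParameters, q_h: float) -> float:
    """Oral bioavailability ``F = fa * Fh`` (gut availability fixed at 1)."""
    return drug.fa * hepatic_availability(drug.cl_h, q_h)
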