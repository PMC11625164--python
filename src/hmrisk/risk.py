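"""Deterministic dietary exposure and health-risk equations.

Implements the USEPA-style ingestion-route chain for fish consumption:

    EDI = (EFr * ED * FIR * Cm) / (BW * TA) * 1e-3      [mg/kg/day]
    THQ = EDI / RfD                                      [-]
    HI  = sum of THQs over co-occurring metals           [-]
    TR  = EDI * CSF                                      [-]

with Cm the mean wet-weight concentration in the consumed tissue (mg/kg),
FIR the intake rate (g/day, hence the 1e-3), BW body weight (kg), EFr
exposure frequency (days/year), ED exposure duration (years) and TA the
averaging time (days). For chronic lifetime scenarios TA = EFr * ED and the
scenario factor cancels; it is computed rather than assumed so shorter
exposure windows stay expressible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ExposureScenario",
    "ToxProfile",
    "RiskTable",
    "edi",
    "thq",
    "hazard_index",
    "tr",
    "classify_tr",
    "flag_ptdi",
    "build_risk_table",
]

#: USEPA carcinogenic-risk bands: below 1e-6 negligible, above 1e-4
#: unacceptable. Both boundaries fall in the middle (tolerable) band.
TR_NEGLIGIBLE_BELOW = 1e-6
TR_UNACCEPTABLE_ABOVE = 1e-4


@dataclass(frozen=True)
class ExposureScenario:
    """Consumer-group parameters of the intake equation."""

    label: str
    body_weight_kg: float
    intake_rate_g_per_day: float
    exposure_frequency_days_per_year: float = 365.0
    exposure_duration_years: float = 72.3
    averaging_time_days: float = 365.0 * 72.3

    def __post_init__(self) -> None:
        for name in (
            "body_weight_kg",
            "intake_rate_g_per_day",
            "exposure_frequency_days_per_year",
            "exposure_duration_years",
            "averaging_time_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"scenario {self.label!r}: {name} must be strictly positive"
                )

    @property
    def is_chronic(self) -> bool:
        """True when TA equals EFr * ED, i.e. the scenario factor is 1."""
        return math.isclose(
            self.averaging_time_days,
            self.exposure_frequency_days_per_year * self.exposure_duration_years,
            rel_tol=1e-9,
        )

    @property
    def daily_intake_factor(self) -> float:
        """(EFr * ED * FIR) / (BW * TA) * 1e-3 — EDI per unit Cm."""
        return (
            self.exposure_frequency_days_per_year
            * self.exposure_duration_years
            * self.intake_rate_g_per_day
        ) / (self.body_weight_kg * self.averaging_time_days) * 1e-3


@dataclass(frozen=True)
class ToxProfile:
    """Per-metal toxicological reference values (mg/kg/day scale).

    A missing RfD means no hazard quotient is defined; a missing CSF means
    the metal is not assessed for carcinogenic risk (e.g. Cu, an essential
    element); a missing PTDI means no intake benchmark comparison.
    """

    metal: str
    rfd: float | None = None
    csf: float | None = None
    ptdi: float | None = None

    def __post_init__(self) -> None:
        for name in ("rfd", "csf", "ptdi"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{self.metal}: {name} must be positive when present")


def edi(cm_ww: float, scenario: ExposureScenario) -> float:
    """Estimated daily intake, mg per kg body weight per day.

    Linear through the origin in ``cm_ww`` (mg/kg wet weight) and in the
    intake rate, inverse in body weight.
    """
    if cm_ww < 0:
        raise ValueError("mean concentration must be non-negative")
    return cm_ww * scenario.daily_intake_factor


def thq(edi_value: float, rfd: float) -> float:
    """Target hazard quotient EDI/RfD; above 1 flags potential noncancer risk."""
    if rfd <= 0:
        raise ValueError("RfD must be strictly positive")
    if edi_value < 0:
        raise ValueError("EDI must be non-negative")
    return edi_value / rfd


def hazard_index(thqs: Iterable[float]) -> float:
    """Hazard index: the sum of quotients, treating toxic effects as additive."""
    values = list(thqs)
    if not values:
        raise ValueError("hazard index of an empty collection is undefined")
    if any(v < 0 for v in values):
        raise ValueError("hazard quotients must be non-negative")
    return float(sum(values))


def tr(edi_value: float, csf: float) -> float:
    """Incremental lifetime carcinogenic risk, EDI * CSF."""
    if csf <= 0:
        raise ValueError("CSF must be strictly positive")
    if edi_value < 0:
        raise ValueError("EDI must be non-negative")
    return edi_value * csf


def classify_tr(tr_value: float) -> str:
    """Band a lifetime risk: negligible (<1e-6), tolerable, unacceptable (>1e-4)."""
    if tr_value < 0:
        raise ValueError("carcinogenic risk must be non-negative")
    if tr_value < TR_NEGLIGIBLE_BELOW:
        return "negligible"
    if tr_value > TR_UNACCEPTABLE_ABOVE:
        return "unacceptable"
    return "tolerable"


def flag_ptdi(edi_value: float, ptdi: float) -> tuple[bool, float]:
    """Compare an intake against a provisional tolerable daily intake.

    Returns (exceeds, ratio); equality is compliant.
    """
    if ptdi <= 0:
        raise ValueError("PTDI must be strictly positive")
    return edi_value > ptdi, edi_value / ptdi


@dataclass(frozen=True)
class RiskTable:
    """Risk-engine output: per-metal quantities and per-group hazard indices.

    ``per_metal`` has one row per (species, scenario, metal) with columns
    ``edi``, ``thq``, ``tr``, ``tr_class``, ``ptdi_exceeds``, ``ptdi_ratio``
    (NaN/None where the ToxProfile lacks the needed constant); ``hi`` has
    one row per (species, scenario).
    """

    per_metal: pd.DataFrame
    hi: pd.DataFrame


def build_risk_table(
    summaries: pd.DataFrame,
    scenarios: Sequence[ExposureScenario],
    tox: Mapping[str, ToxProfile],
) -> RiskTable:
    """Cross every pooled concentration with every scenario.

    ``summaries`` is the pooled output of
    :func:`hmrisk.concentrations.summarize_concentrations`. Every species
    must cover every metal present in ``tox``; a species with a missing
    metal is rejected outright rather than zero-filled.
    """
    if not len(scenarios):
        raise ValueError("at least one exposure scenario is required")
    need = set(tox)
    have = summaries.groupby("species_id")["metal"].agg(set)
    for species_id, metals in have.items():
        lacking = sorted(need - metals)
        if lacking:
            raise ValueError(
                f"species {species_id!r} lacks concentrations for: {', '.join(lacking)}"
            )

    rows = []
    for _, s in summaries.iterrows():
        metal = s["metal"]
        if metal not in tox:
            continue
        t = tox[metal]
        for sc in scenarios:
            e = edi(float(s["mean_ww"]), sc)
            q = thq(e, t.rfd) if t.rfd is not None else None
            r = tr(e, t.csf) if t.csf is not None else None
            exceeds, ratio = flag_ptdi(e, t.ptdi) if t.ptdi is not None else (None, None)
            rows.append(
                {
                    "species_id": s["species_id"],
                    "scenario": sc.label,
                    "metal": metal,
                    "cm_ww": float(s["mean_ww"]),
                    "edi": e,
                    "thq": q,
                    "tr": r,
                    "tr_class": classify_tr(r) if r is not None else None,
                    "ptdi_exceeds": exceeds,
                    "ptdi_ratio": ratio,
                }
            )
    per_metal = pd.DataFrame(rows).sort_values(
        ["scenario", "species_id", "metal"], ignore_index=True
    )

    hi = (
        per_metal.dropna(subset=["thq"])
        .groupby(["species_id", "scenario"], as_index=False)["thq"]
        .sum()
        .rename(columns={"thq": "hi"})
        .sort_values(["scenario", "species_id"], ignore_index=True)
    )
    return RiskTable(per_metal=per_metal, hi=hi)
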