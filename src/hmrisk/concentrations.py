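"""Sample-level concentration handling.

Reads, validates, censor-substitutes, basis-converts and aggregates
measurements of trace-metal concentrations in fish muscle into the
per-species mean wet-weight concentrations (Cm) that feed the exposure
equations.

Censoring convention: a record reported below the detection limit (BDL)
carries no value, a ``censored`` flag and the detection limit on the
measurement basis; the substitution rule replaces it by half the limit
(LOD/2), the standard simple substitution for left-censored trace data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

METALS: tuple[str, ...] = ("Cr", "Pb", "Cu", "Cd", "As")
SEASONS: tuple[str, ...] = ("dry", "wet")
FEEDING_HABITS: tuple[str, ...] = ("carnivore", "omnivore", "herbivore")
BASES: tuple[str, ...] = ("dry_weight", "wet_weight")

#: Column schema of a tidy measurement table (one row per observation).
MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "species_id",
    "season",
    "metal",
    "value",
    "basis",
    "censored",
    "detection_limit",
)


@dataclass(frozen=True)
class Measurement:
    """One concentration observation, possibly left-censored.

    ``value`` (mg/kg on ``basis``) is present exactly when the record is
    not censored; a censored record instead carries the positive
    ``detection_limit`` on the same basis.
    """

    sample_id: str
    species_id: str
    season: str
    metal: str
    value: float | None
    basis: str
    censored: bool
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(
                f"sample {self.sample_id!r}: season {self.season!r} not in {SEASONS}"
            )
        if self.metal not in METALS:
            raise ValueError(
                f"sample {self.sample_id!r}: metal {self.metal!r} not in {METALS}"
            )
        if self.basis not in BASES:
            raise ValueError(
                f"sample {self.sample_id!r}: basis {self.basis!r} not in {BASES}"
            )
        if self.censored:
            if self.value is not None and not (
                isinstance(self.value, float) and np.isnan(self.value)
            ):
                raise ValueError(
                    f"sample {self.sample_id!r}: censored record must not carry a value"
                )
            if not self.detection_limit or self.detection_limit <= 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: censored record needs a positive "
                    f"detection limit (got {self.detection_limit!r})"
                )
        else:
            if self.value is None or (
                isinstance(self.value, float) and np.isnan(self.value)
            ):
                raise ValueError(
                    f"sample {self.sample_id!r}: uncensored record needs a value"
                )
            if self.value < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: negative concentration {self.value}"
                )


@dataclass(frozen=True)
class SpeciesProfile:
    """Taxon identity, feeding habit and tissue moisture of one species."""

    species_id: str
    scientific_name: str
    local_name: str
    feeding_habit: str
    moisture_fraction: float

    def __post_init__(self) -> None:
        if self.feeding_habit not in FEEDING_HABITS:
            raise ValueError(
                f"species {self.species_id!r}: feeding habit "
                f"{self.feeding_habit!r} not in {FEEDING_HABITS}"
            )
        if not 0.0 < self.moisture_fraction < 1.0:
            raise ValueError(
                f"species {self.species_id!r}: moisture fraction must lie in "
                f"(0, 1), got {self.moisture_fraction}"
            )


def substitute_censored(m: Measurement) -> float:
    """Concentration to use for one record, on its own basis.

    Uncensored records pass through unchanged; censored (BDL) records are
    replaced by half their detection limit.
    """
    if not m.censored:
        return float(m.value)  # type: ignore[arg-type]
    # Measurement.__post_init__ already rejects a censored record without a
    # positive detection limit, so this is a belt-and-braces message for
    # records built by other means.
    if not m.detection_limit or m.detection_limit <= 0:
        raise ValueError(
            f"sample {m.sample_id!r}: cannot substitute a censored record "
            f"without a positive detection limit"
        )
    return m.detection_limit / 2.0


def dw_to_ww(c_dw: float | np.ndarray, moisture_fraction: float) -> float | np.ndarray:
    """Convert a dry-weight concentration to wet (fresh) weight.

    C_ww = C_dw * (1 - moisture_fraction): the analyte mass is unchanged
    while the reference mass grows by the water content, so the wet-weight
    value never exceeds the dry-weight value.
    """
    if not 0.0 < moisture_fraction < 1.0:
        raise ValueError(
            f"moisture fraction must lie strictly in (0, 1), got {moisture_fraction}"
        )
    if np.any(np.asarray(c_dw) < 0):
        raise ValueError("dry-weight concentration must be non-negative")
    return c_dw * (1.0 - moisture_fraction)


def measurements_from_frame(df: pd.DataFrame) -> list[Measurement]:
    """Validate a tidy measurement table row by row.

    Raises ``ValueError`` naming the first offending row (1-based position
    in the table, header excluded).
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns: {missing}")
    out = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        censored = _as_bool(row["censored"])
        value = row["value"]
        value = None if (value is None or (isinstance(value, float) and np.isnan(value)) or value == "") else float(value)
        dl = row["detection_limit"]
        dl = None if (dl is None or (isinstance(dl, float) and np.isnan(dl)) or dl == "") else float(dl)
        try:
            out.append(
                Measurement(
                    sample_id=str(row["sample_id"]),
                    species_id=str(row["species_id"]),
                    season=str(row["season"]),
                    metal=str(row["metal"]),
                    value=value,
                    basis=str(row["basis"]),
                    censored=censored,
                    detection_limit=dl,
                )
            )
        except ValueError as err:
            raise ValueError(f"row {pos}: {err}") from err
    return out


def _as_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, str):
        if x.lower() in ("true", "1", "yes"):
            return True
        if x.lower() in ("false", "0", "no", ""):
            return False
        raise ValueError(f"unreadable censored flag {x!r}")
    return bool(x)


def _validate_frame(df: pd.DataFrame) -> None:
    """Vectorised schema validation; raises naming the first bad rows (1-based)."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns: {missing}")

    def _complain(mask: pd.Series, what: str) -> None:
        if mask.any():
            rows = [str(i + 1) for i in np.flatnonzero(mask.to_numpy())[:5]]
            raise ValueError(f"row(s) {', '.join(rows)}: {what}")

    censored = df["censored"].map(_as_bool)
    value = pd.to_numeric(df["value"], errors="coerce")
    dl = pd.to_numeric(df["detection_limit"], errors="coerce")
    _complain(~df["season"].isin(SEASONS), f"season not in {SEASONS}")
    _complain(~df["metal"].isin(METALS), f"metal not in {METALS}")
    _complain(~df["basis"].isin(BASES), f"basis not in {BASES}")
    _complain(censored & value.notna(), "censored record must not carry a value")
    _complain(censored & ~(dl > 0), "censored record needs a positive detection limit")
    _complain(~censored & value.isna(), "uncensored record needs a value")
    _complain(~censored & (value < 0), "negative concentration")


def read_measurements(path) -> pd.DataFrame:
    """Read the measurement CSV (empty ``value`` + censored=true encodes BDL)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "species_id": str})
    _validate_frame(df)
    df = df.copy()
    df["censored"] = df["censored"].map(_as_bool)
    return df


def replicate_wet_weights(
    measurements: pd.DataFrame | Iterable[Measurement],
    profiles: Mapping[str, SpeciesProfile],
) -> pd.DataFrame:
    """Replicate-level wet-weight values after substitution and conversion.

    Tidy frame with columns ``species_id, metal, season, basis, ww,
    censored`` — the inferential stage runs on this, the risk stage on the
    means derived from it. Rejects species without a profile and cells that
    mix dry- and wet-weight records.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:
        records = list(measurements)
        df = pd.DataFrame(
            [
                (m.sample_id, m.species_id, m.season, m.metal, m.value,
                 m.basis, m.censored, m.detection_limit)
                for m in records
            ],
            columns=MEASUREMENT_COLUMNS,
        )
    if df.empty:
        raise ValueError("no measurements supplied")
    _validate_frame(df)
    df["censored"] = df["censored"].map(_as_bool)

    missing = sorted(set(df["species_id"]) - set(profiles))
    if missing:
        raise ValueError(f"no species profile for: {', '.join(missing)}")

    value = pd.to_numeric(df["value"], errors="coerce").to_numpy(dtype=float)
    dl = pd.to_numeric(df["detection_limit"], errors="coerce").to_numpy(dtype=float)
    censored = df["censored"].to_numpy(dtype=bool)
    substituted = np.where(censored, dl / 2.0, value)
    solids = df["species_id"].map(
        {sid: 1.0 - p.moisture_fraction for sid, p in profiles.items()}
    ).to_numpy(dtype=float)
    ww = np.where(df["basis"].to_numpy() == "dry_weight", substituted * solids, substituted)

    tidy = pd.DataFrame(
        {
            "species_id": df["species_id"].to_numpy(),
            "metal": df["metal"].to_numpy(),
            "season": df["season"].to_numpy(),
            "basis": df["basis"].to_numpy(),
            "ww": ww,
            "censored": censored,
        }
    )

    mixed = (
        tidy.groupby(["species_id", "metal", "season"])["basis"].nunique().loc[lambda s: s > 1]
    )
    if len(mixed):
        cells = ", ".join("/".join(ix) for ix in mixed.index)
        raise ValueError(f"mixed dry/wet bases within cell(s): {cells}")
    return tidy


def summarize_concentrations(
    measurements: pd.DataFrame | Iterable[Measurement],
    profiles: Mapping[str, SpeciesProfile],
    pooling: Literal["by_season", "pooled"] = "by_season",
) -> pd.DataFrame:
    """Per-(species, metal) mean wet-weight concentrations.

    The order of operations fixes the estimand: censored substitution first
    (on the measurement basis), then conversion to wet weight with the
    species moisture, then the arithmetic mean per (species, metal, season).
    ``pooled`` returns the unweighted mean of the two seasonal means — the
    across-season summary used for chronic-exposure risk — which equals the
    grand mean only when replicate counts per season are equal.

    Returns a tidy frame with columns ``species_id, metal, season, mean_ww,
    n, substituted_fraction`` (season is ``"pooled"`` in pooled mode).
    """
    if pooling not in ("by_season", "pooled"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    tidy = replicate_wet_weights(measurements, profiles)

    seasonal = (
        tidy.groupby(["species_id", "metal", "season"], as_index=False)
        .agg(mean_ww=("ww", "mean"), n=("ww", "size"), substituted_fraction=("censored", "mean"))
    )
    if pooling == "by_season":
        return seasonal.sort_values(["species_id", "metal", "season"], ignore_index=True)

    pooled = (
        seasonal.groupby(["species_id", "metal"], as_index=False)
        .agg(mean_ww=("mean_ww", "mean"), n=("n", "sum"))
    )
    # substituted_fraction pooled over replicates, not over seasonal means
    frac = (
        tidy.groupby(["species_id", "metal"], as_index=False)["censored"]
        .mean()
        .rename(columns={"censored": "substituted_fraction"})
    )
    pooled = pooled.merge(frac, on=["species_id", "metal"])
    pooled.insert(2, "season", "pooled")
    return pooled.sort_values(["species_id", "metal"], ignore_index=True)


def apply_uniform_ww(
    summaries: pd.DataFrame, metal: str, value: float
) -> pd.DataFrame:
    """Replace every summary mean for ``metal`` by a constant wet-weight value.

    Reproduction switch for surveys that report a single substituted value
    for a metal below detection in all samples, ignoring per-species
    moisture differences.
    """
    if value <= 0:
        raise ValueError("uniform wet-weight value must be positive")
    out = summaries.copy()
    out.loc[out["metal"] == metal, "mean_ww"] = value
    return out


def flag_guideline_exceedance(
    summaries: pd.DataFrame,
    limits: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Compare summary means against per-authority permissible limits (ww).

    One output row per (summary row, configured authority-metal pair);
    metals an authority does not regulate produce no row. Equality with the
    limit is compliant (strict inequality).
    """
    rows = []
    for _, s in summaries.iterrows():
        for authority, table in limits.items():
            if s["metal"] not in table:
                continue
            limit = float(table[s["metal"]])
            if limit <= 0:
                raise ValueError(
                    f"{authority} limit for {s['metal']} must be positive, got {limit}"
                )
            rows.append(
                {
                    "species_id": s["species_id"],
                    "metal": s["metal"],
                    "season": s["season"],
                    "authority": authority,
                    "mean_ww": s["mean_ww"],
                    "limit_ww": limit,
                    "ratio": s["mean_ww"] / limit,
                    "exceeds": bool(s["mean_ww"] > limit),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "metal", "season", "authority",
            "mean_ww", "limit_ww", "ratio", "exceeds",
        ],
    )
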