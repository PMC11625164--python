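"""Configuration documents: species table, censoring limits, toxicology,
scenarios, guideline limits and reproduction switches.

All constants live in the YAML document, never in code, so jurisdictions
other than the shipped reproduction profile are supported without edits.
Profiles bundled with the package are addressed by name; ``paper`` is an
alias for the shipped reproduction profile ``dhaleshwari``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .concentrations import METALS, SpeciesProfile
from .risk import ExposureScenario, ToxProfile

PROFILE_ALIASES = {"paper": "dhaleshwari"}


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated, typed view of one configuration document."""

    name: str
    species: dict[str, SpeciesProfile]
    metals: tuple[str, ...]
    detection_limit_dw: dict[str, float]
    loq_dw: dict[str, float]
    tox: dict[str, ToxProfile]
    scenarios: dict[str, ExposureScenario]
    guideline_limits_ww: dict[str, dict[str, float]]
    overrides: dict[str, Any] = field(default_factory=dict)
    synthetic: dict[str, Any] = field(default_factory=dict)
    source_digest: str = ""

    @property
    def as_uniform_ww(self) -> float | None:
        """Uniform substituted wet-weight As value, when the switch is set."""
        v = self.overrides.get("as_uniform_ww")
        return float(v) if v is not None else None


def profile_path(name: str) -> Path:
    """Filesystem path of a shipped profile (``paper`` aliases the default)."""
    name = PROFILE_ALIASES.get(name, name)
    path = resources.files("hmrisk").joinpath(f"profiles/{name}.yaml")
    with resources.as_file(path) as p:
        if not p.exists():
            raise FileNotFoundError(f"no shipped profile named {name!r}")
        return Path(p)


def load_config(source: str | Path) -> AnalysisConfig:
    """Load and validate a config document from a path or profile name."""
    path = Path(source)
    if not path.exists() and not str(source).endswith((".yaml", ".yml")):
        path = profile_path(str(source))
    raw = path.read_text()
    doc = yaml.safe_load(raw)
    return parse_config(doc, digest=hashlib.sha256(raw.encode()).hexdigest()[:16])


def parse_config(doc: Mapping[str, Any], digest: str = "") -> AnalysisConfig:
    for key in ("species", "tox", "scenarios"):
        if key not in doc:
            raise ValueError(f"config lacks required section {key!r}")

    species = {
        sid: SpeciesProfile(species_id=sid, **entry)
        for sid, entry in doc["species"].items()
    }
    metals = tuple(doc.get("metals", METALS))
    unknown = set(metals) - set(METALS)
    if unknown:
        raise ValueError(f"config lists unknown metals: {sorted(unknown)}")

    tox = {
        metal: ToxProfile(
            metal=metal,
            rfd=entry.get("rfd"),
            csf=entry.get("csf"),
            ptdi=entry.get("ptdi"),
        )
        for metal, entry in doc["tox"].items()
    }
    scenarios = {
        label: ExposureScenario(label=label, **entry)
        for label, entry in doc["scenarios"].items()
    }
    limits = {
        authority: {m: float(v) for m, v in table.items()}
        for authority, table in doc.get("guideline_limits_ww", {}).items()
    }
    for authority, table in limits.items():
        for m, v in table.items():
            if v <= 0:
                raise ValueError(f"{authority} limit for {m} must be positive")

    return AnalysisConfig(
        name=str(doc.get("name", "unnamed")),
        species=species,
        metals=metals,
        detection_limit_dw={m: float(v) for m, v in doc.get("detection_limit_dw", {}).items()},
        loq_dw={m: float(v) for m, v in doc.get("loq_dw", {}).items()},
        tox=tox,
        scenarios=scenarios,
        guideline_limits_ww=limits,
        overrides=dict(doc.get("overrides", {})),
        synthetic=dict(doc.get("synthetic", {})),
        source_digest=digest,
    )
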