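"""Config and report I/O.

Profiles, scenarios and registry overrides are YAML (or JSON, which YAML
subsumes) documents with all fractions as decimals in [0, 1] - the readers
reject values above 1 rather than guessing percent units.  Three failure
modes are signalled distinctly: ParseError (malformed file), SchemaError
(missing/mistyped fields) and InvariantViolation (valid shape, invalid
values), each reporting field paths.

Reports are a CSV table (UTF-8, comma delimiter, '.' decimal separator,
fixed column order year,intervention,timing,averted,residual,sbr) at full
float precision plus a human-readable text summary with counts rounded to
integers.  Every run can record a RunManifest sufficient to reproduce its
outputs bit-for-bit with the same code version.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .engine import (
    CountryProfile,
    ImpactResult,
    Scenario,
    enap_met,
    validate_profile,
    validate_scenario,
)
from .errors import InvariantViolation, ParseError, SchemaError
from .registry import InterventionSpec, registry_from_config, registry_to_config

REPORT_COLUMNS = ["year", "intervention", "timing", "averted", "residual", "sbr"]


def _load_document(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path} is not valid YAML/JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top level must be a mapping, got {type(doc).__name__}")
    return doc


def _number(doc: dict, key: str, path: Path, required: bool = True) -> float | None:
    if key not in doc or doc[key] is None:
        if required:
            raise SchemaError(f"{path}: missing required field {key!r}")
        return None
    value = doc[key]
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise SchemaError(f"{path}: field {key!r} must be a number, got {value!r}")
    return float(value)


def _fraction_map(doc: dict, key: str, path: Path) -> dict[str, float]:
    raw = doc.get(key) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: field {key!r} must be a mapping")
    out = {}
    for k, v in raw.items():
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise SchemaError(f"{path}: {key}.{k} must be a number, got {v!r}")
        out[str(k)] = float(v)
    return out


def read_profile(path: str | Path) -> CountryProfile:
    """Read and validate a country profile document."""
    path = Path(path)
    doc = _load_document(path)
    births = _number(doc, "births_per_year", path)
    stillbirths = _number(doc, "stillbirths", path, required=False)
    sbr_value = _number(doc, "sbr", path, required=False)
    if stillbirths is None and sbr_value is None:
        raise SchemaError(
            f"{path}: one of 'stillbirths' or 'sbr' is required; "
            "fields 'stillbirths' and 'sbr' are both absent"
        )
    profile = CountryProfile(
        births_per_year=births,
        prop_intrapartum=_number(doc, "prop_intrapartum", path),
        stillbirths=stillbirths,
        sbr=sbr_value,
        prevalences=_fraction_map(doc, "prevalences", path),
        baseline_indicators=_fraction_map(doc, "baseline_indicators", path),
        name=str(doc.get("name", "")),
    )
    problems = validate_profile(profile)
    if problems:
        raise InvariantViolation(f"{path}: " + "; ".join(problems))
    return profile


def write_profile(profile: CountryProfile, path: str | Path) -> None:
    doc: dict[str, Any] = {
        "name": profile.name,
        "births_per_year": profile.births_per_year,
        "prop_intrapartum": profile.prop_intrapartum,
        "prevalences": dict(profile.prevalences),
        "baseline_indicators": dict(profile.baseline_indicators),
    }
    if profile.stillbirths is not None:
        doc["stillbirths"] = profile.stillbirths
    if profile.sbr is not None:
        doc["sbr"] = profile.sbr
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_scenario(path: str | Path) -> Scenario:
    """Read and validate a coverage scenario document."""
    path = Path(path)
    doc = _load_document(path)
    for key in ("base_year", "end_year"):
        if key not in doc:
            raise SchemaError(f"{path}: missing required field {key!r}")
        if isinstance(doc[key], bool) or not isinstance(doc[key], int):
            raise SchemaError(f"{path}: field {key!r} must be an integer")
    scenario = Scenario(
        base_year=int(doc["base_year"]),
        end_year=int(doc["end_year"]),
        targets=_fraction_map(doc, "targets", path),
        trajectory=str(doc.get("trajectory", "linear")),
        name=str(doc.get("name", "")),
    )
    problems = validate_scenario(scenario)
    if problems:
        raise InvariantViolation(f"{path}: " + "; ".join(problems))
    return scenario


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    doc = {
        "name": scenario.name,
        "base_year": scenario.base_year,
        "end_year": scenario.end_year,
        "trajectory": scenario.trajectory,
        "targets": dict(scenario.targets),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_registry(path: str | Path) -> list[InterventionSpec]:
    doc = _load_document(path)
    if "interventions" not in doc:
        raise SchemaError(f"{path}: missing required field 'interventions'")
    try:
        return registry_from_config(doc)
    except (KeyError, ValueError) as exc:
        raise SchemaError(f"{path}: bad intervention entry: {exc}") from exc


def write_registry(specs: list[InterventionSpec], path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(registry_to_config(specs), sort_keys=False), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Reports


def write_report(result: ImpactResult, out_dir: str | Path) -> list[Path]:
    """Write the impact CSV and text summary; return the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    detail = result.detail.copy()
    detail["residual"] = float("nan")
    detail["sbr"] = float("nan")
    totals = result.summary.rename(columns={"averted": "averted"})[
        ["year", "averted", "residual", "sbr"]
    ]
    totals["intervention"] = "ALL"
    totals["timing"] = "all"
    table = pd.concat([detail, totals], ignore_index=True)[REPORT_COLUMNS]
    csv_path = out_dir / "impact.csv"
    table.to_csv(csv_path, index=False)

    lines = [
        "Stillbirths averted projection",
        f"Envelope: {result.envelope:.0f} stillbirths/year "
        f"({result.prop_intrapartum:.0%} intrapartum), "
        f"{result.births_per_year:.0f} total births/year",
        "",
        f"{'year':>6} {'averted':>9} {'residual':>9} {'SBR':>7}  ENAP<=12",
    ]
    for _, row in result.summary.iterrows():
        lines.append(
            f"{int(row['year']):>6} {row['averted']:>9.0f} "
            f"{row['residual']:>9.0f} {row['sbr']:>7.1f}  "
            f"{'yes' if row['enap_met'] else 'no'}"
        )
    final = result.summary.iloc[-1]
    lines += [
        "",
        f"Final-year stillbirth rate: {final['sbr']:.1f} per 1000 total births "
        f"({'meets' if enap_met(final['sbr']) else 'does not meet'} the "
        "ENAP target of <=12 per 1000).",
    ]
    txt_path = out_dir / "summary.txt"
    txt_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return [csv_path, txt_path]


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Run manifests


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit (same code version)."""

    tool_version: str
    registry_hash: str
    profile_path: str
    scenario_path: str
    seed: int
    timestamp: str

    @classmethod
    def create(
        cls,
        registry_hash: str,
        profile_path: str | Path,
        scenario_path: str | Path,
        seed: int,
    ) -> "RunManifest":
        return cls(
            tool_version=__version__,
            registry_hash=registry_hash,
            profile_path=str(profile_path),
            scenario_path=str(scenario_path),
            seed=seed,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))
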