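"""Readers and writers for the package's file formats.

Formats are deliberately plain: parameter profiles are flat key-value YAML
documents; exposure schedules are piecewise-constant segment CSVs with a
JSON sidecar carrying the duration and initial burden; trajectories and
Monte Carlo dumps are one-row-per-day / one-row-per-iteration CSVs;
summaries and run manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DailyState, SimulationResult
from .exposure import ExposureScenario
from .halflife import HalfLifeEvidence
from .physiology import GrowthParams, IntakeParams
from .profiles import ParameterProfile, PartitionParams, TransferParams

__all__ = [
    "ProfileError",
    "default_profile_path",
    "default_evidence_path",
    "profile_to_dict",
    "profile_from_dict",
    "load_profile",
    "write_profile",
    "write_trajectory",
    "read_trajectory",
    "write_scenario",
    "read_scenario",
    "read_evidence",
    "write_evidence",
    "write_pool",
    "write_summary",
    "write_manifest",
]


class ProfileError(ValueError):
    """A parameter profile document failed validation."""


def default_profile_path() -> Path:
    """Path to the bundled default parameter profile (flat YAML)."""
    return Path(__file__).parent / "data" / "default_profile.yaml"


def default_evidence_path() -> Path:
    """Path to the bundled half-life weight-of-evidence table (CSV)."""
    return Path(__file__).parent / "data" / "halflife_evidence.csv"


_SECTIONS = {
    "growth": GrowthParams,
    "intake": IntakeParams,
    "transfer": TransferParams,
    "partition": PartitionParams,
}


def _section_fields(cls) -> list[str]:
    return [f.name for f in dataclasses.fields(cls)]


def profile_to_dict(profile: ParameterProfile) -> dict:
    """Flatten a profile to a single key-value mapping (tuples as lists)."""
    out: dict = {}
    for section, cls in _SECTIONS.items():
        obj = getattr(profile, section)
        for name in _section_fields(cls):
            value = getattr(obj, name)
            out[name] = list(value) if isinstance(value, tuple) else value
    out["update_order"] = profile.update_order
    return out


def profile_from_dict(doc: dict) -> ParameterProfile:
    """Validate a flat key-value document into a :class:`ParameterProfile`.

    Missing ``*_sd`` keys are filled with 20% of the corresponding value
    (the default used when a literature SD is unavailable); any other
    missing or unrecognised key is a hard error naming the key.
    """
    if not isinstance(doc, dict):
        raise ProfileError("profile document must be a mapping")
    doc = dict(doc)
    update_order = doc.pop("update_order", "intake_first")
    known = {name for cls in _SECTIONS.values() for name in _section_fields(cls)}
    unknown = set(doc) - known
    if unknown:
        raise ProfileError(f"unrecognised profile keys: {sorted(unknown)}")
    kwargs: dict = {}
    for section, cls in _SECTIONS.items():
        section_kwargs = {}
        for f in dataclasses.fields(cls):
            name = f.name
            if name in doc:
                value = doc[name]
            elif name.endswith("_sd") and name[:-3] in doc:
                base = doc[name[:-3]]
                if not isinstance(base, (int, float)):
                    raise ProfileError(f"cannot default SD for non-scalar key {name[:-3]!r}")
                value = 0.2 * float(base)
            else:
                raise ProfileError(f"missing required profile key: {name!r}")
            if isinstance(value, list):
                value = tuple(float(v) for v in value)
            section_kwargs[name] = value
        try:
            kwargs[section] = cls(**section_kwargs)
        except (TypeError, ValueError) as exc:
            raise ProfileError(f"invalid {section} parameters: {exc}") from exc
    try:
        return ParameterProfile(update_order=update_order, **kwargs)
    except ValueError as exc:
        raise ProfileError(str(exc)) from exc


def load_profile(path) -> ParameterProfile:
    """Read and validate a flat YAML/JSON parameter profile."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ProfileError(f"cannot parse profile {path}: {exc}") from exc
    return profile_from_dict(doc)


def write_profile(profile: ParameterProfile, path) -> None:
    Path(path).write_text(yaml.safe_dump(profile_to_dict(profile), sort_keys=True))


# -- trajectories -----------------------------------------------------------

_TRAJ_COLUMNS = [f.name for f in dataclasses.fields(DailyState)]


def write_trajectory(result: "SimulationResult | list[DailyState]", path) -> None:
    """One CSV row per simulated day, columns mirroring :class:`DailyState`
    (including the serum column)."""
    states = result.trajectory if isinstance(result, SimulationResult) else result
    df = pd.DataFrame([vars(s) for s in states], columns=_TRAJ_COLUMNS)
    df.to_csv(path, index=False)


def read_trajectory(path) -> list[DailyState]:
    """Read a trajectory CSV back into :class:`DailyState` records."""
    df = pd.read_csv(path)
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file {path} missing columns {sorted(missing)}")
    return [
        DailyState(age=int(row.age), **{
            c: float(getattr(row, c)) for c in _TRAJ_COLUMNS if c != "age"
        })
        for row in df.itertuples(index=False)
    ]


# -- exposure scenarios -----------------------------------------------------

_SCHEDULE_COLUMNS = [
    "start_day", "end_day",
    "forage_conc", "water_conc", "soil_conc", "cow_forage_conc", "cow_water_conc",
]


def _sidecar(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_scenario(scenario: ExposureScenario, csv_path) -> None:
    """Write a scenario as a piecewise-constant segment CSV plus a JSON
    header (duration, initial body burden) next to it."""
    csv_path = Path(csv_path)
    pd.DataFrame(scenario.to_segments(), columns=_SCHEDULE_COLUMNS).to_csv(
        csv_path, index=False
    )
    _sidecar(csv_path).write_text(json.dumps({
        "duration": scenario.duration,
        "initial_body_burden": scenario.initial_body_burden,
    }, indent=2))


def read_scenario(csv_path) -> ExposureScenario:
    csv_path = Path(csv_path)
    header = json.loads(_sidecar(csv_path).read_text())
    df = pd.read_csv(csv_path)
    missing = set(_SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule {csv_path} missing columns {sorted(missing)}")
    return ExposureScenario.from_segments(
        df.to_dict("records"),
        duration=int(header["duration"]),
        initial_body_burden=float(header.get("initial_body_burden", 0.0)),
    )


# -- half-life evidence -----------------------------------------------------

_EVIDENCE_COLUMNS = [
    "study_label", "tissue", "half_life", "sd",
    "exposure_weight", "type_weight", "tissue_weight", "duration_weight", "divisor",
]


def read_evidence(path) -> list[HalfLifeEvidence]:
    """Read a weight-of-evidence table CSV; an empty SD cell means
    'use the 20% default'."""
    df = pd.read_csv(path)
    missing = set(_EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table {path} missing columns {sorted(missing)}")
    rows = []
    for row in df.itertuples(index=False):
        sd = float(row.sd) if pd.notna(row.sd) else None
        rows.append(HalfLifeEvidence(
            study_label=str(row.study_label), tissue=str(row.tissue),
            half_life=float(row.half_life), sd=sd,
            exposure_weight=int(row.exposure_weight), type_weight=int(row.type_weight),
            tissue_weight=int(row.tissue_weight), duration_weight=int(row.duration_weight),
            divisor=float(row.divisor),
        ))
    return rows


def write_evidence(evidence: list[HalfLifeEvidence], path) -> None:
    pd.DataFrame(
        [{c: getattr(ev, c) for c in _EVIDENCE_COLUMNS} for ev in evidence]
    ).to_csv(path, index=False)


def write_pool(points: np.ndarray, path) -> None:
    """One-column CSV of the pooled half-life sample points (for
    histogram plotting)."""
    pd.DataFrame({"half_life_days": np.asarray(points)}).to_csv(path, index=False)


# -- summaries and manifests ------------------------------------------------

def write_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=float))


def write_manifest(config: dict, path) -> None:
    """Echo the run configuration (arguments, seed, package version) so a
    run can be reproduced bit-exactly."""
    from . import __version__

    doc = {"package": "beefdam", "version": __version__, **config}
    Path(path).write_text(json.dumps(doc, indent=2, default=str))
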