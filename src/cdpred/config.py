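"""YAML round-trip for bin definitions, feature schemas and potentials."""

from __future__ import annotations

from pathlib import Path

import yaml

from .constraints import DEFAULT_POTENTIALS
from .features import FeatureSchema
from .geometry import BinSpec, DEFAULT_BINS, validate_bins


def save_bins(bins: tuple[BinSpec, ...], path: str | Path) -> None:
    payload = [
        {
            "name": b.name, "low": b.low, "high": b.high, "min_sep": b.min_sep,
            "score_threshold": b.score_threshold, "cap_factor": b.cap_factor,
            "exclude_same_ss": b.exclude_same_ss,
        }
        for b in bins
    ]
    Path(path).write_text(yaml.safe_dump({"bins": payload}, sort_keys=False))


def load_bins(path: str | Path) -> tuple[BinSpec, ...]:
    data = yaml.safe_load(Path(path).read_text())
    bins = tuple(BinSpec(**entry) for entry in data["bins"])
    validate_bins(bins)
    return bins


def save_schema(schema: FeatureSchema, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(schema.to_dict(), sort_keys=False))


def load_schema(path: str | Path) -> FeatureSchema:
    return FeatureSchema.from_dict(yaml.safe_load(Path(path).read_text()))


def save_potentials(
    potentials: dict[str, tuple[str, tuple[float, ...]]], path: str | Path
) -> None:
    payload = {
        name: {"function": func, "parameters": list(params)}
        for name, (func, params) in potentials.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_potentials(path: str | Path) -> dict[str, tuple[str, tuple[float, ...]]]:
    data = yaml.safe_load(Path(path).read_text())
    out = {}
    for name, entry in data.items():
        out[name] = (entry["function"], tuple(float(x) for x in entry["parameters"]))
    return out


def default_config_files(directory: str | Path) -> None:
    """Write the package defaults as editable YAML files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_bins(DEFAULT_BINS, directory / "bins.yaml")
    save_schema(FeatureSchema(), directory / "schema.yaml")
    save_potentials(DEFAULT_POTENTIALS, directory / "potentials.yaml")
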