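"""Run configuration: one YAML profile with CLI overrides.

The packaged default profile carries every tunable of the pipeline
(selection cutoff alpha, overflow fraction epsilon, return probability p0,
the distance scheme, GO term groups, curation lists, format type maps).  A
user file overrides keys selectively; unknown keys are rejected so typos
surface immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "default_profile"]

_NUMERIC_RANGES = {
    "alpha": (0.0, 1.0),
    "epsilon": (0.0, float("inf")),
    "p0": (0.0, 1.0),
    "silac_threshold": (0.0, 1.0),
    "tol": (0.0, 1.0),
}


def default_profile() -> dict:
    """The packaged default settings as a plain dict."""
    text = resources.files("signet").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class RunConfig:
    """All pipeline settings plus the input/output paths of a run."""

    settings: dict = field(default_factory=default_profile)
    inputs: dict[str, Path] = field(default_factory=dict)
    output_dir: Path | None = None
    seed: int = 0

    def __getitem__(self, key: str):
        return self.settings[key]

    @property
    def scheme(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.settings["scheme"].items()}

    @property
    def term_groups(self) -> dict[str, list[str]]:
        return self.settings["term_groups"]

    @property
    def kgml_type_map(self) -> dict[str, tuple[str, str]]:
        return {k: tuple(v) for k, v in self.settings["kgml_type_map"].items()}

    @property
    def sif_type_map(self) -> dict[str, tuple[str, str, bool]]:
        return {k: tuple(v) for k, v in self.settings["sif_type_map"].items()}

    @property
    def direct_substrate_excludes(self) -> list[tuple[str, str | None]]:
        return [
            (e["protein"], e.get("sequence")) for e in self.settings["direct_substrate_excludes"]
        ]


def load_config(
    path: str | Path | None = None,
    overrides: dict | None = None,
    inputs: dict[str, str | Path] | None = None,
    output_dir: str | Path | None = None,
    seed: int = 0,
) -> RunConfig:
    """Load the default profile, then a user YAML, then explicit overrides.

    Input files named in *inputs* must exist; numeric parameters are
    range-checked; keys absent from the default profile are rejected.
    """
    settings = default_profile()
    for layer in (yaml.safe_load(Path(path).read_text()) if path else None, overrides):
        if not layer:
            continue
        unknown = set(layer) - set(settings)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        settings.update(layer)

    for key, (lo, hi) in _NUMERIC_RANGES.items():
        val = float(settings[key])
        if not (lo <= val <= hi) or (key in ("alpha", "p0", "silac_threshold") and val in (lo, hi)):
            raise ValueError(f"configuration value {key}={val} outside ({lo}, {hi})")

    resolved: dict[str, Path] = {}
    for name, p in (inputs or {}).items():
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"configured input {name!r} does not exist: {p}")
        resolved[name] = p

    return RunConfig(settings=settings, inputs=resolved,
                     output_dir=Path(output_dir) if output_dir else None, seed=seed)
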