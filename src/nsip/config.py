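"""Run configuration: a YAML schema with strict unknown-key rejection."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from nsip.synthetic_data import GradientProtocol, MicrocosmParams, TaxonSpec

_SCHEMA_VERSION = 1


def _build(cls, block: dict[str, Any], where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    # YAML 1.1 reads "1.0e7" (no sign) as a string; coerce numeric-looking text
    block = dict(block)
    for key, value in block.items():
        if isinstance(value, str):
            try:
                block[key] = float(value)
            except ValueError:
                pass
    if cls is MicrocosmParams and "urea_doses" in block:
        block = dict(block, urea_doses=tuple(tuple(d) for d in block["urea_doses"]))
    return cls(**block)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML.

    ``taxa``/``protocol``/``microcosms`` drive simulation when present;
    ``fractions``/``totals``/``chemistry``/``counts``/... point at existing
    input tables. ``hf_overrides`` maps gene -> explicit HF fraction list.
    """

    seed: int = 0
    out_dir: str = "results"
    schema_version: int = _SCHEMA_VERSION
    # simulation blocks
    taxa: tuple[TaxonSpec, ...] = ()
    protocol: GradientProtocol | None = None
    microcosms: dict[str, MicrocosmParams] = field(default_factory=dict)
    # input tables (paths)
    fractions: str | None = None
    totals: dict[str, float] = field(default_factory=dict)
    chemistry: str | None = None
    soil_metadata: str | None = None
    counts: str | None = None
    sample_metadata: str | None = None
    taxonomy: str | None = None
    # thresholds
    margin: float = 0.10
    min_abund: float = 0.01
    fold: float = 2.0
    hf_overrides: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.schema_version != _SCHEMA_VERSION:
            raise ValueError(
                f"unsupported config schema_version {self.schema_version}"
            )
        for name in ("fractions", "chemistry", "soil_metadata", "counts",
                     "sample_metadata", "taxonomy"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name}={p!r} does not exist")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys anywhere in the file are rejected with an error listing
    them, so a misspelled threshold cannot silently fall back to a default.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")

    kwargs: dict[str, Any] = dict(raw)
    if "taxa" in kwargs:
        kwargs["taxa"] = tuple(
            _build(TaxonSpec, t, f"taxa[{i}]") for i, t in enumerate(kwargs["taxa"])
        )
    if kwargs.get("protocol") is not None:
        kwargs["protocol"] = _build(GradientProtocol, kwargs["protocol"], "protocol")
    if "microcosms" in kwargs:
        kwargs["microcosms"] = {
            name: _build(MicrocosmParams, block, f"microcosms.{name}")
            for name, block in kwargs["microcosms"].items()
        }
    if "hf_overrides" in kwargs:
        kwargs["hf_overrides"] = {
            gene: tuple(int(i) for i in v)
            for gene, v in kwargs["hf_overrides"].items()
        }
    return RunConfig(**kwargs)
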