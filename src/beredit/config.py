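"""Pipeline configuration: a documented YAML key-value schema with
all-at-once validation and lossless round-trips."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from beredit.amplicon_quant import Scoring, WindowSpec
from beredit.edit_calling import FilterParams
from beredit.synthetic_data import SimParams


class ConfigError(ValueError):
    """Invalid configuration; carries every problem found, not just the first."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class AmpliconSimConfig:
    """Planted amplicon editing profile for the synthetic demo."""

    n_reads: int = 10000
    profile: dict[int, float] = field(
        default_factory=lambda: {4: 0.15, 5: 0.60, 9: 0.08})
    nonG_rate: float = 0.004
    indel_rate: float = 0.05
    error_rate: float = 0.001


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "beredit_out"
    sim: SimParams = field(default_factory=SimParams)
    filters: FilterParams = field(default_factory=FilterParams)
    window: WindowSpec = field(default_factory=lambda: WindowSpec(4, 8))
    scoring: Scoring = field(default_factory=Scoring)
    amplicon: AmpliconSimConfig = field(default_factory=AmpliconSimConfig)
    min_score_fraction: float = 0.6
    motif_strata: tuple[float, ...] = (0.2, 0.4)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["transcript_length"] = list(self.sim.transcript_length)
        for k in ("motif_eff_distribution", "background_eff_distribution",
                  "endogenous_eff_distribution"):
            d["sim"][k] = list(getattr(self.sim, k))
        d["motif_strata"] = list(self.motif_strata)
        return d

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


_SECTION_TYPES = {
    "sim": SimParams,
    "filters": FilterParams,
    "window": WindowSpec,
    "scoring": Scoring,
    "amplicon": AmpliconSimConfig,
}

_TUPLE_FIELDS = {
    ("sim", "transcript_length"),
    ("sim", "motif_eff_distribution"),
    ("sim", "background_eff_distribution"),
    ("sim", "endogenous_eff_distribution"),
}


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain dict, collecting every error."""
    errors: list[str] = []
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])
    known_top = {f.name for f in dataclasses.fields(PipelineConfig)}
    for k in data:
        if k not in known_top:
            errors.append(f"unknown key: {k}")

    kwargs: dict = {}
    for name in ("seed", "outdir", "min_score_fraction"):
        if name in data:
            kwargs[name] = data[name]
    if "motif_strata" in data:
        kwargs["motif_strata"] = tuple(data["motif_strata"])

    for section, typ in _SECTION_TYPES.items():
        if section not in data:
            continue
        sub = data[section]
        if not isinstance(sub, dict):
            errors.append(f"{section}: must be a mapping")
            continue
        known = {f.name for f in dataclasses.fields(typ)}
        sub_kwargs = {}
        for k, v in sub.items():
            if k not in known:
                errors.append(f"{section}.{k}: unknown key")
                continue
            if (section, k) in _TUPLE_FIELDS:
                v = tuple(v)
            sub_kwargs[k] = v
        try:
            obj = typ(**sub_kwargs)
            if hasattr(obj, "validate"):
                obj.validate()
            kwargs[section] = obj
        except (TypeError, ValueError) as e:
            errors.append(f"{section}: {e}")

    cfg = None
    if not errors:
        try:
            cfg = PipelineConfig(**kwargs)
            cfg.filters.validate()
            cfg.sim.validate()
            if not 0.0 < cfg.min_score_fraction <= 1.0:
                errors.append("min_score_fraction must be in (0, 1]")
            if cfg.seed < 0 or cfg.seed >= 2**31:
                errors.append("seed must be in [0, 2^31)")
            for p, v in cfg.amplicon.profile.items():
                if not 0.0 <= v <= 1.0:
                    errors.append(
                        f"amplicon.profile[{p}]: probability {v} outside [0, 1]")
        except (TypeError, ValueError) as e:
            errors.append(str(e))
    if errors:
        raise ConfigError(errors)
    assert cfg is not None
    return cfg


def validate_config(path: str | Path) -> PipelineConfig:
    """Load, validate and normalize a YAML config file.

    Raises :class:`ConfigError` listing every problem at once.
    """
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    except yaml.YAMLError as e:
        raise ConfigError([f"YAML parse error: {e}"]) from e
    except OSError as e:
        raise ConfigError([str(e)]) from e
    return config_from_dict(data)
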