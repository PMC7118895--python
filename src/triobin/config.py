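"""Flat key=value configuration for the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from .kmers import MarkerConfig
from .simulate import SimConfig

ALL_STAGES = (
    "simulate",
    "markers",
    "bin-reads",
    "bin-hic",
    "parentage",
    "phase-qc",
    "gaps",
    "telomeres",
)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; unknown keys are rejected.

    ``seed`` feeds every source of randomness; a run's provenance header
    (config hash, seed, version) is written at the top of each report.
    """

    out_dir: str = "triobin_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    log_level: str = "info"
    normalize_binning: bool = False
    hic_margin: int = 0
    n_trio_sites: int = 20_000
    sim: SimConfig = field(default_factory=SimConfig)
    markers: MarkerConfig = field(default_factory=MarkerConfig)

    def config_hash(self) -> str:
        # hash the scientific configuration only, not output paths
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        text = repr(payload)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def provenance(self) -> str:
        from . import __version__

        return (
            f"# triobin v{__version__} seed={self.seed} "
            f"config={self.config_hash()}"
        )


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _convert(value: str, target_type):
    if target_type is bool:
        try:
            return _BOOL[value.strip().lower()]
        except KeyError:
            raise ValueError(f"expected a boolean, got {value!r}") from None
    if target_type is int:
        return int(value)
    if target_type is float:
        return float(value)
    return value


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a flat key=value file and/or overrides.

    Recognized keys are the PipelineConfig fields plus the SimConfig and
    MarkerConfig fields (e.g. ``divergence=0.012``, ``k=21``); ``stages``
    is a comma-separated list.  Unknown keys, type mismatches and invariant
    violations raise descriptive errors.
    """
    pairs: dict[str, str] = {}
    if path is not None:
        for n, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{n}: expected key=value, got {line!r}")
            key, value = line.split("=", 1)
            pairs[key.strip()] = value.strip()
    pairs.update({k: str(v) for k, v in overrides.items() if v is not None})

    top = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    sim_fields = {f.name: f for f in dataclasses.fields(SimConfig)}
    marker_fields = {f.name: f for f in dataclasses.fields(MarkerConfig)}
    top_kwargs: dict = {}
    sim_kwargs: dict = {}
    marker_kwargs: dict = {}
    for key, value in pairs.items():
        if key == "stages":
            top_kwargs["stages"] = tuple(s.strip() for s in value.split(",") if s.strip())
        elif key in ("sim", "markers"):
            raise ValueError(f"nested key {key!r} cannot be set directly")
        elif key in top:
            top_kwargs[key] = _convert(value, top[key].type if isinstance(top[key].type, type) else {"out_dir": str, "seed": int, "log_level": str, "normalize_binning": bool, "hic_margin": int, "n_trio_sites": int}[key])
        elif key in sim_fields:
            ftype = type(getattr(SimConfig(), key))
            sim_kwargs[key] = _convert(value, ftype)
        elif key in marker_fields:
            ftype = type(getattr(MarkerConfig(), key))
            marker_kwargs[key] = _convert(value, ftype)
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    unknown_stages = set(top_kwargs.get("stages", ())) - set(ALL_STAGES)
    if unknown_stages:
        raise ValueError(f"unknown stage(s): {sorted(unknown_stages)}")
    if "seed" in top_kwargs:
        sim_kwargs.setdefault("seed", top_kwargs["seed"])
    config = PipelineConfig(
        **top_kwargs,
        sim=SimConfig(**sim_kwargs),
        markers=MarkerConfig(**marker_kwargs),
    )
    return config
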