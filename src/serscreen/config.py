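"""YAML configuration loading for the screening pipeline.

Every decision-relevant number — the penalty lambda, the band
intervals, the detection floor, the 1.5 / 5 / 600 thresholds — lives in
config rather than in logic, so a run is auditable from its config echo.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .baseline import AirplsConfig
from .scoring import Band, BandSet, RuleConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    airpls: AirplsConfig = AirplsConfig()
    bands: BandSet = BandSet()
    rules: RuleConfig = RuleConfig()
    regulatory_limit: float = 600.0
    mc_iters: int = 10_000

    def to_dict(self) -> dict:
        from dataclasses import fields

        d = {
            "airpls": asdict(self.airpls),
            "bands": {
                f.name: [getattr(self.bands, f.name).lower, getattr(self.bands, f.name).upper]
                for f in fields(self.bands)
            },
            "rules": asdict(self.rules),
            "regulatory_limit": self.regulatory_limit,
            "mc_iters": self.mc_iters,
        }
        return d


def _band(value) -> Band:
    if isinstance(value, (int, float)):
        return Band(float(value), float(value))
    lo, hi = value
    return Band(float(lo), float(hi))


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline config; missing keys fall back to defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    airpls = AirplsConfig(**raw.get("airpls", {}))
    bands_raw = raw.get("bands", {})
    defaults = BandSet()
    bands = BandSet(
        monomer_naphthenic=_band(bands_raw["monomer_naphthenic"])
        if "monomer_naphthenic" in bands_raw
        else defaults.monomer_naphthenic,
        monomer_carboxylic=_band(bands_raw["monomer_carboxylic"])
        if "monomer_carboxylic" in bands_raw
        else defaults.monomer_carboxylic,
        dimer_naphthenic=_band(bands_raw["dimer_naphthenic"])
        if "dimer_naphthenic" in bands_raw
        else defaults.dimer_naphthenic,
        dimer_carboxylic=_band(bands_raw["dimer_carboxylic"])
        if "dimer_carboxylic" in bands_raw
        else defaults.dimer_carboxylic,
    )
    rules = RuleConfig(**raw.get("rules", {}))
    return PipelineConfig(
        airpls=airpls,
        bands=bands,
        rules=rules,
        regulatory_limit=float(raw.get("regulatory_limit", 600.0)),
        mc_iters=int(raw.get("mc_iters", 10_000)),
    )
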