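"""Pipeline configuration: every tunable threshold in one serialisable tree."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .autoencoder import AEConfig
from .templates import RuleConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All knobs of the detection pipeline.

    Matching thresholds are the published decision rule: a beat is the same
    type as its template iff Covr >= 0.9, or Covr >= 0.8 with ArDiff < 10%
    and EnDiff < 1.  Rhythm thresholds encode prematurity (coupling interval
    < 0.9 of the local RR) and a compensatory pause (pre+post >= 1.8 local
    RRs).
    """

    seed: int = 0
    ae: AEConfig = field(default_factory=AEConfig)
    rules: RuleConfig = field(default_factory=RuleConfig)

    # clustering
    k_min: int = 2
    k_max: int = 8
    cluster_restarts: int = 10
    n_template: int = 30

    # template matching (decision rule thresholds)
    covr_hi: float = 0.9
    covr_lo: float = 0.8
    ardiff_max: float = 10.0
    endiff_max: float = 1.0

    # rhythm rule
    prematurity: float = 0.9
    pause: float = 1.8

    # template reuse / update
    update_unknown_frac: float = 0.10
    update_min_covr: float = 0.9
    segment_minutes: float = 30.0

    # quality gate: 'segment' rejects a whole segment; 'subwindow' excises
    # failing 10 s stretches.  Segment-level is the default because windowed
    # spectral indices systematically reject stretches rich in ectopic beats
    # (wide QRS and large T waves shift power below the QRS band).
    quality_granularity: str = "segment"
    quality_window_s: float = 10.0
    flat_max: float = 0.2
    clipped_max: float = 0.05
    # The pipeline's spectral floor sits below assess_quality's stand-alone
    # default (0.5): wide ectopic QRS complexes shift power below 5 Hz, so
    # PVC-rich yet perfectly clean segments score ~0.3-0.45 while flatline
    # and out-of-band artefact still score ~0.
    band_ratio_min: float = 0.25

    # label for beats matching no template with inconclusive rhythm
    unknown_fallback: str = "Non_PVC"

    # band-pass
    filter_band: tuple = (0.1, 45.0)
    filter_order: int = 4

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "ae" in d and isinstance(d["ae"], dict):
            d["ae"] = AEConfig(**d["ae"])
        if "rules" in d and isinstance(d["rules"], dict):
            d["rules"] = RuleConfig(**d["rules"])
        if "filter_band" in d:
            d["filter_band"] = tuple(d["filter_band"])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)
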