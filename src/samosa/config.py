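"""Schema-validated run configuration for the pipeline.

A single YAML document configures every stage; unknown keys are rejected
and every stochastic stage must carry an explicit seed so that a full run
is reproducible from the config alone.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PatternConfig(_Strict):
    pattern_id: str
    pattern_type: Literal["regular", "irregular"] = "regular"
    weight: float = Field(gt=0)
    n_nucleosomes: int = Field(default=8, ge=1)
    nrl: Optional[int] = None
    footprint: int = 147
    dyad_jitter_sd: float = 2.0
    linker_meth_prob: float = Field(default=0.9, ge=0, le=1)
    occluded_meth_prob: float = Field(default=0.05, ge=0, le=1)
    flank5: int = 0
    flank3: int = 0
    seq_mode: Literal["random", "array601"] = "random"

    @model_validator(mode="after")
    def _check_regular(self):
        if self.pattern_type == "regular" and self.nrl is None:
            raise ValueError("regular pattern requires nrl")
        return self


class IPDConfig(_Strict):
    unmeth_logmean: float = 0.0
    unmeth_logsd: float = 0.5
    meth_logmean: float = 1.1
    meth_logsd: float = 0.5
    context_effect_sd: float = 0.0
    missing_rate: float = Field(default=0.1, ge=0, le=1)


class SimulateConfig(_Strict):
    seed: int
    n_molecules: int = Field(gt=0)
    patterns: list[PatternConfig]
    ipd: IPDConfig = IPDConfig()


class CallConfig(_Strict):
    seed: int
    max_iter: int = 2000
    tol: float = 1e-4
    per_molecule: bool = False
    anchor: Literal["gc", "all", "at"] = "gc"
    score: Literal["AT", "T"] = "AT"
    min_at: int = 20


class FootprintConfig(_Strict):
    mode: Literal["invitro", "invivo"] = "invivo"
    smooth_window: Optional[int] = None  # default: 5 (invitro) / 33 (invivo)
    dyad_window: int = 133
    min_separation: int = 147
    edge_margin: int = 73
    lag_min: int = 120
    lag_max: int = 350
    prominence: float = 0.03
    peak_height: float = 0.1
    max_len_used: int = 1000


class ClusterStageConfig(_Strict):
    seed: int
    k_neighbors: int = 15
    resolution: float = 1.0
    min_len: int = 500
    max_len_used: int = 1000


class EnrichConfig(_Strict):
    fdr: float = 0.1


class RunConfig(_Strict):
    simulate: Optional[SimulateConfig] = None
    call: Optional[CallConfig] = None
    footprint: Optional[FootprintConfig] = None
    cluster: Optional[ClusterStageConfig] = None
    enrich: Optional[EnrichConfig] = None


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
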