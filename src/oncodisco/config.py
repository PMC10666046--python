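"""Pipeline configuration: schema, validation, presets.

The configuration is validated against a versioned pydantic schema before
any stage runs: unknown keys are rejected, range violations are reported
exhaustively (not first-error-only), and the resolved (defaults-filled)
config is echoed into the run report.
"""

from __future__ import annotations

from typing import List, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

from .errors import ConfigError

SCHEMA_VERSION = 1


class CohortBlock(BaseModel, extra="forbid"):
    n_patients: int = Field(500, ge=4)
    n_genes: int = Field(120, ge=2)
    n_prognostic: int = Field(10, ge=0)
    effect_size: float = Field(2.0, ge=0)
    endpoints: List[str] = ["OS", "PFI"]
    augment: int = Field(1500, ge=0)
    top_k: int = Field(25, ge=1)
    folds: int = Field(5, ge=2)


class TissueBlock(BaseModel, extra="forbid"):
    n_tumor: int = Field(300, ge=1)
    n_normal: int = Field(180, ge=1)
    n_discriminative: int = Field(20, ge=0)
    shift: float = 2.0
    select_top_k: int = Field(50, ge=1)
    folds: int = Field(5, ge=2)


class LitmineBlock(BaseModel, extra="forbid"):
    enabled: bool = True
    n_docs: int = Field(250, ge=1)


class DpiBlock(BaseModel, extra="forbid"):
    n_background_proteins: int = Field(40, ge=0)
    n_train_compounds: int = Field(250, ge=10)
    pos_fraction: float = Field(0.05, gt=0, lt=0.5)
    embedding_dim: int = Field(100, ge=2)
    screen_threshold: float = Field(0.9, ge=0, le=1)
    folds: int = Field(5, ge=2)


class PreclinicalBlock(BaseModel, extra="forbid"):
    n_lines: int = Field(36, ge=2)
    n_assay_compounds: int = Field(122, ge=10)
    n_driver_genes: int = Field(15, ge=0)
    steepness: float = Field(4.0, ge=0)
    threshold: float = Field(0.9, ge=0, le=1)
    n_target_lines: int = Field(2, ge=1)
    target_lines: Optional[List[str]] = None  # None: designate from the data
    top_n: int = Field(5, ge=1)
    folds: int = Field(5, ge=2)


class PipelineConfig(BaseModel, extra="forbid"):
    schema_version: int = SCHEMA_VERSION
    seed: int = Field(0, ge=0, lt=2**31)
    out_dir: str = "oncodisco_run"
    cohort: CohortBlock = CohortBlock()
    tissue: TissueBlock = TissueBlock()
    litmine: LitmineBlock = LitmineBlock()
    dpi: DpiBlock = DpiBlock()
    preclinical: PreclinicalBlock = PreclinicalBlock()


#: Synthetic-run presets.  "strong" is the default planted-signal study
#: condition; "weak" halves effect sizes to probe degradation.
PRESETS = {
    "strong": {},
    "weak": {
        "cohort": {"effect_size": 0.6},
        "tissue": {"shift": 0.6},
        "preclinical": {"steepness": 1.5},
    },
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def build_config(
    overrides: Optional[dict] = None,
    preset: Optional[str] = None,
    seed: Optional[int] = None,
    out_dir: Optional[str] = None,
) -> PipelineConfig:
    """Construct a validated config from a preset plus overrides."""
    data: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        data = _deep_update(data, PRESETS[preset])
    if overrides:
        data = _deep_update(data, overrides)
    if seed is not None:
        data["seed"] = seed
    if out_dir is not None:
        data["out_dir"] = out_dir
    try:
        return PipelineConfig(**data)
    except ValidationError as err:
        msgs = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(msgs)) from None


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML config file; empty file = all defaults.

    All type/range violations are listed exhaustively in the raised
    :class:`ConfigError`; the resolved config re-validates to itself.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return build_config(overrides=data)
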