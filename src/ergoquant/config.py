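"""Pipeline configuration: a flat key=value file validated by pydantic.

Every tunable of the generate → calibrate → quantify → call-pathway chain
lives here with its documented default, so a single config file (plus the
seed) pins a fully reproducible pipeline execution.  Unknown keys are
rejected and validation reports the complete list of violations, not just
the first.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional, Tuple

from pydantic import BaseModel, Field, ValidationError, model_validator

__all__ = ["PipelineConfig", "parse_config_file", "validate_config"]


class PipelineConfig(BaseModel, extra="forbid"):
    # scenario / paths
    scenario: str = "deletion_panel"
    out_dir: str = "results"
    runs_dir: Optional[str] = None
    manifest: Optional[str] = None
    calibration: Optional[str] = None
    # generator
    seed: int = 0
    ppm_jitter: float = Field(2.0, ge=0)
    scan_interval: float = Field(0.05, gt=0)
    baseline_noise: float = Field(1.0, ge=0)
    noise_peak_rate: float = Field(20.0, ge=0)
    response_cv: float = Field(0.02, ge=0)
    # quantification
    tol_ppm: float = Field(5.0, gt=0)
    rt_window: float = Field(0.5, gt=0)
    min_snr: float = Field(3.0, gt=0)
    is_weight_hepes: float = Field(0.5, ge=0, le=1)
    is_weight_pipes: float = Field(0.5, ge=0, le=1)
    # pathway calling
    absent_frac: float = Field(0.05, gt=0, lt=1)
    accum_fold: float = Field(5.0, gt=1)
    min_score: float = Field(0.95, gt=0, le=1)

    @model_validator(mode="after")
    def _weights_sum_to_one(self) -> "PipelineConfig":
        total = self.is_weight_hepes + self.is_weight_pipes
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"internal-standard weights must sum to 1 (got {total})")
        return self

    @property
    def is_weights(self) -> dict:
        return {"HEPES": self.is_weight_hepes, "PIPES": self.is_weight_pipes}

    def config_hash(self) -> str:
        """Hash of the scientifically relevant parameters (paths excluded,
        so reruns into different directories compare equal)."""
        payload = json.dumps(
            self.model_dump(exclude={"out_dir", "runs_dir", "manifest", "calibration"}),
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _coerce(value: str):
    value = value.strip()
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value


def parse_config_file(path) -> dict:
    """Parse the flat ``key = value`` format (# comments, blank lines ok)."""
    data = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        data[key.strip()] = _coerce(value)
    return data


def validate_config(path) -> Tuple[Optional[PipelineConfig], List[str]]:
    """Validate a config file; returns the parsed config or every violation."""
    try:
        data = parse_config_file(path)
    except (OSError, ValueError) as exc:
        return None, [str(exc)]
    try:
        return PipelineConfig(**data), []
    except ValidationError as exc:
        errors = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<config>"
            errors.append(f"{loc}: {err['msg']}")
        # cross-field weight check is skipped by pydantic once any field
        # fails; still report it so the violation list is complete
        if not any("weights must sum to 1" in e for e in errors):
            try:
                total = float(data.get("is_weight_hepes", 0.5)) + float(
                    data.get("is_weight_pipes", 0.5)
                )
                if abs(total - 1.0) > 1e-9:
                    errors.append(
                        f"is_weight_hepes/is_weight_pipes: weights must sum to 1 (got {total})"
                    )
            except (TypeError, ValueError):
                pass
        return None, errors
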