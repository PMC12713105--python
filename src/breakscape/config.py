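"""Pipeline configuration with the analysis's canonical default constants."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "validate_config", "load_config"]


@dataclass
class PipelineConfig:
    """Resolutions, thresholds and paths for a full pipeline run.

    Defaults are the analysis's canonical constants: 5 kb DSB bins, 10 kb
    loop anchors, 100 kb compartments, 50 kb TADs, the 0.95/0.8 differential
    probability rule, a 20 kb enhancer-proximity window, 500 TSS-distance
    profile bins, 100 expression bins, 10 ratio classes and busy anchors at
    frequency >= 2.
    """

    bin_width: int = 5000
    loop_resolution: int = 10000
    compartment_resolution: int = 100_000
    tad_resolution: int = 50_000
    p_high: float = 0.95
    p_low: float = 0.8
    enhancer_window: int = 20_000
    n_ratio_bins: int = 500
    n_expr_bins: int = 100
    n_classes: int = 10
    busy_min_frequency: int = 2
    q_threshold: float = 0.05
    fold_threshold: float = 2.0
    pseudocount: float = 0.5
    fpkm_threshold: float = 1.0
    apa_window: int = 10
    seed: int = 0
    outdir: str = "breakscape_out"
    # optional input paths (ignored when --simulate supplies the inputs)
    paths: dict = field(default_factory=dict)


def validate_config(raw: Mapping[str, Any] | PipelineConfig) -> PipelineConfig:
    """Normalise a raw mapping into a PipelineConfig, collecting all errors.

    Missing fields are filled with the defaults; unknown keys warn but do not
    fail; every violated constraint is reported in one error.
    """
    if isinstance(raw, PipelineConfig):
        cfg = raw
    else:
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            warnings.warn(
                f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2
            )
        cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})

    errors: list[str] = []
    for name in (
        "bin_width",
        "loop_resolution",
        "compartment_resolution",
        "tad_resolution",
        "enhancer_window",
        "n_ratio_bins",
        "n_expr_bins",
        "n_classes",
        "busy_min_frequency",
        "apa_window",
    ):
        if getattr(cfg, name) <= 0:
            errors.append(f"{name} must be positive (got {getattr(cfg, name)})")
    for name in ("p_high", "p_low", "q_threshold"):
        if not 0 < getattr(cfg, name) < 1:
            errors.append(f"{name} must be in (0, 1) (got {getattr(cfg, name)})")
    if cfg.p_low >= cfg.p_high:
        errors.append(f"p_low ({cfg.p_low}) must be < p_high ({cfg.p_high})")
    if cfg.pseudocount < 0:
        errors.append("pseudocount must be >= 0")
    if cfg.fold_threshold < 0:
        errors.append("fold_threshold must be >= 0")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return validate_config(raw)
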