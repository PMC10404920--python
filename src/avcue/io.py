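"""Tabular I/O and pipeline configuration.

All tables are comma-separated text with a header row; positions are stored
in screen-proportion units ([0, 1]). ``read_response_table`` validates the
schema and value ranges and reports offending rows by line number, and
accepts a column-mapping for externally produced tables whose headers
differ from the canonical schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .conflict_model import McmcConfig
from .design import DesignConfig
from .observers import CohortSpec

__all__ = [
    "ResponseTableError",
    "read_response_table",
    "write_response_table",
    "PipelineConfig",
]

REQUIRED_COLUMNS = ("observer", "block", "condition", "cues", "hidden", "response")
POSITION_COLUMNS = ("hidden", "visual_source", "audio_loc", "x_v", "x_a", "response")
LEGAL_CONDITIONS = {"single", "congruent", "incongruent"}
LEGAL_BLOCKS = {"calibration", "audio_training", "test"}


class ResponseTableError(ValueError):
    """Schema or value validation failure, with offending rows listed."""


def write_response_table(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_response_table(path, column_mapping: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a per-trial response table.

    ``column_mapping`` maps canonical names to the file's column names
    (e.g. ``{"response": "resp_x"}``) to support external layouts. Rows are
    reported by 1-based data line number (header excluded) on failure.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if column_mapping:
        frame = frame.rename(columns={v: k for k, v in column_mapping.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ResponseTableError(f"missing required column(s): {', '.join(missing)}")

    problems: list[str] = []
    for col in POSITION_COLUMNS:
        if col not in frame.columns:
            continue
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[vals.notna() & ((vals < 0) | (vals > 1))]
        for i in bad[:20]:
            problems.append(f"row {i + 1}: {col}={frame.at[i, col]} outside [0, 1]")
    bad_cond = frame.index[~frame["condition"].isin(LEGAL_CONDITIONS)]
    for i in bad_cond[:20]:
        problems.append(f"row {i + 1}: illegal condition {frame.at[i, 'condition']!r}")
    bad_block = frame.index[~frame["block"].isin(LEGAL_BLOCKS)]
    for i in bad_block[:20]:
        problems.append(f"row {i + 1}: illegal block {frame.at[i, 'block']!r}")
    if problems:
        raise ResponseTableError("invalid response table:\n" + "\n".join(problems))
    return frame


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the end-to-end pipeline reproducibly."""

    design: DesignConfig = field(default_factory=DesignConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    calibration_method: str = "corrected"
    fit_switching: bool = True
    credible_level: float = 0.95
    outdir: str = "avcue_output"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.calibration_method not in ("corrected", "naive"):
            raise ValueError(f"unknown calibration method {self.calibration_method!r}")
        if not 0.0 < self.credible_level < 1.0:
            raise ValueError("credible_level must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "design" in kwargs:
            d = dict(kwargs["design"])
            for key in ("locations", "intermittent"):
                if key in d:
                    d[key] = tuple(d[key])
            kwargs["design"] = DesignConfig(**d)
        if "cohort" in kwargs:
            c = dict(kwargs["cohort"])
            for key, v in c.items():
                if isinstance(v, list):
                    c[key] = tuple(v)
            kwargs["cohort"] = CohortSpec(**c)
        if "mcmc" in kwargs:
            m = dict(kwargs["mcmc"])
            if "sigma_prior" in m:
                m["sigma_prior"] = tuple(m["sigma_prior"])
            kwargs["mcmc"] = McmcConfig(**m)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        def plain(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {k: plain(getattr(obj, k)) for k in obj.__dataclass_fields__}
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            return obj

        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(plain(self), fh, sort_keys=False)
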