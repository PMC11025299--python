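"""CSV/YAML serialization, configuration parsing and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import HypothesisSpec, InvalidDataError, StudyData
from .datagen import BiomarkerConfig, LfcConfig, TruthTable
from .mcp import PROCEDURES, MBetaConfig


class ConfigError(ValueError):
    pass


# --------------------------------------------------------------- study data

def read_study_csv(path: str | Path) -> StudyData:
    """Read subject-level data: column ``disease`` then one 0/1 column per test."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise InvalidDataError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise InvalidDataError(f"{path}: need a disease column plus at least one test column")
    if df.columns[0] != "disease":
        raise InvalidDataError(f"{path}: first column must be named 'disease', got {df.columns[0]!r}")
    if df.isna().any().any():
        rows = np.flatnonzero(df.isna().any(axis=1))[:5] + 2  # 1-based + header
        raise InvalidDataError(f"{path}: missing values near line(s) {list(rows)}")
    for col in df.columns:
        bad = ~df[col].isin((0, 1))
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2
            raise InvalidDataError(f"{path}: non-binary value in column {col!r} at line {line}")
    return StudyData(
        disease_status=df["disease"].to_numpy(),
        test_results=df.iloc[:, 1:].to_numpy(),
        test_labels=tuple(df.columns[1:]),
    )


def write_study_csv(data: StudyData, path: str | Path) -> None:
    df = pd.DataFrame(data.test_results, columns=list(data.test_labels))
    df.insert(0, "disease", data.disease_status)
    df.to_csv(path, index=False)


def write_truth_csv(truth: TruthTable, path: str | Path,
                    labels: tuple[str, ...] | None = None) -> None:
    m = truth.m
    df = pd.DataFrame({
        "test": labels if labels else [f"T{j + 1}" for j in range(m)],
        "se_true": truth.se_true,
        "sp_true": truth.sp_true,
        "true_null": truth.null_mask.astype(int) if truth.null_mask is not None else [""] * m,
    })
    df.to_csv(path, index=False)


# ------------------------------------------------------------- configuration

@dataclass(frozen=True)
class RunConfig:
    """Validated analysis configuration with the package defaults."""

    se0: float = 0.8
    sp0: float = 0.8
    alpha: float = 0.025
    shrinkage: float = 0.5
    procedures: tuple[str, ...] = ("maxt",)
    B: int = 2000
    seed: int = 0
    lfc_pr: float = 1.0
    posterior_draws: int = 10_000
    weight_dist: str = "normal"

    def hypothesis(self) -> HypothesisSpec:
        return HypothesisSpec(se0=self.se0, sp0=self.sp0, alpha=self.alpha)

    def mbeta(self) -> MBetaConfig:
        return MBetaConfig(lfc_pr=self.lfc_pr, posterior_draws=self.posterior_draws)


_RUN_KEYS = set(RunConfig.__dataclass_fields__)


def parse_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config; unknown keys are rejected, defaults applied."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    if "procedures" in raw:
        procs = raw["procedures"]
        if isinstance(procs, str):
            procs = [procs]
        raw["procedures"] = tuple(procs)
    cfg = RunConfig(**raw)
    for p in cfg.procedures:
        if p not in PROCEDURES:
            raise ConfigError(f"unknown procedure {p!r} in key 'procedures'")
    for key in ("se0", "sp0"):
        v = getattr(cfg, key)
        if not 0 < v < 1:
            raise ConfigError(f"key {key!r} must lie in (0, 1), got {v}")
    if not 0 < cfg.alpha < 0.5:
        raise ConfigError(f"key 'alpha' must lie in (0, 0.5), got {cfg.alpha}")
    if not 0 <= cfg.lfc_pr <= 1:
        raise ConfigError(f"key 'lfc_pr' must lie in [0, 1], got {cfg.lfc_pr}")
    if cfg.shrinkage < 0:
        raise ConfigError("key 'shrinkage' must be non-negative")
    if cfg.B < 100:
        raise ConfigError("key 'B' must be >= 100")
    return cfg


def parse_generator_config(raw: dict) -> LfcConfig | BiomarkerConfig:
    """Build a generator from a config mapping with a ``setting`` key."""
    if not isinstance(raw, dict) or "setting" not in raw:
        raise ConfigError("generator config must be a mapping with a 'setting' key")
    raw = dict(raw)
    setting = raw.pop("setting")
    try:
        if setting == "lfc":
            if "b" in raw:
                raw["b"] = tuple(raw["b"])
            return LfcConfig(**raw)
        if setting == "biomarker":
            raw["cutpoints"] = tuple((int(k), float(c)) for k, c in raw["cutpoints"])
            if isinstance(raw.get("auc"), (int, float)):
                raw["auc"] = (float(raw["auc"]),) * int(raw["l"])
            else:
                raw["auc"] = tuple(raw.get("auc", ()))
            return BiomarkerConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"invalid generator config: {exc}") from exc
    raise ConfigError(f"unknown setting {setting!r}; expected 'lfc' or 'biomarker'")


def generator_to_dict(gen: LfcConfig | BiomarkerConfig) -> dict:
    d = asdict(gen)
    d["setting"] = "lfc" if isinstance(gen, LfcConfig) else "biomarker"
    if "cutpoints" in d:
        d["cutpoints"] = [list(cp) for cp in d["cutpoints"]]
    if "b" in d:
        d["b"] = list(d["b"])
    if "auc" in d:
        d["auc"] = list(d["auc"])
    return d


# ------------------------------------------------------------------ manifest

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    seeds: dict
    package_version: str
    timestamp: str = ""
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[p.name] = _sha256(p)

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[p.name] = _sha256(p)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
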