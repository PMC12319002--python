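"""Pipeline configuration: YAML loading with validated defaults."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ahp import DEFAULT_RANDOM_INDEX, SaatyMapping
from .delphi import CA_TABLES, FAMILIARITY_LEVELS, ScreeningConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; ``None`` paths fall back to the
    bundled reference fixtures."""

    hierarchy_path: Path | None = None
    round1_scores: Path | None = None
    round1_votes: Path | None = None
    round1_authority: Path | None = None
    round2_scores: Path | None = None
    round2_votes: Path | None = None
    round2_authority: Path | None = None
    means_path: Path | None = None
    output_dir: Path = Path("delphiahp_out")
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    saaty_mapping: SaatyMapping = field(default_factory=SaatyMapping)
    random_index: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RANDOM_INDEX)
    )
    ca_tables: dict = field(default_factory=lambda: {k: dict(v) for k, v in CA_TABLES.items()})
    familiarity_levels: dict = field(default_factory=lambda: dict(FAMILIARITY_LEVELS))
    stats_decimals: int = 2
    weight_decimals: int = 4
    seed: int = 0

    def validate_paths(self) -> None:
        for name in (
            "hierarchy_path",
            "round1_scores",
            "round1_votes",
            "round1_authority",
            "round2_scores",
            "round2_votes",
            "round2_authority",
            "means_path",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def _path_or_none(v) -> Path | None:
    return None if v in (None, "", "builtin") else Path(v)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file; missing blocks keep defaults.

    Recognised blocks: ``paths:``, ``screening:``, ``saaty_mapping:``,
    ``random_index:``, ``authority:``, ``report:``, ``seed:``.
    """
    cfg = PipelineConfig()
    if path is None:
        return cfg
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}

    paths = doc.get("paths", {})
    for key, attr in (
        ("hierarchy", "hierarchy_path"),
        ("round1_scores", "round1_scores"),
        ("round1_votes", "round1_votes"),
        ("round1_authority", "round1_authority"),
        ("round2_scores", "round2_scores"),
        ("round2_votes", "round2_votes"),
        ("round2_authority", "round2_authority"),
        ("means", "means_path"),
    ):
        if key in paths:
            setattr(cfg, attr, _path_or_none(paths[key]))
    if "output_dir" in paths:
        cfg.output_dir = Path(paths["output_dir"])

    if "screening" in doc:
        cfg.screening = ScreeningConfig(**doc["screening"])
    if "saaty_mapping" in doc:
        cfg.saaty_mapping = SaatyMapping.from_config(doc["saaty_mapping"])
    if "random_index" in doc:
        cfg.random_index = {int(k): float(v) for k, v in doc["random_index"].items()}
    auth = doc.get("authority", {})
    if "ca_tables" in auth:
        cfg.ca_tables = {k: dict(v) for k, v in auth["ca_tables"].items()}
    if "familiarity_levels" in auth:
        cfg.familiarity_levels = dict(auth["familiarity_levels"])
    report = doc.get("report", {})
    cfg.stats_decimals = int(report.get("stats_decimals", cfg.stats_decimals))
    cfg.weight_decimals = int(report.get("weight_decimals", cfg.weight_decimals))
    cfg.seed = int(doc.get("seed", cfg.seed))
    return cfg
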