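"""Flat key-value configuration shared by the CLI and the pipeline.

Keys are namespaced (``chunk.window``, ``anchors.seed_len``,
``detector.r_high``, ``paint.hierarchy`` ...) and map onto the dataclass
parameters of the corresponding modules.  Unknown keys are rejected.
Config files are INI-style flat ``key = value`` lines; ``#`` starts a
comment.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields

from .anchors import AnchorParams
from .chunker import chunk_cds  # noqa: F401  (re-export convenience)
from .detector import DetectorConfig
from .haplopaint import DEFAULT_HIERARCHY, PaintConfig

__all__ = ["ScanConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or unparsable values."""


@dataclass
class ScanConfig:
    """All tunables of the scan and painting stages, with their defaults."""

    chunk_window: int = 10_000
    chunk_min_tail: int = 100
    anchors_seed_len: int = 12
    anchors_match_score: int = 5
    anchors_mismatch_score: int = -4
    anchors_xdrop: int = 30
    anchors_min_anchor_score: int = 70
    anchors_min_identity: float = 0.7
    anchors_width: int = 750
    anchors_height: int = 750
    detector_min_copies: int = 5
    detector_gap_split_factor: float = 2.0
    detector_min_gap: int = 500
    detector_period_tolerance: int = 2
    detector_min_confidence: float = 0.80
    detector_r_low: float = 0.9
    detector_r_high: float = 1.1
    paint_slice_len: int = 100_000
    paint_window_len: int = 10_000
    paint_max_snps_per_window: int = 3
    paint_hierarchy: str = ",".join(DEFAULT_HIERARCHY)
    seed: int = 0
    verbose: bool = False

    @classmethod
    def _key_map(cls) -> dict[str, str]:
        return {f.name.replace("_", ".", 1) if "_" in f.name else f.name: f.name
                for f in fields(cls)}

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "ScanConfig":
        cfg = cls()
        cfg.update(mapping)
        return cfg

    def update(self, mapping: dict[str, str]) -> None:
        key_map = self._key_map()
        for key, value in mapping.items():
            attr = key_map.get(key)
            if attr is None:
                raise ConfigError(f"unknown config key {key!r}")
            current = getattr(self, attr)
            try:
                if isinstance(current, bool):
                    parsed = str(value).lower() in ("1", "true", "yes", "on")
                elif isinstance(current, int):
                    parsed = int(value)
                elif isinstance(current, float):
                    parsed = float(value)
                else:
                    parsed = str(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad value for {key}: {value!r}") from exc
            setattr(self, attr, parsed)

    @classmethod
    def from_file(cls, path) -> "ScanConfig":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected key = value")
                key, value = (x.strip() for x in line.split("=", 1))
                mapping[key] = value
        return cls.from_mapping(mapping)

    # views onto the per-module parameter objects -------------------------

    def anchor_params(self) -> AnchorParams:
        return AnchorParams(
            seed_len=self.anchors_seed_len,
            match_score=self.anchors_match_score,
            mismatch_score=self.anchors_mismatch_score,
            xdrop=self.anchors_xdrop,
            min_anchor_score=self.anchors_min_anchor_score,
            min_identity=self.anchors_min_identity)

    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(
            min_copies=self.detector_min_copies,
            gap_split_factor=self.detector_gap_split_factor,
            min_gap=self.detector_min_gap,
            period_tolerance=self.detector_period_tolerance,
            min_confidence=self.detector_min_confidence,
            r_low=self.detector_r_low,
            r_high=self.detector_r_high)

    def paint_config(self) -> PaintConfig:
        return PaintConfig(
            slice_len=self.paint_slice_len,
            window_len=self.paint_window_len,
            max_snps_per_window=self.paint_max_snps_per_window,
            hierarchy=tuple(x.strip() for x in self.paint_hierarchy.split(",")
                            if x.strip()))
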