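"""Pipeline configuration: analysis settings and protocol files.

A single YAML file can override any of the analysis defaults and/or define
the exam protocol::

    protocol:
      repetitions: 3
      inter_epoch_buffer_s: [5, 15]
      sequence:
        - {position: rest, duration_s: 30, active_side: none}
        - {position: posture_unimanual_dominant, duration_s: 30, active_side: right}
        ...
    filter: {low_cut_hz: 0.5, high_cut_hz: 25, order: 4}
    estimator: {segment_s: 10, overlap: 0.5, window: hann}
    band: [1, 20]
    trim_s: 1.0
    markers: {threshold_k: 10, debounce_s: 0.5}
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .preprocess import FilterSpec
from .segmentation import Position, ProtocolDef, ProtocolEntry, default_protocol
from .spectral import DEFAULT_BAND


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable analysis parameters with their defaults."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    segment_s: float = 10.0
    overlap: float = 0.5
    window: str = "hann"
    band: tuple[float, float] = DEFAULT_BAND
    trim_s: float = 1.0
    threshold_k: float = 10.0
    debounce_s: float = 0.5

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d


def config_hash(config: AnalysisConfig, protocol: ProtocolDef) -> str:
    """Stable hash of the full configuration (identical configs ⇒ identical hash)."""
    payload = {
        "analysis": config.to_dict(),
        "protocol": protocol_to_dict(protocol),
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def protocol_to_dict(protocol: ProtocolDef) -> dict:
    return {
        "repetitions": protocol.repetitions,
        "inter_epoch_buffer_s": list(protocol.inter_epoch_buffer_s),
        "epoch_duration_s": protocol.epoch_duration_s,
        "sequence": [
            {
                "position": e.position.value,
                "duration_s": e.duration_s,
                "active_side": e.active_side,
            }
            for e in protocol.sequence
        ],
    }


def protocol_from_dict(d: dict) -> ProtocolDef:
    try:
        seq = tuple(
            ProtocolEntry(
                position=Position(e["position"]),
                duration_s=float(e.get("duration_s", 30.0)),
                active_side=str(e.get("active_side", "both")),
            )
            for e in d["sequence"]
        )
    except (KeyError, ValueError) as exc:
        raise ConfigurationError(f"invalid protocol definition: {exc}") from exc
    return ProtocolDef(
        sequence=seq,
        repetitions=int(d.get("repetitions", 3)),
        inter_epoch_buffer_s=tuple(d.get("inter_epoch_buffer_s", (5.0, 15.0))),
        epoch_duration_s=float(d.get("epoch_duration_s", 30.0)),
    )


def load_config(path: str | Path | None) -> tuple[AnalysisConfig, ProtocolDef]:
    """Load analysis config + protocol from YAML; missing keys take defaults."""
    if path is None:
        return AnalysisConfig(), default_protocol()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    filt = FilterSpec(**raw.get("filter", {}))
    est = raw.get("estimator", {})
    markers = raw.get("markers", {})
    cfg = AnalysisConfig(
        filter=filt,
        segment_s=float(est.get("segment_s", 10.0)),
        overlap=float(est.get("overlap", 0.5)),
        window=str(est.get("window", "hann")),
        band=tuple(raw.get("band", DEFAULT_BAND)),
        trim_s=float(raw.get("trim_s", 1.0)),
        threshold_k=float(markers.get("threshold_k", 10.0)),
        debounce_s=float(markers.get("debounce_s", 0.5)),
    )
    proto = (
        protocol_from_dict(raw["protocol"]) if "protocol" in raw else default_protocol()
    )
    return cfg, proto
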