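"""Protocol-driven segmentation of a recording into labeled epochs.

The structured exam records a fixed sequence of upper-limb positions, each
held for 30 s, repeated three times.  A flashlight pulse registered by the
watch photodiode brackets every *active* (tremor-eliciting) position; the
rest position and the prescribed intervening rest periods are not marked and
are recovered from the protocol timing instead.

Sample indexing is 0-based; all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataError, SegmentationError


class Position(str, Enum):
    """Exam positions of the structured tremor protocol."""

    REST = "rest"
    POSTURE_UNIMANUAL_DOMINANT = "posture_unimanual_dominant"
    POSTURE_UNIMANUAL_NONDOMINANT = "posture_unimanual_nondominant"
    POSTURE_BIMANUAL = "posture_bimanual"
    WING = "wing"
    ACTION_LOADING = "action_loading"


@dataclass(frozen=True)
class ProtocolEntry:
    """One position in the per-repetition exam sequence.

    ``active_side`` is which arm performs the position ("left", "right",
    "both") or "none" for rest.  Rest entries are not light-marked.
    """

    position: Position
    duration_s: float
    active_side: str  # left | right | both | none

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("entry duration must be positive")
        if self.active_side not in ("left", "right", "both", "none"):
            raise ConfigurationError(
                f"active_side must be left/right/both/none, got {self.active_side!r}"
            )

    @property
    def marked(self) -> bool:
        """Whether this entry is bracketed by light pulses."""
        return self.position is not Position.REST


@dataclass(frozen=True)
class ProtocolDef:
    """Ordered exam sequence, repetition count and timing tolerances."""

    sequence: tuple[ProtocolEntry, ...]
    repetitions: int = 3
    inter_epoch_buffer_s: tuple[float, float] = (5.0, 15.0)
    epoch_duration_s: float = 30.0

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")
        if not self.sequence:
            raise ConfigurationError("protocol sequence must be non-empty")
        lo, hi = self.inter_epoch_buffer_s
        if not (0 <= lo <= hi):
            raise ConfigurationError("inter_epoch_buffer_s must satisfy 0 <= lo <= hi")

    @property
    def marked_entries(self) -> tuple[ProtocolEntry, ...]:
        return tuple(e for e in self.sequence if e.marked)

    @property
    def n_marked_per_repetition(self) -> int:
        return len(self.marked_entries)

    @property
    def nominal_buffer_s(self) -> float:
        """Midpoint of the buffer range, used to anchor unmarked rest windows."""
        lo, hi = self.inter_epoch_buffer_s
        return 0.5 * (lo + hi)


def default_protocol(dominant_side: str = "right") -> ProtocolDef:
    """The default structured exam.

    Per repetition: an opening rest position; unimanual extended-arm posture
    with each arm (the contralateral arm rests); an intervening rest period;
    bimanual extended-arm posture; wing position; then the loaded drinking
    action performed by each arm.  Repeated three times, 30 s per position,
    5–15 s buffer between positions.  Each wrist therefore rests during 12
    windows per session: 6 dedicated rest periods plus 6 contralateral
    unimanual epochs.
    """
    if dominant_side not in ("left", "right"):
        raise ConfigurationError("dominant_side must be 'left' or 'right'")
    other = "left" if dominant_side == "right" else "right"
    d = 30.0
    seq = (
        ProtocolEntry(Position.REST, d, "none"),
        ProtocolEntry(Position.POSTURE_UNIMANUAL_DOMINANT, d, dominant_side),
        ProtocolEntry(Position.POSTURE_UNIMANUAL_NONDOMINANT, d, other),
        ProtocolEntry(Position.REST, d, "none"),
        ProtocolEntry(Position.POSTURE_BIMANUAL, d, "both"),
        ProtocolEntry(Position.WING, d, "both"),
        ProtocolEntry(Position.ACTION_LOADING, d, dominant_side),
        ProtocolEntry(Position.ACTION_LOADING, d, other),
    )
    return ProtocolDef(sequence=seq)


@dataclass(frozen=True)
class Epoch:
    """A labeled half-open sample interval ``[start, end)`` of one recording."""

    position: Position
    repetition: int  # 1-based
    start: int
    end: int  # exclusive
    source_wrist: str  # wrist the samples come from: left | right
    active_side: str  # which arm the protocol entry engaged
    derived_rest: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SegmentationError(
                f"invalid epoch interval [{self.start}, {self.end})"
            )
        if self.repetition < 1:
            raise SegmentationError("repetition index is 1-based")

    @property
    def n_samples(self) -> int:
        return self.end - self.start


def detect_light_markers(
    light: Sequence[float],
    sample_rate: float,
    threshold_k: float = 10.0,
    debounce_s: float = 0.5,
) -> list[int]:
    """Detect flashlight pulse onsets in the photodiode channel.

    A marker is the first sample of each maximal run where the light level
    exceeds ``median + threshold_k * MAD``; onsets closer than ``debounce_s``
    merge into one marker (flashlight flicker).  Robust statistics make the
    threshold insensitive to ambient-light drift.  Returns a strictly
    increasing list of sample indices (empty when nothing crosses).
    """
    x = np.asarray(light, dtype=float)
    if x.size < 2:
        raise DataError("light channel must have at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise DataError("light channel contains non-finite values")
    if threshold_k <= 0:
        raise ConfigurationError("threshold_k must be positive")

    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    thresh = med + threshold_k * mad
    above = x > thresh
    if not above.any():
        return []

    onsets = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    debounce = int(round(debounce_s * sample_rate))
    markers: list[int] = []
    for idx in onsets.tolist():
        if markers and idx - markers[-1] < debounce:
            continue
        markers.append(idx)
    return markers


def segment_epochs(
    markers: Sequence[int],
    protocol: ProtocolDef,
    recording_length: int,
    sample_rate: float,
    source_wrist: str = "right",
    trim_s: float = 1.0,
) -> list[Epoch]:
    """Assign marker pairs to the protocol's marked entries, in order.

    Marker ``2i``/``2i+1`` bracket the i-th marked protocol entry in
    repetition-major order.  Each epoch is trimmed by ``trim_s`` at both
    edges to suppress transition transients.
    """
    markers = list(markers)
    if len(markers) % 2 != 0:
        raise SegmentationError(
            f"odd number of light markers ({len(markers)}); dangling marker at "
            f"sample {markers[-1]}"
        )
    n_pairs = len(markers) // 2
    expected = protocol.repetitions * protocol.n_marked_per_repetition
    if n_pairs != expected:
        raise SegmentationError(
            f"found {n_pairs} marker pairs but the protocol defines {expected} "
            f"marked epochs ({protocol.n_marked_per_repetition} per repetition "
            f"x {protocol.repetitions})"
        )
    if any(b <= a for a, b in zip(markers, markers[1:])):
        raise SegmentationError("light markers are not strictly increasing")

    trim = int(round(trim_s * sample_rate))
    epochs: list[Epoch] = []
    marked = protocol.marked_entries
    for i in range(n_pairs):
        rep = i // len(marked) + 1
        entry = marked[i % len(marked)]
        start = markers[2 * i] + trim
        end = markers[2 * i + 1] - trim
        if end <= start:
            raise SegmentationError(
                f"epoch {i} collapses after trimming ({trim_s} s each edge): "
                f"markers {markers[2 * i]}..{markers[2 * i + 1]}"
            )
        if end > recording_length:
            raise SegmentationError(
                f"epoch {i} extends past the recording ({end} > {recording_length})"
            )
        epochs.append(
            Epoch(
                position=entry.position,
                repetition=rep,
                start=start,
                end=end,
                source_wrist=source_wrist,
                active_side=entry.active_side,
            )
        )
    return epochs


def derive_rest_epochs(
    epochs: Sequence[Epoch],
    protocol: ProtocolDef,
    wrist: str,
    sample_rate: float,
    trim_s: float = 1.0,
) -> list[Epoch]:
    """Rest epochs for one wrist: dedicated rest windows + contralateral copies.

    Two sources, following the exam design:

    * each unmarked rest entry of the protocol maps to the window of its
      stated duration ending one nominal buffer before the next marked
      epoch's start marker (dedicated rest, ``derived_rest=False``);
    * each unimanual marked epoch whose ``active_side`` is the *other* wrist
      is copied for this wrist (the contralateral arm stays in the rest
      position), flagged ``derived_rest=True``.

    Under :func:`default_protocol` this yields 12 rest epochs per wrist.
    """
    if wrist not in ("left", "right"):
        raise ConfigurationError("wrist must be 'left' or 'right'")
    active = sorted(
        (e for e in epochs if not e.derived_rest and e.position is not Position.REST),
        key=lambda e: e.start,
    )
    if not active:
        return []

    trim = int(round(trim_s * sample_rate))
    buffer = int(round(protocol.nominal_buffer_s * sample_rate))

    # Map epochs back onto marked entries to locate each rest entry's anchor.
    marked_idx = [i for i, e in enumerate(protocol.sequence) if e.marked]
    per_rep = len(marked_idx)
    rest: list[Epoch] = []
    for rep in range(1, protocol.repetitions + 1):
        rep_epochs = active[(rep - 1) * per_rep : rep * per_rep]
        if len(rep_epochs) != per_rep:
            raise SegmentationError(
                f"repetition {rep}: expected {per_rep} active epochs, "
                f"got {len(rep_epochs)}"
            )
        for j, entry in enumerate(protocol.sequence):
            if entry.marked:
                continue
            nxt = next((k for k, m in enumerate(marked_idx) if m > j), None)
            if nxt is None:
                continue  # trailing rest entry: no following anchor, skip
            anchor = rep_epochs[nxt]
            anchor_marker = anchor.start - trim
            dur = int(round(entry.duration_s * sample_rate))
            end = anchor_marker - buffer - trim
            start = end - dur + 2 * trim
            prev_end = rest[-1].end if rest else 0
            if nxt > 0:
                prev_end = max(prev_end, rep_epochs[nxt - 1].end)
            start = max(start, prev_end, 0)
            if end <= start:
                continue
            rest.append(
                Epoch(
                    position=Position.REST,
                    repetition=rep,
                    start=start,
                    end=end,
                    source_wrist=wrist,
                    active_side="none",
                    derived_rest=False,
                )
            )
        for e in rep_epochs:
            if e.active_side in ("left", "right") and e.active_side != wrist:
                rest.append(
                    Epoch(
                        position=Position.REST,
                        repetition=rep,
                        start=e.start,
                        end=e.end,
                        source_wrist=wrist,
                        active_side="none",
                        derived_rest=True,
                    )
                )
    return rest
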