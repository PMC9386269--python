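"""Whole-session orchestration: two wrists in, per-position tremor metrics out.

For each wrist and exam position the pipeline is::

    epoch slice → SI units → demean → band-pass → PC1 projection
                → Welch PSD → band metrics

Per-position results carry both the per-epoch metrics and the metrics of the
averaged spectrum; the averaged-spectrum values are designated the *summary*
(they correspond to the solid mean trace in the per-position spectrum plots).
The session-level rest/posture power ratios flag residual rest tremor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, config_hash, protocol_to_dict
from .device_io import DeviceMeta, RawRecording, to_si
from .errors import TremorKitError
from .preprocess import bandpass, demean
from .segmentation import (
    Epoch,
    Position,
    ProtocolDef,
    default_protocol,
    derive_rest_epochs,
    detect_light_markers,
    segment_epochs,
)
from .spectral import (
    SpectrumEstimate,
    TremorMetrics,
    average_spectra,
    band_metrics,
    pca_first_component,
    power_spectrum,
)


@dataclass
class PositionResult:
    """All epochs of one exam position on one wrist."""

    position: Position
    wrist: str
    epoch_metrics: list[TremorMetrics]
    epoch_spectra: list[SpectrumEstimate]
    mean_spectrum: SpectrumEstimate
    summary_metrics: TremorMetrics
    epochs: list[Epoch]

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_metrics)


@dataclass
class SessionResult:
    """Full analysis of one session (both wrists)."""

    meta: dict[str, DeviceMeta]
    positions: list[PositionResult]
    rest_posture_peak_ratio: dict[str, float]
    rest_posture_total_ratio: dict[str, float]
    run_manifest: dict

    def wrist_positions(self, wrist: str) -> list[PositionResult]:
        return [p for p in self.positions if p.wrist == wrist]

    def metrics_frame(self) -> pd.DataFrame:
        """Long-format metrics table: one row per epoch plus a 'mean' row."""
        rows = []
        for pr in self.positions:
            for ep, m in zip(pr.epochs, pr.epoch_metrics):
                rows.append(
                    {
                        "wrist": pr.wrist,
                        "position": pr.position.value,
                        "repetition": str(ep.repetition),
                        "derived_rest": ep.derived_rest,
                        "peak_frequency_hz": m.peak_frequency_hz,
                        "peak_power": m.peak_power,
                        "total_power": m.total_power,
                        "pc1_variance_fraction": m.pc1_variance_fraction,
                    }
                )
            s = pr.summary_metrics
            rows.append(
                {
                    "wrist": pr.wrist,
                    "position": pr.position.value,
                    "repetition": "mean",
                    "derived_rest": False,
                    "peak_frequency_hz": s.peak_frequency_hz,
                    "peak_power": s.peak_power,
                    "total_power": s.total_power,
                    "pc1_variance_fraction": s.pc1_variance_fraction,
                }
            )
        return pd.DataFrame(rows)


def _analyze_epoch(
    acc_si: np.ndarray,
    epoch: Epoch,
    sample_rate: float,
    config: AnalysisConfig,
) -> tuple[TremorMetrics, SpectrumEstimate]:
    sl = acc_si[epoch.start : epoch.end]
    x = demean(sl.T)  # (3, n), time on the last axis
    x = bandpass(x, sample_rate, config.filter)
    pca = pca_first_component(x.T)
    spec = power_spectrum(
        pca.component_series,
        sample_rate,
        segment_s=config.segment_s,
        overlap=config.overlap,
        window=config.window,
    )
    return band_metrics(spec, config.band, pca.variance_fraction), spec


def analyze_session(
    recordings: dict[str, RawRecording],
    protocol: ProtocolDef | None = None,
    config: AnalysisConfig | None = None,
) -> SessionResult:
    """Run the full pipeline on one session (one recording per wrist).

    ``recordings`` maps "left"/"right" to the corresponding wrist recording;
    a single-wrist session is accepted.  The analysis is deterministic given
    inputs and configuration.
    """
    protocol = protocol or default_protocol()
    config = config or AnalysisConfig()
    if not recordings:
        raise TremorKitError("no recordings supplied")

    positions: list[PositionResult] = []
    peak_ratio: dict[str, float] = {}
    total_ratio: dict[str, float] = {}
    meta: dict[str, DeviceMeta] = {}
    for wrist, rec in sorted(recordings.items()):
        if wrist not in ("left", "right"):
            raise TremorKitError(f"recording key must be left/right, got {wrist!r}")
        meta[wrist] = rec.meta
        rec_si = to_si(rec)
        try:
            markers = detect_light_markers(
                rec.light, rec.sample_rate, config.threshold_k, config.debounce_s
            )
            active = segment_epochs(
                markers,
                protocol,
                rec.n_samples,
                rec.sample_rate,
                source_wrist=wrist,
                trim_s=config.trim_s,
            )
            rest = derive_rest_epochs(
                active, protocol, wrist, rec.sample_rate, trim_s=config.trim_s
            )
        except TremorKitError as exc:
            raise type(exc)(f"[{wrist} wrist] {exc}") from exc

        own = [e for e in active if e.active_side in (wrist, "both")] + rest
        by_pos: dict[Position, list[Epoch]] = {}
        for e in sorted(own, key=lambda e: (e.position.value, e.start)):
            by_pos.setdefault(e.position, []).append(e)

        for pos, eps in by_pos.items():
            metrics, spectra = [], []
            for e in eps:
                try:
                    m, s = _analyze_epoch(
                        rec_si.acceleration, e, rec.sample_rate, config
                    )
                except TremorKitError as exc:
                    raise type(exc)(
                        f"[{wrist} wrist, {pos.value}, rep {e.repetition}] {exc}"
                    ) from exc
                metrics.append(m)
                spectra.append(s)
            mean_spec = average_spectra(spectra)
            summary = band_metrics(
                mean_spec,
                config.band,
                float(np.mean([m.pc1_variance_fraction for m in metrics])),
            )
            positions.append(
                PositionResult(
                    position=pos,
                    wrist=wrist,
                    epoch_metrics=metrics,
                    epoch_spectra=spectra,
                    mean_spectrum=mean_spec,
                    summary_metrics=summary,
                    epochs=eps,
                )
            )

        # Rest/posture ratios: rest vs the unimanual posture this wrist held.
        own_positions = {p.position: p for p in positions if p.wrist == wrist}
        rest_pr = own_positions.get(Position.REST)
        posture_pr = None
        for cand in (
            Position.POSTURE_UNIMANUAL_DOMINANT,
            Position.POSTURE_UNIMANUAL_NONDOMINANT,
        ):
            pr = own_positions.get(cand)
            if pr is not None and any(e.active_side == wrist for e in pr.epochs):
                posture_pr = pr
                break
        if rest_pr and posture_pr:
            if posture_pr.summary_metrics.peak_power > 0:
                peak_ratio[wrist] = (
                    rest_pr.summary_metrics.peak_power
                    / posture_pr.summary_metrics.peak_power
                )
            if posture_pr.summary_metrics.total_power > 0:
                total_ratio[wrist] = (
                    rest_pr.summary_metrics.total_power
                    / posture_pr.summary_metrics.total_power
                )

    manifest = {
        "tool": "tremorkit",
        "version": __version__,
        "config": config.to_dict(),
        "protocol": protocol_to_dict(protocol),
        "config_hash": config_hash(config, protocol),
        "inputs": {
            w: {
                "subject_id": m.subject_id,
                "watch_id": m.watch_id,
                "start_datetime": m.start_datetime.isoformat(),
            }
            for w, m in meta.items()
        },
    }
    return SessionResult(
        meta=meta,
        positions=positions,
        rest_posture_peak_ratio=peak_ratio,
        rest_posture_total_ratio=total_ratio,
        run_manifest=manifest,
    )


def write_session(
    result: SessionResult, out_dir: str | Path, plots: bool = True
) -> dict[str, Path]:
    """Write the metrics table, per-position spectra, manifest and figure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    metrics_path = out / "metrics.csv"
    result.metrics_frame().to_csv(metrics_path, index=False)
    files["metrics"] = metrics_path

    spectra_dir = out / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    for pr in result.positions:
        base = f"{pr.wrist}_{pr.position.value}"
        spath = spectra_dir / f"{base}.csv"
        pd.DataFrame(
            {
                "frequency_hz": pr.mean_spectrum.frequencies,
                "psd_m2s4_per_hz": pr.mean_spectrum.psd,
            }
        ).to_csv(spath, index=False)
        meta = pr.mean_spectrum.estimator_meta
        (spectra_dir / f"{base}.json").write_text(
            json.dumps(
                {
                    "window": meta.window,
                    "segment_s": meta.segment_s,
                    "overlap": meta.overlap,
                    "n_averaged": meta.n_segments,
                    "delta_f_hz": pr.mean_spectrum.delta_f,
                },
                indent=2,
            )
        )
    files["spectra"] = spectra_dir

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(result.run_manifest, indent=2, sort_keys=True))
    files["manifest"] = manifest_path

    if plots:
        files["figure"] = _plot_session(result, out / "spectra_overview.png")
    return files


def _plot_session(result: SessionResult, path: Path) -> Path:
    """Grid of per-position spectra: dotted epoch traces, solid mean."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wrists = sorted({p.wrist for p in result.positions})
    pos_order = [p.value for p in Position]
    cols = max(
        len({p.position for p in result.wrist_positions(w)}) for w in wrists
    )
    fig, axes = plt.subplots(
        len(wrists), cols, figsize=(3.2 * cols, 3.0 * len(wrists)), squeeze=False
    )
    for i, w in enumerate(wrists):
        prs = sorted(
            result.wrist_positions(w), key=lambda p: pos_order.index(p.position.value)
        )
        for j in range(cols):
            ax = axes[i][j]
            if j >= len(prs):
                ax.axis("off")
                continue
            pr = prs[j]
            for spec in pr.epoch_spectra:
                ax.plot(spec.frequencies, spec.psd, ls=":", lw=0.7, color="gray")
            ax.plot(
                pr.mean_spectrum.frequencies, pr.mean_spectrum.psd, lw=1.4, color="C0"
            )
            s = pr.summary_metrics
            ax.set_xlim(0, s.band[1] + 2)
            ax.set_title(
                f"{w} {pr.position.value}\n"
                f"TPwr={s.total_power:.3g} m$^2$/s$^4$, "
                f"peak {s.peak_frequency_hz:.1f} Hz",
                fontsize=8,
            )
            if i == len(wrists) - 1:
                ax.set_xlabel("frequency (Hz)")
            if j == 0:
                ax.set_ylabel("PSD (m$^2$/s$^4$/Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
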