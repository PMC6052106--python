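"""Readers and writers for the interchange formats the pipeline touches.

Continuous EEG is read from EDF or BrainVision through :mod:`mne.io` and
written as a raw float32 binary with a JSON sidecar (rate, channel names,
units, markers); event streams and gaze traces are delimited text; ROI
layouts are an integer label raster (.npy) plus a JSON legend.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousEEG, EventStream, GazeRecording, ROILayout


def read_eeg(path: str | Path) -> tuple[ContinuousEEG, pd.DataFrame]:
    """Read continuous EEG; returns the recording (microvolts) and a marker
    table (onset_ms, label) extracted from annotations or the sidecar.

    Supported: ``.edf``, BrainVision ``.vhdr`` triplets, and the package's
    raw float32 + JSON sidecar format.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".edf", ".vhdr"}:
        import mne

        reader = (mne.io.read_raw_edf if suffix == ".edf"
                  else mne.io.read_raw_brainvision)
        try:
            raw = reader(path, preload=True, verbose="error")
        except Exception as exc:  # malformed header
            raise ValueError(f"cannot parse {path.name}: {exc}") from exc
        data = raw.get_data() * 1e6  # volts -> microvolts
        markers = pd.DataFrame({
            "onset_ms": raw.annotations.onset * 1000.0,
            "label": list(raw.annotations.description),
        })
        eeg = ContinuousEEG(data.T, float(raw.info["sfreq"]),
                            tuple(raw.ch_names))
        return eeg, markers
    if suffix == ".dat":
        return _read_raw_sidecar(path)
    raise ValueError(f"unsupported EEG format {suffix!r}")


def write_eeg(eeg: ContinuousEEG, path: str | Path,
              markers: pd.DataFrame | None = None) -> Path:
    """Write EEG as raw float32 [time x channels] plus a JSON sidecar."""
    path = Path(path).with_suffix(".dat")
    eeg.data.astype("<f4").tofile(path)
    sidecar = {
        "format": "fixglm-raw-eeg",
        "dtype": "<f4",
        "order": "time_by_channel",
        "units": "uV",
        "rate_hz": eeg.rate,
        "n_samples": eeg.n_samples,
        "ch_names": list(eeg.ch_names),
        "reference": eeg.reference,
        "markers": ([] if markers is None else
                    markers.to_dict(orient="records")),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def _read_raw_sidecar(path: Path) -> tuple[ContinuousEEG, pd.DataFrame]:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValueError(f"missing sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("format") != "fixglm-raw-eeg":
        raise ValueError("not a fixglm raw EEG sidecar")
    if meta.get("units") != "uV":
        raise ValueError(f"unit mismatch: expected uV, got {meta.get('units')!r}")
    raw = np.fromfile(path, dtype=meta["dtype"])
    n, c = meta["n_samples"], len(meta["ch_names"])
    if raw.size != n * c:
        raise ValueError(
            f"truncated data: expected {n * c} values, found {raw.size} "
            f"(byte offset {raw.size * 4})")
    eeg = ContinuousEEG(raw.reshape(n, c).astype(float), meta["rate_hz"],
                        tuple(meta["ch_names"]), meta.get("reference", "unknown"))
    markers = pd.DataFrame(meta.get("markers", []),
                           columns=["onset_ms", "label"])
    return eeg, markers


def write_roi_layout(layout: ROILayout, stem: str | Path) -> tuple[Path, Path]:
    """Write a layout as <stem>.npy (labels) + <stem>.json (legend/transform)."""
    stem = Path(stem)
    raster = stem.with_suffix(".npy")
    np.save(raster, layout.labels)
    meta = {
        "legend": {str(k): v for k, v in layout.legend.items()},
        "deg_per_px": layout.deg_per_px,
        "origin_deg": list(layout.origin_deg),
    }
    legend = stem.with_suffix(".json")
    legend.write_text(json.dumps(meta, indent=1))
    return raster, legend


def read_roi_layout(stem: str | Path) -> ROILayout:
    stem = Path(stem)
    labels = np.load(stem.with_suffix(".npy"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    legend = {int(k): v for k, v in meta["legend"].items()}
    return ROILayout(labels, legend, float(meta["deg_per_px"]),
                     tuple(meta["origin_deg"]))


def write_estimates(est, stem: str | Path) -> tuple[Path, Path]:
    """Export kernel estimates as delimited text plus a JSON manifest."""
    stem = Path(stem)
    table = stem.with_suffix(".tsv")
    est.to_frame().to_csv(table, sep="\t", index=False)
    manifest = stem.with_suffix(".json")
    manifest.write_text(json.dumps({
        "condition": est.condition,
        "channels": list(est.ch_names),
        "classes": {k: [float(w.lags_ms[0]), float(w.lags_ms[-1])]
                    for k, w in est.estimates.items()},
        "diagnostics": est.diagnostics,
    }, indent=1, default=float))
    return table, manifest
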