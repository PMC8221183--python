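"""Dataset and artifact plumbing.

The canonical interchange format is a "portable" directory: one numeric
array per trial (``.npy`` or ``.csv``, channels x samples for raw signals,
electrodes x bands x frames for features) plus a ``manifest.json`` carrying
subject/trial/label metadata, the sampling rate and the channel order.
MAT-file sessions (one file per subject, one channels x samples array per
trial) are supported as an import path; trial arrays are auto-detected by
shape because variable naming differs between dataset releases.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import loadmat

from .features import BandFeatureTensor, EEGRecording

__all__ = ["save_dataset", "load_dataset", "save_features", "load_features"]

_MANIFEST = "manifest.json"


def _write_array(path: Path, arr: np.ndarray, fmt: str) -> str:
    if fmt == "npy":
        np.save(path.with_suffix(".npy"), arr)
        return path.with_suffix(".npy").name
    if fmt == "csv":
        if arr.ndim != 2:
            raise ValueError("csv arrays must be 2-D")
        np.savetxt(path.with_suffix(".csv"), arr, delimiter=",")
        return path.with_suffix(".csv").name
    raise ValueError(f"unknown array format {fmt!r}")


def _read_array(path: Path) -> np.ndarray:
    if path.suffix == ".npy":
        return np.load(path)
    if path.suffix == ".csv":
        return np.loadtxt(path, delimiter=",")
    raise ValueError(f"unrecognized array file {path.name!r}")


def save_dataset(out_dir, samples: list, ground_truth: dict | None = None,
                 fmt: str = "npy") -> Path:
    """Write recordings or feature tensors as a portable directory."""
    out = Path(out_dir)
    (out / "arrays").mkdir(parents=True, exist_ok=True)
    entries = []
    meta: dict = {"samples": entries}
    for s in samples:
        stem = out / "arrays" / s.trial_id
        if isinstance(s, EEGRecording):
            fname = _write_array(stem, s.signal, fmt)
            entries.append({
                "kind": "raw", "file": f"arrays/{fname}", "subject_id": s.subject_id,
                "trial_id": s.trial_id, "label": int(s.label),
            })
            meta.setdefault("fs", s.fs)
            meta.setdefault("channel_names", list(s.channel_names))
            if meta["fs"] != s.fs or meta["channel_names"] != list(s.channel_names):
                raise ValueError(f"trial {s.trial_id!r}: inconsistent fs or channel order")
        elif isinstance(s, BandFeatureTensor):
            fname = _write_array(stem, s.values, "npy")  # 3-D: npy only
            entries.append({
                "kind": "features", "file": f"arrays/{fname}",
                "subject_id": s.subject_id, "trial_id": s.trial_id,
                "label": int(s.label), "feature_kind": s.feature_kind,
                "frame_seconds": s.frame_seconds, "valid_T": int(s.valid_T),
            })
        else:
            raise TypeError(f"cannot save sample of type {type(s).__name__}")
    with open(out / _MANIFEST, "w") as fh:
        json.dump(meta, fh, indent=1)
    if ground_truth is not None:
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(ground_truth, fh, indent=1)
    return out


def _load_portable(path: Path) -> list:
    with open(path / _MANIFEST) as fh:
        meta = json.load(fh)
    samples = []
    for e in meta["samples"]:
        f = path / e["file"]
        if not f.exists():
            raise FileNotFoundError(f"manifest entry {e['trial_id']!r}: missing file {f}")
        for key in ("subject_id", "trial_id", "label"):
            if key not in e:
                raise ValueError(f"manifest entry for {f.name!r} lacks {key!r}")
        arr = _read_array(f)
        if e["kind"] == "raw":
            if arr.ndim != 2 or arr.shape[0] != len(meta["channel_names"]):
                raise ValueError(
                    f"trial {e['trial_id']!r}: array shape {arr.shape} inconsistent "
                    f"with {len(meta['channel_names'])} channels"
                )
            samples.append(EEGRecording(
                signal=arr, fs=meta["fs"], channel_names=meta["channel_names"],
                subject_id=e["subject_id"], trial_id=e["trial_id"], label=e["label"],
            ))
        elif e["kind"] == "features":
            samples.append(BandFeatureTensor(
                values=arr, feature_kind=e.get("feature_kind", "de"),
                frame_seconds=e.get("frame_seconds", 1.0),
                subject_id=e["subject_id"], trial_id=e["trial_id"],
                label=e["label"], valid_T=e.get("valid_T", arr.shape[2]),
            ))
        else:
            raise ValueError(f"unknown sample kind {e['kind']!r} in manifest")
    return samples


def _load_seed_mat(path: Path) -> list:
    """Import per-subject MAT sessions (pre-v7.3 files).

    Each ``*.mat`` file holds one channels x samples array per trial; trial
    arrays are detected by being 2-D numeric with a consistent channel
    count, taken in sorted variable-name order.  Labels and the sampling
    rate come from a ``manifest.json`` next to the MAT files mapping file
    name -> {subject_id, labels, fs}.
    """
    manifest_path = path / _MANIFEST
    if not manifest_path.exists():
        raise FileNotFoundError(f"seed-mat layout requires {manifest_path}")
    with open(manifest_path) as fh:
        meta = json.load(fh)
    samples = []
    for fname, info in sorted(meta["files"].items()):
        fpath = path / fname
        if not fpath.exists():
            raise FileNotFoundError(f"manifest lists missing MAT file {fpath}")
        try:
            mat = loadmat(fpath)
        except Exception as exc:
            raise ValueError(f"corrupt MAT file {fpath}") from exc
        arrays = {
            k: v for k, v in mat.items()
            if not k.startswith("__") and isinstance(v, np.ndarray)
            and v.ndim == 2 and np.issubdtype(v.dtype, np.number)
        }
        if not arrays:
            raise ValueError(f"no trial arrays found in {fpath}")
        n_channels = {v.shape[0] for v in arrays.values()}
        if len(n_channels) != 1:
            raise ValueError(f"{fpath}: inconsistent channel counts {sorted(n_channels)}")
        names = sorted(arrays)
        labels = info["labels"]
        if len(labels) != len(names):
            raise ValueError(
                f"{fpath}: {len(labels)} labels for {len(names)} trial arrays"
            )
        channel_names = meta.get(
            "channel_names", [f"E{i + 1:02d}" for i in range(n_channels.pop())]
        )
        for t_idx, (var, label) in enumerate(zip(names, labels)):
            samples.append(EEGRecording(
                signal=np.asarray(arrays[var], dtype=np.float64),
                fs=info.get("fs", meta.get("fs", 200.0)),
                channel_names=channel_names,
                subject_id=info["subject_id"],
                trial_id=f"{info['subject_id']}_t{t_idx:03d}",
                label=int(label),
            ))
    return samples


def load_dataset(path, fmt: str = "portable") -> list:
    """Load all trials with metadata; returns recordings or feature tensors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset path {path} does not exist")
    if fmt == "portable":
        return _load_portable(path)
    if fmt == "seed-mat":
        return _load_seed_mat(path)
    raise ValueError(f"unknown dataset format {fmt!r}")


def save_features(out_dir, samples: list[BandFeatureTensor]) -> Path:
    """Feature-tensor writer: compressed array container + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / "features.npz",
                        **{s.trial_id: s.values for s in samples})
    sidecar = [
        {"trial_id": s.trial_id, "subject_id": s.subject_id, "label": int(s.label),
         "feature_kind": s.feature_kind, "frame_seconds": s.frame_seconds,
         "valid_T": int(s.valid_T)}
        for s in samples
    ]
    with open(out / "features.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return out


def load_features(in_dir) -> list[BandFeatureTensor]:
    in_dir = Path(in_dir)
    with open(in_dir / "features.json") as fh:
        sidecar = json.load(fh)
    samples = []
    with np.load(in_dir / "features.npz") as data:
        for e in sidecar:
            samples.append(BandFeatureTensor(
                values=data[e["trial_id"]], feature_kind=e["feature_kind"],
                frame_seconds=e["frame_seconds"], subject_id=e["subject_id"],
                trial_id=e["trial_id"], label=e["label"], valid_T=e["valid_T"],
            ))
    return samples
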