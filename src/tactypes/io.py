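"""Session container I/O: one HDF5 file per session plus TSV side tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import GroundTruth, Recording

SESSION_FILE = "session.h5"
EVENTS_FILE = "events.tsv"
TRUTH_TYPES_FILE = "truth_types.tsv"


def save_session(out_dir: str | Path, rec: Recording, truth: GroundTruth | None = None) -> Path:
    """Write a session directory: session.h5, events.tsv, truth_types.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / SESSION_FILE, "w") as f:
        f.create_dataset("vm", data=np.asarray(rec.vm, dtype=np.float32))
        f.create_dataset("ecog", data=np.asarray(rec.ecog, dtype=np.float32))
        f.attrs["fs_vm"] = float(rec.fs_vm)
        f.attrs["fs_ecog"] = float(rec.fs_ecog)
        f.attrs["neuron_id"] = int(rec.neuron_id)
    rec.events.to_csv(out / EVENTS_FILE, sep="\t", index=False)
    if truth is not None:
        truth.type_labels.to_csv(out / TRUTH_TYPES_FILE, sep="\t", index=False)
    return out


def load_session(session_dir: str | Path) -> tuple[Recording, pd.DataFrame | None]:
    """Read a session directory back; returns (recording, truth labels or None)."""
    d = Path(session_dir)
    with h5py.File(d / SESSION_FILE, "r") as f:
        vm = f["vm"][:]
        ecog = f["ecog"][:]
        fs_vm = float(f.attrs["fs_vm"])
        fs_ecog = float(f.attrs["fs_ecog"])
        neuron_id = int(f.attrs["neuron_id"])
    events = pd.read_csv(d / EVENTS_FILE, sep="\t")
    rec = Recording(vm=vm, ecog=ecog, events=events, neuron_id=neuron_id,
                    fs_vm=fs_vm, fs_ecog=fs_ecog)
    truth_path = d / TRUTH_TYPES_FILE
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None
    return rec, truth


def windows_to_frame(windows: np.ndarray, meta: pd.DataFrame, neuron_id: int) -> pd.DataFrame:
    """Long-format window table: neuron, label, repetition, sample_ms, value."""
    rows = []
    for (_, m), w in zip(meta.iterrows(), windows):
        rows.append(pd.DataFrame({
            "neuron": neuron_id,
            "label": m.label,
            "repetition": int(m.repetition),
            "sample_ms": np.arange(w.size),
            "value": w,
        }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["neuron", "label", "repetition", "sample_ms", "value"])


def frame_to_windows(df: pd.DataFrame) -> dict[tuple[int, str], tuple[np.ndarray, np.ndarray]]:
    """Invert ``windows_to_frame``: {(neuron, label): (windows, repetitions)}."""
    out = {}
    for (neuron, label), g in df.groupby(["neuron", "label"], sort=True):
        reps = np.sort(g.repetition.unique())
        wins = np.stack([
            g[g.repetition == r].sort_values("sample_ms").value.to_numpy() for r in reps
        ])
        out[(int(neuron), str(label))] = (wins, reps)
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, header_comment: str = "") -> None:
    """TSV with an optional provenance comment line on top."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        if header_comment:
            f.write(f"# {header_comment}\n")
        df.to_csv(f, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
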