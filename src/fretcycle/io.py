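"""Plain-text dataset persistence: one TSV per trace plus a JSON manifest."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .schemes import KineticScheme
from .simulate import PhotophysicsParams, SimulationConfig, Trace, TraceSet, TraceTruth

__all__ = ["write_dataset", "read_dataset"]

_MANIFEST = "manifest.json"


def write_dataset(traceset: TraceSet, directory) -> Path:
    """Write a dataset losslessly: intensities, truth, and the manifest.

    Layout::

        directory/
          manifest.json             # frame_interval, seed, scheme, trace index
          trace_0000.tsv            # frame_index  donor  acceptor
          trace_0000.truth.tsv      # frame_index  state_label   (if truth)
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, tr in enumerate(traceset.traces):
        fname = f"trace_{i:04d}.tsv"
        df = pd.DataFrame(
            {"frame_index": np.arange(tr.n_frames), "donor": tr.donor, "acceptor": tr.acceptor}
        )
        # %.17g round-trips float64 exactly through text
        df.to_csv(directory / fname, sep="\t", index=False, float_format="%.17g")
        entry = {"file": fname, "molecule_id": tr.molecule_id}
        if tr.truth is not None:
            tname = f"trace_{i:04d}.truth.tsv"
            labels = [tr.truth.state_labels[int(s)] for s in tr.truth.state_path]
            pd.DataFrame(
                {"frame_index": np.arange(tr.n_frames), "state_label": labels}
            ).to_csv(directory / tname, sep="\t", index=False)
            entry.update(
                truth_file=tname,
                bleach_frame=int(tr.truth.bleach_frame),
                bleach_time=(None if np.isinf(tr.truth.bleach_time)
                             else float(tr.truth.bleach_time)),
                blink_frames=np.flatnonzero(tr.truth.blink_mask).tolist(),
                active=bool(tr.truth.active),
                state_labels=list(tr.truth.state_labels),
            )
        entries.append(entry)

    cfg = traceset.config
    manifest = {
        "frame_interval": traceset.traces[0].frame_interval if traceset.traces else None,
        "condition": traceset.condition,
        "traces": entries,
    }
    if cfg is not None:
        manifest.update(
            frame_interval=cfg.frame_interval,
            seed=cfg.seed,
            injection_time=cfg.injection_time,
            active_fraction=cfg.active_fraction,
            n_frames=cfg.n_frames,
            scheme=cfg.scheme.to_dict(),
            photophysics=vars(cfg.photophysics),
        )
    with open(directory / _MANIFEST, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return directory


def read_dataset(directory) -> TraceSet:
    """Load a dataset written by :func:`write_dataset` (lossless round trip)."""
    directory = Path(directory)
    path = directory / _MANIFEST
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    with open(path) as fh:
        manifest = json.load(fh)
    for field in ("frame_interval", "traces"):
        if manifest.get(field) is None:
            raise ValueError(f"{path}: manifest missing field {field!r}")
    dt = float(manifest["frame_interval"])

    traces = []
    for entry in manifest["traces"]:
        fpath = directory / entry["file"]
        df = pd.read_csv(fpath, sep="\t", float_precision="round_trip")
        for col in ("donor", "acceptor"):
            if col not in df.columns:
                raise ValueError(f"{fpath}: missing column {col!r}")
        if df[["donor", "acceptor"]].isna().any().any():
            bad = int(df[df[["donor", "acceptor"]].isna().any(axis=1)].index[0])
            raise ValueError(f"{fpath}: ragged or missing values at line {bad + 2}")
        truth: Optional[TraceTruth] = None
        if "truth_file" in entry:
            tdf = pd.read_csv(directory / entry["truth_file"], sep="\t")
            labels = tuple(entry["state_labels"])
            index = {s: i for i, s in enumerate(labels)}
            states = np.array([index[s] for s in tdf["state_label"]], dtype=np.int64)
            blink = np.zeros(len(df), dtype=bool)
            blink[np.asarray(entry.get("blink_frames", []), dtype=int)] = True
            bt = entry.get("bleach_time")
            truth = TraceTruth(
                state_path=states,
                state_labels=labels,
                bleach_frame=int(entry["bleach_frame"]),
                bleach_time=np.inf if bt is None else float(bt),
                blink_mask=blink,
                active=bool(entry.get("active", True)),
            )
        traces.append(
            Trace(entry["molecule_id"], dt, df["donor"].to_numpy(),
                  df["acceptor"].to_numpy(), truth=truth)
        )

    config = None
    if "scheme" in manifest:
        config = SimulationConfig(
            scheme=KineticScheme.from_dict(manifest["scheme"]),
            n_traces=len(traces),
            n_frames=int(manifest["n_frames"]),
            frame_interval=dt,
            photophysics=PhotophysicsParams(**manifest["photophysics"]),
            active_fraction=float(manifest.get("active_fraction", 1.0)),
            injection_time=manifest.get("injection_time"),
            condition=manifest.get("condition", ""),
            seed=int(manifest.get("seed", 0)),
        )
    return TraceSet(traces, config=config, condition=manifest.get("condition", ""))
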