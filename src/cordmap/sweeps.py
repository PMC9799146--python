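"""Sweep container and cohort I/O.

A *sweep* is one stimulation trial's EMG trace from a single muscle/side
channel, together with the full stimulation and recording metadata needed
downstream (who, which muscle, which spinal segment, electrode position,
intensity, timing).  Cohorts are interchanged as a tidy CSV metadata table
plus an HDF5 trace container and a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

#: Fixed rostro-caudal order of the cervical segments under study.
SEGMENTS: tuple[str, ...] = ("C4", "C5", "C6", "C7", "C8", "T1")

SEGMENT_INDEX = {s: i for i, s in enumerate(SEGMENTS)}

SIDES = ("left", "right")
POSITIONS = ("midline", "lateral")
DEPTHS = ("epidural", "subdural")
ASPECTS = ("posterior", "anterior")
ELECTRODES = ("ball", "catheter")

#: Metadata columns of the tidy sweep table, in canonical order.
METADATA_COLUMNS = [
    "sweep_id",
    "participant_id",
    "muscle",
    "side",
    "segment",
    "position",
    "depth",
    "aspect",
    "electrode",
    "intensity",
    "pulse_count",
    "block",
    "stim_onset_time",
    "acquisition_time",
    "sampling_rate",
]


class ConfigurationError(ValueError):
    """Invalid configuration or malformed input metadata."""


@dataclass
class SweepRecord:
    """One stimulation trial's EMG trace plus stimulation/recording metadata.

    Parameters
    ----------
    trace : ndarray
        EMG samples in microvolts.
    stim_onset_time : float
        Time of the first stimulation pulse in seconds from the start of
        ``trace``.
    intensity : float
        Stimulus intensity in mA.
    block : str
        ``"ramp"`` for intensity-ramp sweeps, ``"fixed"`` for fixed-intensity
        blocks at 120 % of midline threshold.
    acquisition_time : float
        Seconds since the start of the experiment; used only for deterministic
        tie-breaking.
    """

    sweep_id: int
    participant_id: str
    muscle: str
    side: str
    segment: str
    position: str
    intensity: float
    pulse_count: int
    stim_onset_time: float
    sampling_rate: float
    trace: np.ndarray
    block: str = "fixed"
    acquisition_time: float = 0.0
    depth: str = "epidural"
    aspect: str = "posterior"
    electrode: str = "ball"

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if not np.all(np.isfinite(self.trace)):
            raise ValueError(f"sweep {self.sweep_id}: trace contains non-finite samples")
        if self.segment not in SEGMENT_INDEX:
            raise ConfigurationError(
                f"sweep {self.sweep_id}: unknown segment {self.segment!r}"
            )
        if self.side not in SIDES:
            raise ConfigurationError(f"sweep {self.sweep_id}: unknown side {self.side!r}")
        if self.position not in POSITIONS:
            raise ConfigurationError(
                f"sweep {self.sweep_id}: unknown position {self.position!r}"
            )
        if self.intensity < 0:
            raise ValueError(f"sweep {self.sweep_id}: negative intensity")
        n = self.trace.size
        if not (0 <= self.stim_onset_time < n / self.sampling_rate):
            raise ValueError(f"sweep {self.sweep_id}: stimulus onset outside trace")

    @property
    def stim_onset_index(self) -> int:
        return int(round(self.stim_onset_time * self.sampling_rate))

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the first stimulation pulse."""
        n = self.trace.size
        return (np.arange(n) / self.sampling_rate - self.stim_onset_time) * 1000.0

    def metadata(self) -> dict:
        d = {k: getattr(self, k) for k in METADATA_COLUMNS}
        return d


def metadata_table(sweeps: Iterable[SweepRecord]) -> pd.DataFrame:
    """Tidy one-row-per-sweep metadata table in canonical column order."""
    rows = [s.metadata() for s in sweeps]
    df = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    return df


def write_cohort(
    sweeps: Sequence[SweepRecord],
    outdir: str | Path,
    ground_truth: dict | None = None,
    extra_manifest: dict | None = None,
) -> dict:
    """Write a cohort as CSV metadata + HDF5 traces + JSON manifest.

    All traces must share length and sampling rate (one recording montage per
    cohort).  Returns the manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not sweeps:
        raise ConfigurationError("cannot write an empty cohort")
    lengths = {s.trace.size for s in sweeps}
    if len(lengths) != 1:
        raise ConfigurationError("all traces in a cohort container must share length")

    meta = metadata_table(sweeps)
    meta_path = outdir / "sweeps.csv"
    meta.to_csv(meta_path, index=False, float_format="%.10g")

    traces = np.stack([s.trace for s in sweeps])
    traces_path = outdir / "traces.h5"
    with h5py.File(traces_path, "w") as f:
        f.create_dataset("traces", data=traces, compression="gzip", compression_opts=4)
        f.create_dataset("sweep_id", data=meta["sweep_id"].to_numpy())

    manifest = {
        "format": "cordmap-cohort",
        "version": 1,
        "n_sweeps": len(sweeps),
        "n_participants": int(meta["participant_id"].nunique()),
        "segments": sorted(meta["segment"].unique(), key=SEGMENT_INDEX.get),
        "muscles": sorted(meta["muscle"].unique()),
        "sampling_rate": float(meta["sampling_rate"].iloc[0]),
        "trace_samples": int(traces.shape[1]),
        "files": {"metadata": meta_path.name, "traces": traces_path.name},
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    if ground_truth is not None:
        gt_path = outdir / "ground_truth.json"
        gt_path.write_text(json.dumps(ground_truth, indent=1, sort_keys=True))
        manifest["files"]["ground_truth"] = gt_path.name
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_cohort(directory: str | Path) -> list[SweepRecord]:
    """Load a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    meta = pd.read_csv(directory / manifest["files"]["metadata"])
    with h5py.File(directory / manifest["files"]["traces"], "r") as f:
        traces = f["traces"][...]
    sweeps = []
    for i, row in enumerate(meta.itertuples(index=False)):
        kw = row._asdict()
        sweeps.append(SweepRecord(trace=traces[i], **kw))
    return sweeps
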