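"""Frame-level fluorescence container and HDF5 I/O."""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TraceSet:
    """Fluorescence traces for a recording.

    F            array (n_neurons, n_trials, n_frames), raw fluorescence (a.u.)
    frame_rate   Hz
    onset_frame  index of the stimulus-onset frame (0-based); at least one
                 second of pre-stimulus baseline must precede it and at least
                 five seconds of post-onset frames follow it
    labels       DataFrame with one row per trial: level_db, laser
    """

    F: np.ndarray
    frame_rate: float
    onset_frame: int
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.F.ndim != 3:
            raise ValueError("F must be neuron x trial x frame")
        if len(self.labels) != self.F.shape[1]:
            raise ValueError("labels length must match the trial axis of F")
        if self.onset_frame < self.frame_rate:
            raise ValueError("need >= 1 s of pre-stimulus baseline frames")
        if self.F.shape[2] < self.onset_frame + 5 * self.frame_rate:
            raise ValueError("need >= 5 s of post-onset frames")

    @property
    def n_neurons(self) -> int:
        return self.F.shape[0]

    @property
    def n_trials(self) -> int:
        return self.F.shape[1]

    def trial_mask(self, level_db: float, laser: str) -> np.ndarray:
        return (
            (self.labels["level_db"].to_numpy() == level_db)
            & (self.labels["laser"].to_numpy() == laser)
        )

    def conditions(self) -> list[tuple[float, str]]:
        uniq = self.labels.drop_duplicates().sort_values(["laser", "level_db"])
        return [(float(r.level_db), str(r.laser)) for r in uniq.itertuples()]


def write_traceset(ts: TraceSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("F", data=ts.F)
        f.create_dataset("onset_frame", data=ts.onset_frame)
        f.create_dataset("frame_rate", data=ts.frame_rate)
        f.create_dataset("level_db", data=ts.labels["level_db"].to_numpy(dtype=float))
        f.create_dataset(
            "laser", data=np.array(ts.labels["laser"], dtype=h5py.string_dtype())
        )


def read_traceset(path) -> TraceSet:
    with h5py.File(path, "r") as f:
        labels = pd.DataFrame(
            {
                "level_db": f["level_db"][...],
                "laser": [s.decode() for s in f["laser"][...]],
            }
        )
        return TraceSet(
            F=f["F"][...],
            frame_rate=float(f["frame_rate"][()]),
            onset_frame=int(f["onset_frame"][()]),
            labels=labels,
        )
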