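"""The single-trial epoch container shared by all analysis stages.

Amplitudes are stored as a dense tensor indexed
``(subject, condition, trial, electrode, time)`` in microvolts, with the
electrode axis ordered as in the attached layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .montage import ElectrodeLayout

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """Single-trial EEG epochs for a multi-subject, multi-condition study.

    Parameters
    ----------
    data
        ``(n_subjects, n_conditions, n_trials, n_electrodes, n_times)``
        amplitudes in microvolts.  Must be finite.
    times
        Time axis in seconds, strictly increasing at ``1/sfreq``.
    sfreq
        Sampling rate in Hz.
    conditions
        Condition labels, one per condition axis entry.
    layout
        Electrode layout; its ids order the electrode axis.
    provenance
        Free-form metadata (seed, generator specs, processing history).
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    conditions: tuple[str, ...]
    layout: ElectrodeLayout
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = tuple(str(c) for c in self.conditions)
        if self.data.ndim != 5:
            raise ValueError("data must be 5-D (subject, condition, trial, electrode, time)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("amplitudes must be finite")
        if self.data.shape[1] != len(self.conditions):
            raise ValueError("condition axis does not match condition labels")
        if self.data.shape[3] != self.layout.n_electrodes:
            raise ValueError("electrode axis does not match layout")
        if self.data.shape[4] != self.times.size:
            raise ValueError("time axis does not match times")
        dt = np.diff(self.times)
        if self.times.size > 1:
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-6, atol=1e-12):
                raise ValueError("time axis spacing must equal 1/sfreq")

    # -- shape accessors ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[3]

    @property
    def n_times(self) -> int:
        return self.data.shape[4]

    # -- indexing helpers ---------------------------------------------------
    def condition_index(self, label: str) -> int:
        try:
            return self.conditions.index(label)
        except ValueError:
            raise KeyError(f"unknown condition {label!r}") from None

    def time_index(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (seconds)."""
        if t < self.times[0] - 0.5 / self.sfreq or t > self.times[-1] + 0.5 / self.sfreq:
            raise ValueError(f"time {t} s outside epoch [{self.times[0]}, {self.times[-1]}] s")
        return int(np.argmin(np.abs(self.times - t)))

    def time_slice(self, window: tuple[float, float]) -> slice:
        """Half-open sample slice covering ``[start, end]`` inclusive of both edges."""
        start, end = window
        if start >= end:
            raise ValueError("window start must precede end")
        i0 = self.time_index(start)
        i1 = self.time_index(end)
        return slice(i0, i1 + 1)

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), provenance=dict(self.provenance))

    def crop(self, tmin: float, tmax: float, origin: float = 0.0) -> "EpochSet":
        """Sub-epoch over ``[origin+tmin, origin+tmax]``, re-timed relative to origin."""
        sl = self.time_slice((origin + tmin, origin + tmax))
        return replace(
            self,
            data=self.data[..., sl].copy(),
            times=self.times[sl] - origin,
            provenance={**self.provenance, "crop": [tmin, tmax, origin]},
        )

    def select_conditions(self, labels) -> "EpochSet":
        idx = [self.condition_index(c) for c in labels]
        return replace(self, data=self.data[:, idx].copy(), conditions=tuple(labels))

    def condition_average(self) -> np.ndarray:
        """Per-subject, per-condition trial average: ``(n_subjects, k, E, T)``."""
        return self.data.mean(axis=2)

    # -- persistence ----------------------------------------------------------
    def save_hdf5(self, path) -> None:
        """Persist to HDF5.

        Schema: ``/amplitudes`` (float32 tensor), ``/time`` (s), ``/labels``
        (condition strings), ``/layout/ids``, ``/layout/positions``,
        ``/provenance`` (JSON string attr), root attr ``sfreq``.
        """
        with h5py.File(path, "w") as f:
            f.create_dataset("amplitudes", data=self.data.astype(np.float32))
            f.create_dataset("time", data=self.times)
            f.create_dataset(
                "labels", data=np.array(self.conditions, dtype=h5py.string_dtype())
            )
            g = f.create_group("layout")
            g.create_dataset("ids", data=np.array(self.layout.ids, dtype=np.int64))
            g.create_dataset("positions", data=self.layout.positions)
            f.attrs["sfreq"] = float(self.sfreq)
            f.attrs["provenance"] = json.dumps(self.provenance, sort_keys=True, default=str)

    @classmethod
    def load_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["amplitudes"][...].astype(float)
            times = f["time"][...]
            labels = tuple(s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][...])
            layout = ElectrodeLayout(
                tuple(int(i) for i in f["layout/ids"][...]), f["layout/positions"][...]
            )
            sfreq = float(f.attrs["sfreq"])
            prov = json.loads(f.attrs["provenance"])
        return cls(data, times, sfreq, labels, layout, prov)

    def export_erp_tsv(self, path) -> None:
        """Write grand-average ERPs (mean over subjects and trials) as TSV.

        Columns: ``condition, electrode, time_s, amplitude_uv``.
        """
        erp = self.data.mean(axis=(0, 2))  # (k, E, T)
        with open(path, "w") as fh:
            fh.write("condition\telectrode\ttime_s\tamplitude_uv\n")
            for ci, cond in enumerate(self.conditions):
                for ei, eid in enumerate(self.layout.ids):
                    for ti, t in enumerate(self.times):
                        fh.write(f"{cond}\t{eid}\t{t:.6f}\t{erp[ci, ei, ti]:.6f}\n")
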