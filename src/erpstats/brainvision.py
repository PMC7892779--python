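"""Minimal reader for BrainVision recordings (.vhdr/.vmrk/.eeg triplets).

Supports binary multiplexed IEEE float32 / int16 data — the common export
configuration — plus an epoching utility driven by a tab-separated event
table (columns: onset_s, condition, word_index).  Output amplitudes are
converted to microvolts using the per-channel resolution and unit.
"""

from __future__ import annotations

import configparser
import os
import re

import numpy as np

from .epochs import EpochSet
from .montage import ElectrodeLayout

__all__ = ["read_brainvision", "read_event_table", "epochs_from_brainvision"]

_UNIT_TO_UV = {"µV": 1.0, "uV": 1.0, "mV": 1e3, "V": 1e6, "": 1.0}


def _parse_vhdr(path: str) -> configparser.ConfigParser:
    cp = configparser.ConfigParser(interpolation=None, strict=False)
    cp.optionxform = str
    with open(path, encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    # drop the non-INI banner line(s) before the first section
    body = text[text.index("[") :]
    cp.read_string(body)
    return cp


def read_brainvision(vhdr_path: str) -> tuple[np.ndarray, float, list[str]]:
    """Read a BrainVision triplet; returns (data (E, T) in µV, sfreq, names)."""
    cp = _parse_vhdr(vhdr_path)
    common = cp["Common Infos"]
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise ValueError("only BINARY DataFormat is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    sfreq = 1e6 / float(common["SamplingInterval"])
    fmt = cp["Binary Infos"]["BinaryFormat"].upper()
    if fmt == "IEEE_FLOAT_32":
        dtype = np.float32
    elif fmt == "INT_16":
        dtype = np.int16
    else:
        raise ValueError(f"unsupported BinaryFormat {fmt!r}")

    names, scales = [], []
    for i in range(1, n_ch + 1):
        raw = cp["Channel Infos"][f"Ch{i}"]
        parts = raw.split(",")
        names.append(parts[0])
        res = float(parts[2]) if len(parts) > 2 and parts[2] else 1.0
        unit = parts[3].strip() if len(parts) > 3 else "µV"
        scales.append(res * _UNIT_TO_UV.get(unit, 1.0))

    eeg_path = os.path.join(os.path.dirname(vhdr_path), common["DataFile"])
    raw = np.fromfile(eeg_path, dtype=dtype)
    if raw.size % n_ch:
        raise ValueError("data file length not a multiple of the channel count")
    data = raw.reshape(-1, n_ch).T.astype(float) * np.asarray(scales)[:, None]
    return data, sfreq, names


def read_event_table(path: str) -> list[dict]:
    """Read a TSV with columns onset_s, condition, word_index."""
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"onset_s", "condition", "word_index"}
        if not required.issubset(header):
            raise ValueError(f"event table must have columns {sorted(required)}")
        idx = {c: header.index(c) for c in header}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            events.append(
                {
                    "onset_s": float(parts[idx["onset_s"]]),
                    "condition": parts[idx["condition"]],
                    "word_index": int(parts[idx["word_index"]]),
                }
            )
    return events


def epochs_from_brainvision(
    vhdr_path: str,
    event_table_path: str,
    layout: ElectrodeLayout,
    window: tuple[float, float],
    word_index: int = 0,
) -> EpochSet:
    """Slice continuous BrainVision data into an EpochSet around the events
    with the given ``word_index``, one subject, trials grouped by condition.

    Channel names must be the layout's electrode ids (as decimal strings).
    Conditions must have equal trial counts; events whose window falls
    outside the recording raise an error.
    """
    data, sfreq, names = read_brainvision(vhdr_path)
    name_ids = [int(re.sub(r"\D", "", n) or -1) for n in names]
    ch_idx = [name_ids.index(i) for i in layout.ids]
    events = [e for e in read_event_table(event_table_path) if e["word_index"] == word_index]
    if not events:
        raise ValueError(f"no events with word_index={word_index}")
    conditions = sorted({e["condition"] for e in events})
    n0 = int(round(window[0] * sfreq))
    n1 = int(round(window[1] * sfreq))
    n_samp = n1 - n0 + 1
    per_cond: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    for e in events:
        onset = int(round(e["onset_s"] * sfreq))
        lo, hi = onset + n0, onset + n1 + 1
        if lo < 0 or hi > data.shape[1]:
            raise ValueError(f"epoch for event at {e['onset_s']} s falls outside the recording")
        per_cond[e["condition"]].append(data[ch_idx, lo:hi])
    counts = {c: len(v) for c, v in per_cond.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"unequal trial counts per condition: {counts}")
    tensor = np.stack([np.stack(per_cond[c]) for c in conditions])[None, ...]
    times = np.arange(n0, n1 + 1) / sfreq
    return EpochSet(
        tensor,
        times,
        sfreq,
        tuple(conditions),
        layout,
        {"source": os.path.basename(vhdr_path), "word_index": word_index},
    )
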