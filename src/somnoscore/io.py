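"""Readers and writers: TSV interchange formats, EDF signals, model archives.

TSV files are tab-separated with ``#``-prefixed comment headers and 1-based
epoch numbers on disk (internally everything is 0-based).  EDF is the only
supported raw-signal container; reading goes through :mod:`mne`.  A minimal
EDF *writer* (plain EDF, 16-bit records) is included so simulated recordings
can round-trip — no installed library writes EDF.
"""

from __future__ import annotations

import fnmatch
import struct
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .core import (EPOCH_LENGTH_S, Hypnogram, N_STAGES, RaterPanel, STAGES,
                   SignalRecord)

#: Archive/file schema version; bumped on incompatible layout changes.
SCHEMA_VERSION = "1"

_HEADER = f"# somnoscore schema={SCHEMA_VERSION}"


# ---------------------------------------------------------------------------
# Hypnogram TSV
# ---------------------------------------------------------------------------

def write_hypnogram_tsv(h: Hypnogram, path) -> None:
    """Write ``epoch<TAB>stage`` (+ per-stage probabilities when present)."""
    lines = [_HEADER,
             f"# epoch_length_s={h.epoch_length:g} start_offset_s={h.start_offset:g}",
             "# epochs are numbered from 1"]
    cols = ["epoch", "stage"] + ([f"p_{s}" for s in STAGES]
                                 if h.probabilities is not None else [])
    lines.append("\t".join(cols))
    for t, s in enumerate(h.stages):
        row = [str(t + 1), s]
        if h.probabilities is not None:
            row += [repr(float(v)) for v in h.probabilities[t]]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_hypnogram_tsv(path) -> Hypnogram:
    epoch_length, start_offset = EPOCH_LENGTH_S, 0.0
    stages, probs = [], []
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("epoch_length_s="):
                        epoch_length = float(tok.split("=")[1])
                    elif tok.startswith("start_offset_s="):
                        start_offset = float(tok.split("=")[1])
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            stage = parts[1]
            if stage not in STAGES:
                raise ValueError(f"{path}:{lineno}: unknown stage token {stage!r}")
            stages.append(stage)
            if len(parts) > 2:
                probs.append([float(v) for v in parts[2:2 + N_STAGES]])
    if not stages:
        raise ValueError(f"{path}: empty hypnogram")
    return Hypnogram(stages=stages,
                     probabilities=np.array(probs) if probs else None,
                     epoch_length=epoch_length, start_offset=start_offset)


# ---------------------------------------------------------------------------
# Rater panel TSV (one stage column per rater; blank = rater skipped epoch)
# ---------------------------------------------------------------------------

def write_rater_tsv(panel: RaterPanel, path) -> None:
    m_max = int(panel.m.max())
    lines = [_HEADER, "\t".join(["epoch"] + [f"rater{j + 1}"
                                             for j in range(m_max)])]
    for t, labels in enumerate(panel.labels):
        row = [str(t + 1)] + list(labels) + [""] * (m_max - len(labels))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_rater_tsv(path) -> RaterPanel:
    labels: list[list[str]] = []
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            row = [p for p in parts[1:] if p != ""]
            bad = [p for p in row if p not in STAGES]
            if bad:
                raise ValueError(f"{path}:{lineno}: unknown stage token {bad[0]!r}")
            if not row:
                raise ValueError(f"{path}:{lineno}: epoch with zero labels")
            labels.append(row)
    if not labels:
        raise ValueError(f"{path}: empty rater file")
    return RaterPanel(labels)


# ---------------------------------------------------------------------------
# Feature table TSV
# ---------------------------------------------------------------------------

def write_features_tsv(df: pd.DataFrame, path) -> None:
    dens = {c: float(df[c].iloc[0]) for c in
            ("spindle_density", "rem_density", "sem_density") if c in df}
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        if dens:
            fh.write("# " + " ".join(f"{k}={v!r}" for k, v in dens.items())
                     + "\n")
        out = df.copy()
        out.insert(0, "epoch", np.arange(1, len(df) + 1))
        out.to_csv(fh, sep="\t", index=False, float_format=None)


def read_features_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.drop(columns=["epoch"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Certainty track TSV
# ---------------------------------------------------------------------------

def write_certainty_tsv(track, path) -> None:
    """Per-epoch category and up to two candidate stages with their p*."""
    lines = [_HEADER, "epoch\tcategory\tstage1\tp1\tstage2\tp2"]
    for t in range(len(track)):
        cands = track.candidate_stages[t][:2]
        vals = [repr(float(track.star_p[t][STAGES.index(s)])) for s in cands]
        row = [str(t + 1), track.category[t]]
        for s, v in zip(cands, vals):
            row += [s, v]
        row += [""] * (6 - len(row))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialise a fitted model with a schema-version stamp."""
    joblib.dump({"schema_version": SCHEMA_VERSION, "model": model}, path)


def load_model(path):
    """Load a model archive, refusing incompatible schema versions."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"unreadable model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ValueError(f"{path} is not a somnoscore model archive")
    found = payload["schema_version"]
    if found != SCHEMA_VERSION:
        raise ValueError(
            f"model archive schema {found!r} incompatible with this version "
            f"({SCHEMA_VERSION!r})")
    return payload["model"]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

@dataclass
class ChannelMap:
    """Role -> channel-label glob patterns.

    Every configured role must resolve to exactly one channel (EMG: one or
    more).  Roles mapped to None are declared absent.
    """

    eeg: str | None = "EEG*"
    eog_l: str | None = "EOG*L*"
    eog_r: str | None = "EOG*R*"
    emg: str | None = "EMG*"
    sao2: str | None = None
    position: str | None = None
    mic: str | None = None

    def resolve(self, labels: list[str]) -> dict:
        out: dict = {}
        roles = {"EEG": self.eeg, "EOG_L": self.eog_l, "EOG_R": self.eog_r,
                 "SAO2": self.sao2, "POSITION": self.position, "MIC": self.mic}
        missing = []
        for role, pattern in roles.items():
            if pattern is None:
                continue
            hits = fnmatch.filter(labels, pattern)
            if len(hits) == 1:
                out[role] = hits[0]
            elif len(hits) > 1:
                raise ValueError(f"ambiguous label match for {role}: {hits}")
            else:
                missing.append(role)
        if self.emg is not None:
            hits = fnmatch.filter(labels, self.emg)
            if hits:
                out["EMG"] = hits
            else:
                missing.append("EMG")
        if missing:
            raise ValueError(f"unmatched channel roles: {missing}")
        return out


def read_edf(path, channel_map: ChannelMap | None = None) -> dict:
    """Read an EDF/EDF+ file into role-keyed :class:`SignalRecord` objects."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    records = {}
    for label in labels:
        idx = labels.index(label)
        data = raw.get_data(picks=[idx])[0]
        records[label] = SignalRecord(label=label,
                                      sampling_rate=float(raw.info["sfreq"]),
                                      samples=data * 1e6,  # Volt -> uV
                                      physical_unit="uV")
    if channel_map is None:
        return records
    resolved = channel_map.resolve(labels)
    out = {}
    for role, label in resolved.items():
        out[role] = ([records[lab] for lab in label] if isinstance(label, list)
                     else records[label])
    return out


def _pad(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(signals: list[SignalRecord], path,
              record_duration: float = 1.0) -> None:
    """Write plain EDF with 16-bit data records.

    All channels must have integer samples-per-record at the chosen record
    duration.  Physical scaling is per channel from the data range.
    """
    ns = len(signals)
    spr = []
    for sig in signals:
        k = sig.sampling_rate * record_duration
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"{sig.label}: non-integer samples per record")
        spr.append(int(round(k)))
    n_records = min(int(sig.samples.size // k)
                    for sig, k in zip(signals, spr))
    if n_records < 1:
        raise ValueError("signals shorter than one data record")

    header = b""
    header += _pad("0", 8)
    header += _pad("X X X X", 80)
    header += _pad("Startdate X X X X", 80)
    header += _pad("01.01.00", 8) + _pad("00.00.00", 8)
    header += _pad(256 * (1 + ns), 8)
    header += _pad("", 44)
    header += _pad(n_records, 8)
    header += _pad(f"{record_duration:g}", 8)
    header += _pad(ns, 4)

    phys_min, phys_max = [], []
    for sig in signals:
        lo = float(np.min(sig.samples)) if sig.samples.size else -1.0
        hi = float(np.max(sig.samples)) if sig.samples.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)

    for getter, width in (
            (lambda s, i: s.label, 16), (lambda s, i: "", 80),
            (lambda s, i: s.physical_unit or "uV", 8),
            (lambda s, i: f"{phys_min[i]:.6g}"[:8], 8),
            (lambda s, i: f"{phys_max[i]:.6g}"[:8], 8),
            (lambda s, i: "-32768", 8), (lambda s, i: "32767", 8),
            (lambda s, i: "", 80), (lambda s, i: spr[i], 8),
            (lambda s, i: "", 32)):
        for i, sig in enumerate(signals):
            header += _pad(getter(sig, i), width)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for i, sig in enumerate(signals):
                chunk = sig.samples[rec * spr[i]:(rec + 1) * spr[i]]
                # careful: physical min/max strings are truncated to 8 chars,
                # so rescale with the *written* values to stay invertible
                lo = float(f"{phys_min[i]:.6g}"[:8])
                hi = float(f"{phys_max[i]:.6g}"[:8])
                dig = np.round((chunk - lo) / (hi - lo) * 65535.0 - 32768.0)
                fh.write(struct.pack(f"<{spr[i]}h",
                                     *np.clip(dig, -32768, 32767).astype(int)))
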