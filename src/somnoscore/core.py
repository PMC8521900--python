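"""Shared domain types: the stage alphabet, the epoch grid, signals and hypnograms.

Sleep staging operates on 30-second non-overlapping windows ("epochs") of a
polysomnographic (PSG) recording.  Every epoch carries exactly one of five
sleep-wake stages: W (wake), N1, N2, N3 (light to deep non-REM) and R (REM).
All vectors and matrices in this package use the fixed canonical stage order
``W, N1, N2, N3, R``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical stage order, used for every stage-indexed vector or matrix.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

#: Number of sleep-wake stages.
N_STAGES: int = len(STAGES)

#: Stage label -> canonical index.
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Default epoch length in seconds (whole scoring windows from recording start).
EPOCH_LENGTH_S: float = 30.0


def stage_codes(stages) -> np.ndarray:
    """Convert a sequence of stage labels to canonical integer codes (0..4)."""
    try:
        return np.asarray([STAGE_INDEX[s] for s in stages], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover - message formatting
        raise ValueError(f"unknown sleep stage {exc.args[0]!r}") from None


def stage_labels(codes) -> list[str]:
    """Convert canonical integer codes back to stage labels."""
    return [STAGES[int(c)] for c in codes]


@dataclass(frozen=True)
class EpochGrid:
    """Contiguous, non-overlapping grid of scoring epochs.

    Parameters
    ----------
    epoch_length : float
        Epoch duration in seconds (default 30).
    n_epochs : int
        Number of whole epochs in the recording.
    start_offset : float
        Offset of the first epoch from recording start, in seconds.
    """

    epoch_length: float = EPOCH_LENGTH_S
    n_epochs: int = 1
    start_offset: float = 0.0

    def __post_init__(self):
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be at least 1")

    @property
    def duration(self) -> float:
        """Total covered duration in seconds."""
        return self.n_epochs * self.epoch_length


def make_epoch_grid(duration: float, epoch_length: float = EPOCH_LENGTH_S,
                    start_offset: float = 0.0) -> EpochGrid:
    """Build the epoch grid for a recording of ``duration`` seconds.

    A trailing partial epoch is discarded: whole epochs are counted from the
    recording start, matching standard scoring practice.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    if duration < epoch_length:
        raise ValueError("recording too short: shorter than one epoch")
    return EpochGrid(epoch_length=epoch_length,
                     n_epochs=int(math.floor(duration / epoch_length)),
                     start_offset=start_offset)


@dataclass
class SignalRecord:
    """A single recorded channel: label, sampling rate and samples."""

    label: str
    sampling_rate: float
    samples: np.ndarray
    physical_unit: str = ""

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


def partition_epochs(signal: SignalRecord, grid: EpochGrid) -> np.ndarray:
    """Split a channel into per-epoch sample windows.

    Returns an array of shape ``(grid.n_epochs, epoch_length * fs)``.  The
    trailing partial window, if any, is dropped.  Raises if the signal is
    shorter than one epoch or shorter than the grid demands.
    """
    spe = int(round(grid.epoch_length * signal.sampling_rate))
    start = int(round(grid.start_offset * signal.sampling_rate))
    usable = signal.samples.size - start
    if usable < spe:
        raise ValueError("recording too short: shorter than one epoch")
    n_avail = usable // spe
    if n_avail < grid.n_epochs:
        raise ValueError(
            f"recording too short: grid wants {grid.n_epochs} epochs, "
            f"signal holds {n_avail}")
    stop = start + grid.n_epochs * spe
    return signal.samples[start:stop].reshape(grid.n_epochs, spe)


@dataclass
class Hypnogram:
    """A per-epoch stage sequence, optionally with per-stage probabilities.

    When ``probabilities`` (an ``n x 5`` row-stochastic matrix in canonical
    stage order) is present, the argmax of each row — ties broken by canonical
    order, W first — must equal the stored stage.
    """

    stages: list[str]
    probabilities: np.ndarray | None = None
    epoch_length: float = EPOCH_LENGTH_S
    start_offset: float = 0.0

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown sleep stage(s): {sorted(unknown)}")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if p.shape != (len(self.stages), N_STAGES):
                raise ValueError("probabilities must be n_epochs x 5")
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("probability rows must sum to 1")
            if stage_labels(np.argmax(p, axis=1)) != list(self.stages):
                raise ValueError("argmax of probabilities disagrees with stages")
            self.probabilities = p

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def codes(self) -> np.ndarray:
        return stage_codes(self.stages)

    @classmethod
    def from_probabilities(cls, probabilities, **kw) -> "Hypnogram":
        """Build a hypnogram from a row-stochastic matrix via canonical argmax."""
        p = np.asarray(probabilities, dtype=float)
        return cls(stages=stage_labels(np.argmax(p, axis=1)),
                   probabilities=p, **kw)


@dataclass
class RaterPanel:
    """Per-epoch stage labels from a variable-size panel of human scorers.

    ``labels[t]`` is the non-empty list of stage labels given to epoch ``t``;
    panels with a different number of raters per epoch are supported.
    """

    labels: list[list[str]]

    def __post_init__(self):
        for t, lab in enumerate(self.labels):
            if len(lab) == 0:
                raise ValueError(f"epoch {t} has no rater labels")
            unknown = set(lab) - set(STAGES)
            if unknown:
                raise ValueError(
                    f"unknown sleep stage(s) at epoch {t}: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def m(self) -> np.ndarray:
        """Number of raters per epoch."""
        return np.asarray([len(lab) for lab in self.labels], dtype=np.intp)

    def fractions(self) -> np.ndarray:
        """Per-epoch fraction of raters voting each stage (n x 5, rows sum to 1)."""
        out = np.zeros((len(self.labels), N_STAGES))
        for t, lab in enumerate(self.labels):
            for s in lab:
                out[t, STAGE_INDEX[s]] += 1.0
            out[t] /= len(lab)
        return out
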