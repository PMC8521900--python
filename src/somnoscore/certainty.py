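"""Turn raw stage posteriors into actionable prediction certainties.

Three transforms are applied to the per-epoch stage probabilities:

1. **Stage-aware smoothing** — a 3-epoch moving average.  N2/N3/R evolve
   gradually, so their tracks are always smoothed; W and N1 can jump within
   a single epoch (arousals, brief awakenings), so those tracks only accept
   the smoothed value when it reduces the raw value by less than one third.
2. **Exclusion** — any stage at least three times less likely than some other
   stage is set to zero; the residual doubt is not worth reporting.
3. **Renormalisation** — surviving values are rescaled to sum to one (p*).

The number of surviving stages then defines the certainty category per
epoch: one stage -> *certain* (no review needed), two -> *doubt* (both
candidates reported with their p*), three or more -> *uncertain* (manual
scoring required).  The same exclusion + renormalisation (without smoothing)
applies to the fraction of raters voting each stage, giving the expert-side
analogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import N_STAGES, STAGE_INDEX, STAGES, RaterPanel

CATEGORIES = ("certain", "doubt", "uncertain")

#: Stage indices whose probability tracks are smoothed unconditionally.
_ALWAYS_SMOOTH = tuple(STAGE_INDEX[s] for s in ("N2", "N3", "R"))
_GUARDED = tuple(STAGE_INDEX[s] for s in ("W", "N1"))


def smooth(raw_p: np.ndarray, max_reduction: float = 1.0 / 3.0) -> np.ndarray:
    """Stage-aware 3-epoch moving average of the raw posteriors.

    Boundary epochs average the two available values (no padding).  For W
    and N1 the smoothed candidate is kept only if it does not reduce the raw
    value by ``max_reduction`` or more; every stage is smoothed from the same
    raw track, so stage order cannot matter.
    """
    p = np.asarray(raw_p, dtype=float)
    n = p.shape[0]
    cand = np.empty_like(p)
    for t in range(n):
        cand[t] = p[max(0, t - 1):min(n, t + 2)].mean(axis=0)
    out = cand.copy()
    keep_ratio = 1.0 - max_reduction
    for s in _GUARDED:
        raw = p[:, s]
        with np.errstate(invalid="ignore"):
            reject = cand[:, s] < keep_ratio * raw
        out[reject, s] = raw[reject]
    return out


def exclude_low(p_prime: np.ndarray, ratio: float = 3.0) -> np.ndarray:
    """Zero out any stage with a ``ratio``-times-more-likely competitor."""
    p = np.asarray(p_prime, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    row_max = p.max(axis=-1, keepdims=True)
    # relative epsilon so exact boundary cases (3 * 0.2 vs 0.6) are excluded
    return np.where(ratio * p <= row_max * (1.0 + 1e-12), 0.0, p)


def normalize_star(p_dd: np.ndarray) -> np.ndarray:
    """Rescale each row of surviving probabilities to sum to one."""
    p = np.asarray(p_dd, dtype=float)
    sums = p.sum(axis=-1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("degenerate certainty row: all stages excluded")
    return p / sums


def categorize(star_p: np.ndarray) -> tuple[list[str], list[tuple[str, ...]]]:
    """Certainty category and surviving candidate stages per epoch."""
    p = np.atleast_2d(np.asarray(star_p, dtype=float))
    categories, candidates = [], []
    for row in p:
        nz = np.flatnonzero(row > 0)
        categories.append(CATEGORIES[min(len(nz), 3) - 1])
        candidates.append(tuple(STAGES[i] for i in nz))
    return categories, candidates


@dataclass
class CertaintyTrack:
    """All four probability tracks plus the per-epoch category."""

    raw_p: np.ndarray
    smoothed_p: np.ndarray
    excluded_p: np.ndarray
    star_p: np.ndarray
    category: list[str]
    candidate_stages: list[tuple[str, ...]]

    def __len__(self) -> int:
        return self.raw_p.shape[0]

    @classmethod
    def from_raw(cls, raw_p, ratio: float = 3.0,
                 max_reduction: float = 1.0 / 3.0) -> "CertaintyTrack":
        raw_p = np.asarray(raw_p, dtype=float)
        sm = smooth(raw_p, max_reduction=max_reduction)
        ex = exclude_low(sm, ratio=ratio)
        star = normalize_star(ex)
        cat, cand = categorize(star)
        return cls(raw_p=raw_p, smoothed_p=sm, excluded_p=ex, star_p=star,
                   category=cat, candidate_stages=cand)


@dataclass
class ExpertCertainty:
    """Expert-side certainty from a multi-rater panel (no smoothing)."""

    rho: np.ndarray
    star_rho: np.ndarray
    category: list[str]
    candidate_stages: list[tuple[str, ...]]

    @classmethod
    def from_panel(cls, panel: RaterPanel, ratio: float = 3.0) -> "ExpertCertainty":
        rho = panel.fractions()
        star = normalize_star(exclude_low(rho, ratio=ratio))
        cat, cand = categorize(star)
        return cls(rho=rho, star_rho=star, category=cat,
                   candidate_stages=cand)


def rater_fractions(panel_labels) -> ExpertCertainty:
    """Per-epoch rater stage fractions with the expert-side certainty transform."""
    panel = panel_labels if isinstance(panel_labels, RaterPanel) \
        else RaterPanel([list(lab) for lab in panel_labels])
    return ExpertCertainty.from_panel(panel)


@dataclass(frozen=True)
class DoubtGuidance:
    """One review recommendation for a maximal run of doubt epochs."""

    start: int          # first doubt epoch of the run (0-based)
    stop: int           # one past the last doubt epoch
    pattern: str        # "transition" or "excursion"
    inspect_epoch: int  # the epoch the expert should score first
    stages: tuple[str, ...]


def doubt_guidance(track: CertaintyTrack) -> list[DoubtGuidance]:
    """Review recommendations for runs of doubt between certain flanks.

    If the certain stages flanking the run differ (a *transition*), one
    decision fixes the whole run: recommend the crossing epoch, the first
    epoch where the rising stage's p* overtakes the falling one's.  If the
    flanks agree (an *excursion*), recommend the epoch where the minority
    stage's p* peaks — if the expert rejects it there, the whole run keeps
    the flanking stage.
    """
    cats = track.category
    n = len(cats)
    out: list[DoubtGuidance] = []
    t = 0
    while t < n:
        if cats[t] != "doubt":
            t += 1
            continue
        start = t
        while t < n and cats[t] == "doubt":
            t += 1
        stop = t
        left = start - 1 if start > 0 and cats[start - 1] == "certain" else None
        right = stop if stop < n and cats[stop] == "certain" else None
        if left is None or right is None:
            continue  # run touches the recording edge or an uncertain block
        s_left = STAGE_INDEX[track.candidate_stages[left][0]]
        s_right = STAGE_INDEX[track.candidate_stages[right][0]]
        run = track.star_p[start:stop]
        if s_left != s_right:
            rising = run[:, s_right] > run[:, s_left]
            inspect = start + (int(np.argmax(rising)) if rising.any()
                               else stop - 1 - start)
            pattern = "transition"
            stages = (STAGES[s_left], STAGES[s_right])
        else:
            minority = run.copy()
            minority[:, s_left] = -np.inf
            idx = np.unravel_index(np.argmax(minority), minority.shape)
            inspect = start + int(idx[0])
            pattern = "excursion"
            stages = (STAGES[s_left], STAGES[int(idx[1])])
        out.append(DoubtGuidance(start=start, stop=stop, pattern=pattern,
                                 inspect_epoch=inspect, stages=stages))
    return out
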