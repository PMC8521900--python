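"""Agreement statistics between hypnograms, rater panels and predictions.

All matrices are 5x5 percentage tables in canonical stage order with rows =
expert labels and columns = algorithm predictions (except the *pairwise*
matrix, which is expert-vs-expert and folded to its upper triangle since
rater order is arbitrary).  Multi-rater matrices are epoch-weighted: every
epoch contributes total weight 1 regardless of how many raters scored it —
1/C(m,2) per unordered rater pair for the pairwise matrix, 1/m per rater for
the panel-vs-prediction matrix.

Derived statistics: accuracy (trace), inter-rater reliability (trace of the
pairwise matrix), Cohen's kappa from the marginals, and per-stage marginal
bias (how much a stage is over- or under-predicted).  A printed percentage
table can be wrapped directly in :class:`ConfusionMatrix`, so published
matrices are first-class inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import (Hypnogram, N_STAGES, RaterPanel, STAGE_INDEX, STAGES,
                   stage_codes)
from .certainty import CertaintyTrack, ExpertCertainty


@dataclass
class ConfusionMatrix:
    """A 5x5 percentage confusion matrix with its weighting convention."""

    cells: np.ndarray
    weighting: str = "single"  # single | pairwise | multi_vs_pred
    n_epochs: int | None = None
    atol: float = 0.1  # tolerance on the 100% total (printed tables round)

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (N_STAGES, N_STAGES):
            raise ValueError("confusion matrix must be 5x5")
        total = self.cells.sum()
        if not np.isclose(total, 100.0, atol=self.atol + 1e-9):
            raise ValueError(f"cells must sum to 100%, got {total:.3f}")

    @classmethod
    def from_table(cls, cells, weighting: str = "single",
                   atol: float = 0.5) -> "ConfusionMatrix":
        """Wrap a published percentage table (rounded to 1 decimal, so the
        total may be a few tenths off 100)."""
        return cls(np.asarray(cells, dtype=float), weighting=weighting,
                   atol=atol)

    @property
    def row_totals(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(STAGES),
                            columns=list(STAGES))


def confusion_single(expert: Hypnogram, predicted: Hypnogram) -> ConfusionMatrix:
    """Percentage confusion matrix between one expert and the prediction."""
    if len(expert) != len(predicted) or len(expert) == 0:
        raise ValueError("hypnograms must have equal, non-zero length")
    n = len(expert)
    cells = np.zeros((N_STAGES, N_STAGES))
    np.add.at(cells, (expert.codes, predicted.codes), 1.0)
    return ConfusionMatrix(cells / n * 100.0, weighting="single", n_epochs=n)


def confusion_pairwise(panel: RaterPanel) -> ConfusionMatrix:
    """Epoch-weighted pairwise expert-vs-expert matrix, folded to the upper
    triangle (rater order is arbitrary)."""
    n = len(panel)
    cells = np.zeros((N_STAGES, N_STAGES))
    for labels in panel.labels:
        m = len(labels)
        if m < 2:
            raise ValueError("pairwise matrix needs >= 2 raters per epoch")
        w = 1.0 / (m * (m - 1) / 2)
        for a, b in combinations(stage_codes(labels), 2):
            i, j = min(a, b), max(a, b)
            cells[i, j] += w
    return ConfusionMatrix(cells / n * 100.0, weighting="pairwise", n_epochs=n)


def confusion_multi_vs_pred(panel: RaterPanel,
                            predicted: Hypnogram) -> ConfusionMatrix:
    """Panel-vs-prediction matrix; each epoch's weight split over its raters."""
    if len(panel) != len(predicted) or len(panel) == 0:
        raise ValueError("panel and prediction must have equal, non-zero length")
    n = len(panel)
    cells = np.zeros((N_STAGES, N_STAGES))
    for labels, pred in zip(panel.labels, predicted.codes):
        w = 1.0 / len(labels)
        for c in stage_codes(labels):
            cells[c, pred] += w
    return ConfusionMatrix(cells / n * 100.0, weighting="multi_vs_pred",
                           n_epochs=n)


def accuracy(C: ConfusionMatrix) -> float:
    """Percentage agreement: the trace of the matrix."""
    return float(np.trace(C.cells))


def irr(C: ConfusionMatrix) -> float:
    """Inter-rater reliability: trace of the *pairwise* matrix."""
    if C.weighting != "pairwise":
        raise ValueError("IRR is defined on the pairwise expert-vs-expert matrix")
    return float(np.trace(C.cells))


def cohen_kappa(C: ConfusionMatrix) -> float:
    """Chance-corrected agreement from the matrix and its marginals."""
    if C.weighting == "pairwise":
        raise ValueError("kappa is undefined on the folded pairwise matrix")
    p_o = np.trace(C.cells) / 100.0
    p_e = float(C.row_totals @ C.col_totals) / 100.0 ** 2
    if np.isclose(p_e, 1.0):
        raise ValueError("kappa undefined: expected agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def marginal_bias(C: ConfusionMatrix, stage: str) -> float:
    """Predicted minus expert marginal for a stage (positive = over-predicted)."""
    i = STAGE_INDEX[stage]
    return float(C.col_totals[i] - C.row_totals[i])


# ---------------------------------------------------------------------------
# Certainty cross-tabulation
# ---------------------------------------------------------------------------

def category_crosstab(model_track: CertaintyTrack,
                      expert: ExpertCertainty) -> pd.DataFrame:
    """Fractions (and per-cell accuracy where defined) of epochs by
    (expert certainty category x model certainty category).

    Correctness semantics per cell:

    * certain / certain — the model's stage equals the experts' consensus;
    * certain (expert) / doubt (model) — the consensus is one of the model's
      two candidates;
    * doubt (expert) / certain (model) — the model's stage is one of the
      experts' two candidates;
    * doubt / doubt — both doubt between the same two stages;
    * any *uncertain* row or column — fraction reported, accuracy undefined.
    """
    if len(model_track) != len(expert.category):
        raise ValueError("model track and expert panel must be aligned")
    n = len(model_track)
    rows = []
    for e_cat in ("certain", "doubt", "uncertain"):
        for m_cat in ("certain", "doubt", "uncertain"):
            sel = [t for t in range(n)
                   if expert.category[t] == e_cat
                   and model_track.category[t] == m_cat]
            frac = 100.0 * len(sel) / n
            acc = np.nan
            if sel and "uncertain" not in (e_cat, m_cat):
                hits = 0
                for t in sel:
                    mc = set(model_track.candidate_stages[t])
                    ec = set(expert.candidate_stages[t])
                    if e_cat == "certain" and m_cat == "certain":
                        hits += mc == ec
                    elif e_cat == "certain":          # model doubts
                        hits += bool(ec & mc)
                    elif m_cat == "certain":          # expert doubts
                        hits += bool(mc & ec)
                    else:                             # both doubt
                        hits += mc == ec
                acc = 100.0 * hits / len(sel)
            rows.append({"expert_category": e_cat, "model_category": m_cat,
                         "fraction": frac, "accuracy": acc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reliability curve and hypnodensity
# ---------------------------------------------------------------------------

def reliability_curve(p_hat, correct, expert_max, window: int = 1000
                      ) -> dict[str, np.ndarray]:
    """Moving averages of accuracy, expert certainty and model certainty as a
    function of the rank of the model's top posterior.

    Epochs are sorted by ``p_hat`` ascending; each track is a centred moving
    average of length ``window`` over the sorted order (length
    ``n - window + 1``).
    """
    p_hat = np.asarray(p_hat, dtype=float)
    correct = np.asarray(correct, dtype=float)
    expert_max = np.asarray(expert_max, dtype=float)
    n = p_hat.size
    if not (correct.size == expert_max.size == n):
        raise ValueError("inputs must have equal length")
    if window < 1 or window > n:
        raise ValueError("window must be between 1 and the number of epochs")
    order = np.argsort(p_hat, kind="stable")
    kernel = np.full(window, 1.0 / window)
    return {
        "rank": np.arange(n - window + 1),
        "accuracy": np.convolve(correct[order], kernel, mode="valid"),
        "expert_certainty": np.convolve(expert_max[order], kernel, mode="valid"),
        "model_certainty": np.convolve(p_hat[order], kernel, mode="valid"),
    }


#: Stage colours for hypnodensity figures.
STAGE_COLORS = {"W": "gold", "N1": "saddlebrown", "N2": "royalblue",
                "N3": "black", "R": "red"}


def hypnodensity_export(prob_matrix, path_prefix) -> tuple[str, str]:
    """Write a hypnodensity (stacked per-epoch stage probabilities) as a
    figure (PNG) and a TSV of the underlying matrix.

    Returns the two written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.asarray(prob_matrix, dtype=float)
    if p.ndim != 2 or p.shape[1] != N_STAGES:
        raise ValueError("probability matrix must be n x 5")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")

    tsv_path = f"{path_prefix}.tsv"
    pd.DataFrame(p, columns=list(STAGES)).to_csv(tsv_path, sep="\t",
                                                 index_label="epoch")
    fig, ax = plt.subplots(figsize=(10, 2.5))
    x = np.arange(p.shape[0])
    ax.stackplot(x, p.T, colors=[STAGE_COLORS[s] for s in STAGES],
                 labels=list(STAGES), step="post")
    ax.set_xlim(0, p.shape[0] - 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("epoch")
    ax.set_ylabel("probability")
    ax.legend(loc="upper right", ncol=5, fontsize="small")
    fig_path = f"{path_prefix}.png"
    fig.savefig(fig_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return fig_path, tsv_path
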