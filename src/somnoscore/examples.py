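"""Bundled reference tables for documentation, tests and worked examples.

These are published percentage confusion matrices from a large multi-center
evaluation of automated sleep staging against expert scorers: a single-expert
comparison on ~2.5 million epochs, a pairwise expert-vs-expert comparison on
a 50-recording multi-scored set, and the panel-vs-algorithm comparison on the
same set.  They let the derived statistics (accuracy, Cohen's kappa,
inter-rater reliability, marginal biases) be recomputed without access to any
recordings — a printed table is a first-class input to the evaluation module.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix

#: Single-expert vs algorithm, percent of epochs (rows: expert; cols: algorithm).
SINGLE_SCORED_TABLE = np.array([
    #   W    N1    N2    N3     R
    [19.5,  1.0,  1.0,  0.0,  0.4],   # W
    [ 2.0,  2.8,  3.0,  0.0,  0.9],   # N1
    [ 0.9,  1.1, 33.8,  2.0,  1.3],   # N2
    [ 0.1,  0.0,  3.5, 12.3,  0.0],   # N3
    [ 0.4,  0.3,  1.5,  0.0, 12.1],   # R
])

#: Pairwise expert-vs-expert matrix (upper triangle; rater order folded).
PAIRWISE_EXPERT_TABLE = np.array([
    [15.2,  2.4,  1.0,  0.0,  0.3],
    [ 0.0,  4.0,  4.5,  0.0,  1.4],
    [ 0.0,  0.0, 38.1,  4.7,  1.4],
    [ 0.0,  0.0,  0.0, 12.7,  0.0],
    [ 0.0,  0.0,  0.0,  0.0, 14.1],
])

#: Multi-rater panel vs algorithm, epoch-weighted (1/m per rater).
MULTI_SCORED_TABLE = np.array([
    [14.7,  1.0,  1.0,  0.0,  0.5],
    [ 1.4,  2.5,  3.5,  0.0,  0.8],
    [ 0.6,  0.7, 39.4,  2.3,  0.9],
    [ 0.0,  0.0,  2.8, 12.2,  0.0],
    [ 0.2,  0.2,  1.3,  0.0, 13.9],
])


def single_scored_confusion() -> ConfusionMatrix:
    return ConfusionMatrix.from_table(SINGLE_SCORED_TABLE, weighting="single")


def pairwise_expert_confusion() -> ConfusionMatrix:
    return ConfusionMatrix.from_table(PAIRWISE_EXPERT_TABLE,
                                      weighting="pairwise")


def multi_scored_confusion() -> ConfusionMatrix:
    return ConfusionMatrix.from_table(MULTI_SCORED_TABLE,
                                      weighting="multi_vs_pred")
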