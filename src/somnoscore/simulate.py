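"""Synthetic PSG generator: stage sequences, features, signals and raters.

Everything the pipeline consumes can be simulated so the whole tool is
testable without clinical data:

* a first-order Markov stage sequence with sleep-architecture-like
  persistence (deep sleep and REM are sticky; wake intrudes briefly),
  stationary stage mix loosely matching the W~22 / N1~9 / N2~39 / N3~16 /
  R~14 % distribution typical of clinical sleep-lab populations;
* per-epoch features drawn from the same stage-conditional families the
  emission layer fits (so maximum-likelihood recovery of the generator
  parameters is a meaningful closed loop), with per-recording event
  densities drawn from log-normal hyper-distributions to mimic
  between-patient variation;
* raw 30-s signal snippets with injected spindles (13 Hz, 4 uV, 1 s),
  sharp conjugate EOG deflections (REM-like, < 0.5 s) and slow ones
  (SEM-like, > 0.5 s), with the injected counts recorded as ground truth;
* simulated rater panels obtained by pushing the true stages through a
  row-stochastic rater-confusion matrix.

Feature-level simulation is the default test path; signal-level simulation
is slower and exists to exercise the detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import N_STAGES, RaterPanel, STAGES, SignalRecord, stage_labels
from .emissions import rem_joint_pmf, sem_joint_pmf, spindle_negbin_params

# ---------------------------------------------------------------------------
# Defaults: the study conditions the synthetic runs emulate
# ---------------------------------------------------------------------------

DEFAULT_TRANSITIONS = np.array([
    #  W     N1    N2    N3    R
    [0.88, 0.08, 0.02, 0.00, 0.02],   # W
    [0.14, 0.58, 0.24, 0.00, 0.04],   # N1
    [0.02, 0.03, 0.88, 0.05, 0.02],   # N2
    [0.01, 0.00, 0.10, 0.88, 0.01],   # N3
    [0.02, 0.03, 0.05, 0.00, 0.90],   # R
])

DEFAULT_INITIAL = np.array([0.85, 0.10, 0.03, 0.01, 0.01])

DEFAULT_RATER_CONFUSION = np.array([
    [0.92, 0.06, 0.01, 0.00, 0.01],
    [0.07, 0.80, 0.10, 0.00, 0.03],
    [0.01, 0.04, 0.89, 0.04, 0.02],
    [0.00, 0.00, 0.09, 0.91, 0.00],
    [0.01, 0.03, 0.04, 0.00, 0.92],
])

#: Stage-conditional feature parameters (canonical stage order W,N1,N2,N3,R).
DEFAULT_FEATURE_PARAMS: dict = {
    # ORP likeliness: mean when the score's stage matches / doesn't match the
    # true stage, and the common spread (clipped to [0, 1]).
    "orp": {"mu_match": 0.65, "mu_other": 0.35, "sd": 0.18},
    # spindle negative binomial (a, b, c, d): mean a*rho^b, var + c*rho^d
    "spindles": [(0.05, 1.0, 0.05, 2.0), (0.30, 1.0, 0.10, 2.0),
                 (2.00, 1.0, 1.00, 2.0), (0.80, 1.0, 0.50, 2.0),
                 (0.10, 1.0, 0.05, 2.0)],
    # REM joint: per stage, (a_x, b_x) vectors over x = 0..3; the x = 0
    # category is the identification reference (a_0 = 1, b_0 = 0)
    "rems": [([1.0, 0.8, 0.4, 0.2], [0.0, 0.4, 0.5, 0.6]),
             ([1.0, 0.10, 0.02, 0.005], [0.0, 0.3, 0.3, 0.3]),
             ([1.0, 0.05, 0.008, 0.002], [0.0, 0.2, 0.2, 0.2]),
             ([1.0, 0.025, 0.004, 0.001], [0.0, 0.2, 0.2, 0.2]),
             ([1.0, 2.5, 4.0, 5.0], [0.0, 0.5, 0.8, 1.0])],
    # SEM joint: (a1, b1) of the logistic in rho (x = 0 pinned at 0)
    "sems": [(-1.5, 1.0), (-0.5, 2.0), (-3.0, 0.5), (-4.0, 0.5), (-3.0, 0.5)],
    # EMG power law (a_s, b_s): W has the heaviest mass above the median
    "emg": [(2.0, 0.3), (1.5, 0.0), (1.2, -0.5), (1.0, -1.0), (0.5, -3.0)],
    # heart rate (quantile mean, change sd); quantile sd shared
    "hr": {"q_mean": [0.70, 0.55, 0.45, 0.30, 0.60], "q_sd": 0.15,
           "change_sd": 2.0},
    # SaO2 (mean level, gamma-distributed variance with stage-typical scale)
    "sao2": {"mean": [96.5, 96.0, 95.5, 95.0, 94.0], "mean_sd": 1.0,
             "var_scale": [0.2, 0.3, 0.4, 0.8, 1.5]},
    "position_change": [0.15, 0.05, 0.01, 0.01, 0.01],
    "snores": [1.0, 0.6, 0.5, 0.4, 0.3],   # Poisson means
    # per-recording density hyper-distributions: (log-mean, log-sd)
    "rho_spindle": (np.log(1.2), 0.4),
    "rho_rem": (np.log(0.8), 0.5),
    "rho_sem": (np.log(0.3), 0.5),
}


@dataclass
class GeneratorConfig:
    """Everything the simulator needs, with reproducibility via explicit seeds."""

    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    initial_dist: np.ndarray = field(
        default_factory=lambda: DEFAULT_INITIAL.copy())
    feature_params: dict = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_FEATURE_PARAMS.items()})
    rater_confusion: np.ndarray = field(
        default_factory=lambda: DEFAULT_RATER_CONFUSION.copy())
    n_epochs: int = 960
    n_psgs: int = 20
    n_raters: int = 5
    seed: int = 0

    def __post_init__(self):
        for name, mat in (("transition_matrix", self.transition_matrix),
                          ("rater_confusion", self.rater_confusion)):
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (N_STAGES, N_STAGES) or np.any(mat < 0) \
                    or not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} must be 5x5 row-stochastic")
        if not np.allclose(np.sum(self.initial_dist), 1.0, atol=1e-9):
            raise ValueError("initial_dist must sum to 1")


# ---------------------------------------------------------------------------
# Stage sequences
# ---------------------------------------------------------------------------

def simulate_stage_sequence(config: GeneratorConfig, seed: int) -> list[str]:
    """Draw one Markov stage sequence of ``config.n_epochs`` epochs."""
    rng = np.random.default_rng(seed)
    P = np.asarray(config.transition_matrix, dtype=float)
    codes = np.empty(config.n_epochs, dtype=np.intp)
    codes[0] = rng.choice(N_STAGES, p=np.asarray(config.initial_dist))
    for t in range(1, config.n_epochs):
        codes[t] = rng.choice(N_STAGES, p=P[codes[t - 1]])
    return stage_labels(codes)


# ---------------------------------------------------------------------------
# Feature-level simulation
# ---------------------------------------------------------------------------

def _draw_rem_counts(rng, codes, rho, params) -> np.ndarray:
    out = np.empty(codes.size, dtype=np.intp)
    for s in range(N_STAGES):
        sel = codes == s
        if not sel.any():
            continue
        a, b = params[s]
        pmf = np.array([rem_joint_pmf(x, rho, np.asarray(a), np.asarray(b))
                        for x in range(4)])
        out[sel] = rng.choice(4, size=int(sel.sum()), p=pmf)
    return out


def simulate_features(stages, config: GeneratorConfig, seed: int
                      ) -> pd.DataFrame:
    """Draw one recording's per-epoch feature table.

    Per-recording event densities (spindles, REMs, SEMs) are drawn first
    from log-normal hyper-distributions and shared by all the recording's
    epochs — both as the conditioning value of the joint count families and
    as the density columns of the output table.
    """
    rng = np.random.default_rng(seed)
    fp = config.feature_params
    codes = np.asarray([STAGES.index(s) for s in stages], dtype=np.intp)
    n = codes.size
    df = pd.DataFrame(index=np.arange(n))

    rho_sp = float(rng.lognormal(*fp["rho_spindle"]))
    rho_rem = float(rng.lognormal(*fp["rho_rem"]))
    rho_sem = float(rng.lognormal(*fp["rho_sem"]))

    orp = fp["orp"]
    for k, s in enumerate(STAGES):
        mu = np.where(codes == k, orp["mu_match"], orp["mu_other"])
        df[f"orp_{s}"] = np.clip(rng.normal(mu, orp["sd"]), 0.0, 1.0)

    spin = np.empty(n, dtype=np.intp)
    for s in range(N_STAGES):
        sel = codes == s
        if not sel.any():
            continue
        a, b, c, d = fp["spindles"][s]
        mu, extra = spindle_negbin_params(rho_sp, a, b, c, d)
        if extra < 1e-9:
            spin[sel] = rng.poisson(mu, size=int(sel.sum()))
        else:
            r = mu ** 2 / extra
            spin[sel] = rng.negative_binomial(r, r / (r + mu),
                                              size=int(sel.sum()))
    df["n_spindles"] = spin

    df["n_rems"] = _draw_rem_counts(rng, codes, rho_rem, fp["rems"])
    p1 = np.array([sem_joint_pmf(1, rho_sem, *fp["sems"][s])
                   for s in range(N_STAGES)])
    df["n_sems"] = (rng.random(n) < p1[codes]).astype(int)

    # EMG: inverse-CDF draw from the two-branch power law
    a = np.array([fp["emg"][s][0] for s in range(N_STAGES)])[codes]
    b = np.array([fp["emg"][s][1] for s in range(N_STAGES)])[codes]
    c = 1.0 / (a + 1.0) + 1.0 / (1.0 - b)
    w_below = 1.0 / (a + 1.0) / c
    u = rng.random(n)
    below = rng.random(n) < w_below
    emg = np.where(below, u ** (1.0 / (a + 1.0)), u ** (1.0 / (b - 1.0)))
    df["emg_background"] = emg

    hr = fp["hr"]
    df["hr_quantile"] = np.clip(
        rng.normal(np.asarray(hr["q_mean"])[codes], hr["q_sd"]), 0.0, 1.0)
    df["hr_change"] = rng.normal(0.0, hr["change_sd"], size=n)

    sa = fp["sao2"]
    df["sao2_mean"] = np.clip(
        rng.normal(np.asarray(sa["mean"])[codes], sa["mean_sd"]), 80.0, 100.0)
    df["sao2_var"] = rng.gamma(2.0, np.asarray(sa["var_scale"])[codes] / 2.0)

    df["position_change"] = (
        rng.random(n) < np.asarray(fp["position_change"])[codes]).astype(int)
    df["n_snores"] = rng.poisson(np.asarray(fp["snores"])[codes])

    df["spindle_density"] = rho_sp
    df["rem_density"] = rho_rem
    df["sem_density"] = rho_sem
    return df


def simulate_dataset(config: GeneratorConfig, seed: int | None = None
                     ) -> tuple[list[pd.DataFrame], list[list[str]]]:
    """Simulate ``config.n_psgs`` recordings at the feature level."""
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base).generate_state(2 * config.n_psgs)
    features, stages = [], []
    for i in range(config.n_psgs):
        st = simulate_stage_sequence(config, int(ss[2 * i]) % (2**31))
        features.append(simulate_features(st, config, int(ss[2 * i + 1]) % (2**31)))
        stages.append(st)
    return features, stages


# ---------------------------------------------------------------------------
# Signal-level simulation
# ---------------------------------------------------------------------------

_STAGE_EEG_BAND = {  # dominant background band (Hz) and RMS amplitude (uV)
    "W": ((8.0, 13.0), 15.0), "N1": ((4.0, 7.0), 20.0),
    "N2": ((2.0, 7.0), 25.0), "N3": ((0.5, 2.0), 60.0), "R": ((4.0, 8.0), 20.0)}

_STAGE_EMG_AMPLITUDE = {"W": 10.0, "N1": 4.0, "N2": 3.0, "N3": 2.0, "R": 1.0}


def _bandlimited_noise(rng, n, fs, band, rms):
    x = rng.standard_normal(n + 2 * int(fs))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)[int(fs):-int(fs)]
    return x * (rms / (np.std(x) + 1e-12))


def simulate_signals(stages, config: GeneratorConfig, seed: int,
                     fs: float = 100.0, epoch_length: float = 30.0,
                     eeg_background: str = "noise",
                     spindle_rate: float = 1.5,
                     eye_movement_rate: float = 1.0) -> dict:
    """Raw EEG/EOG/EMG snippets with injected, ground-truthed events.

    N2 epochs receive a Poisson number of 1-s, 13-Hz, 4-uV spindle bursts;
    W and R epochs receive sharp (< 0.5 s) conjugate EOG deflections, N1
    epochs slow (> 0.5 s) ones.  ``eeg_background="sine"`` replaces the
    stage-typical noise background with a clean 2-Hz, 80-uV sine (the
    detector-validation setting); ``"none"`` removes it entirely.

    Returns ``{"signals": {role: SignalRecord}, "truth": DataFrame}``.
    """
    rng = np.random.default_rng(seed)
    spe = int(round(epoch_length * fs))
    n = len(stages)
    eeg = np.zeros(n * spe)
    eog_l = np.zeros(n * spe)
    eog_r = np.zeros(n * spe)
    emg = np.zeros(n * spe)
    truth = pd.DataFrame(0, index=np.arange(n),
                         columns=["n_spindles", "n_rems", "n_sems"])
    t_axis = np.arange(spe) / fs

    for i, s in enumerate(stages):
        lo = i * spe
        if eeg_background == "noise":
            band, rms = _STAGE_EEG_BAND[s]
            eeg[lo:lo + spe] = _bandlimited_noise(rng, spe, fs, band, rms)
        elif eeg_background == "sine":
            eeg[lo:lo + spe] = 80.0 * np.sin(2 * np.pi * 2.0 * t_axis)
        emg[lo:lo + spe] = rng.standard_normal(spe) * _STAGE_EMG_AMPLITUDE[s]

        if s == "N2":
            k = rng.poisson(spindle_rate)
            starts = np.sort(rng.choice(np.arange(0, spe - 2 * int(fs),
                                                  2 * int(fs)),
                                        size=min(k, 10), replace=False)) \
                if k else []
            for st in starts:
                tt = np.arange(int(fs)) / fs          # 1-s burst
                env = sps.windows.tukey(int(fs), alpha=0.2)
                burst = 4.0 * np.sin(2 * np.pi * 13.0 * tt) * env
                eeg[lo + st:lo + st + int(fs)] += burst
                truth.loc[i, "n_spindles"] += 1

        if s in ("W", "R", "N1"):
            k = rng.poisson(eye_movement_rate)
            for _ in range(min(k, 5)):
                if s == "N1":   # slow sinusoidal half-wave, 1.2 s
                    dur = int(1.2 * fs)
                    shape = 60.0 * np.sin(np.pi * np.arange(dur) / dur)
                    kind = "n_sems"
                else:           # sharp sawtooth, 0.2 s with fast rise
                    dur = int(0.2 * fs)
                    rise = max(2, int(0.02 * fs))
                    shape = np.concatenate([
                        np.linspace(0, 60.0, rise),
                        np.linspace(60.0, 0, dur - rise)])
                    kind = "n_rems"
                st = int(rng.integers(0, spe - dur))
                sign = rng.choice([-1.0, 1.0])
                eog_l[lo + st:lo + st + dur] += sign * shape
                eog_r[lo + st:lo + st + dur] -= sign * shape
                truth.loc[i, kind] += 1

    signals = {
        "EEG": SignalRecord("EEG", fs, eeg, "uV"),
        "EOG_L": SignalRecord("EOG-L", fs, eog_l, "uV"),
        "EOG_R": SignalRecord("EOG-R", fs, eog_r, "uV"),
        "EMG": [SignalRecord("EMG-chin", fs, emg, "uV")],
    }
    return {"signals": signals, "truth": truth}


# ---------------------------------------------------------------------------
# Rater panels
# ---------------------------------------------------------------------------

def simulate_raters(true_stages, rater_confusion, n_raters: int,
                    seed: int) -> RaterPanel:
    """Draw each rater's label from the confusion row of the true stage."""
    Q = np.asarray(rater_confusion, dtype=float)
    if Q.shape != (N_STAGES, N_STAGES) or not np.allclose(
            Q.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rater confusion must be 5x5 row-stochastic")
    rng = np.random.default_rng(seed)
    codes = np.asarray([STAGES.index(s) for s in true_stages])
    cum = np.cumsum(Q, axis=1)
    labels = []
    for c in codes:
        draws = np.searchsorted(cum[c], rng.random(n_raters), side="right")
        labels.append([STAGES[int(d)] for d in np.minimum(draws, N_STAGES - 1)])
    return RaterPanel(labels)
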