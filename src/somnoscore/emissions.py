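"""Stage-conditional emission models.

The second stage of the pipeline replaces each raw feature (or small feature
group) ``x`` by its *emissions*: the five conditional densities ``p(x|s)``
for the stages s in (W, N1, N2, N3, R), normalised so they sum to one over
stages.  The normalised value ``e_s(x) = p(x|s) / sum_t p(x|t)`` is the
posterior stage probability under a uniform prior; it filters out how rare
``x`` is overall and keeps only how discriminative it is.

Families
--------
* counts with no strong patient dependence (snores, position change):
  smoothed normalised histograms;
* REM counts: joint with the recording's REM density rho through
  ``p(x|rho) ∝ a_x / (a_x + rho^(-b_x))`` (x truncated at 3);
* SEM counts: joint log-linear ``p(x|rho) ∝ exp(a_x + b_x rho)``, x in {0,1};
* spindle counts: negative binomial with mean ``a rho^b`` and variance
  ``a rho^b + c rho^d``;
* background EMG: a two-branch power law peaking at the median value 1,
  ``p(x) = x^a / c`` below 1 and ``x^(b-2) / c`` above, with
  ``c = 1/(a+1) + 1/(1-b)``;
* continuous 1-D / 2-D features (ORP scores; heart rate and SaO2 pairs):
  Gaussian kernel density estimates.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .core import N_STAGES, STAGES, stage_codes

logger = logging.getLogger(__name__)

_DENSITY_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Closed-form family densities (module-level so fitting and simulation share
# one definition)
# ---------------------------------------------------------------------------

def emg_powerlaw_logpdf(x, a: float, b: float) -> np.ndarray:
    """Log-density of the two-branch EMG power law.

    Requires ``a > -1`` and ``b < 1`` for normalisability.  The density peaks
    at ``x = 1`` (the recording median after median-centring) whenever
    ``a > 0`` and decays to zero by a power law on both sides.
    """
    if not (a > -1.0 and b < 1.0):
        raise ValueError("power law requires a > -1 and b < 1")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("EMG ratio must be positive")
    c = 1.0 / (a + 1.0) + 1.0 / (1.0 - b)
    return np.where(x < 1.0, a * np.log(x), (b - 2.0) * np.log(x)) - np.log(c)


def emg_powerlaw_pdf(x, a: float, b: float) -> np.ndarray:
    return np.exp(emg_powerlaw_logpdf(x, a, b))


def _rem_unnorm(x, rho, a, b) -> np.ndarray:
    """Unnormalised REM-joint weight for count ``x`` at density ``rho``.

    One chosen reading of an ambiguous printed form, isolated here so it can
    be swapped wholesale: ``a_x / (a_x + rho^(-b_x)) = sigmoid(b_x ln rho +
    ln a_x)``, an increasing-in-rho occupancy curve per count value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rho = np.asarray(rho, dtype=float)
    with np.errstate(over="ignore"):
        return a / (a + rho ** (-b))


def rem_joint_pmf(x, rho, a, b) -> np.ndarray:
    """p(x | rho) for REM counts, normalised over x in {0..3} at the given rho.

    Inputs above 3 are truncated to 3 first (the count is clipped for
    stability; very high counts carry no extra stage information).
    ``a`` and ``b`` are length-4 parameter vectors indexed by the count.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    x = np.minimum(np.asarray(x, dtype=np.intp), a.size - 1)
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    table = _rem_unnorm(np.arange(a.size)[None, :], rho[:, None],
                        a[None, :], b[None, :])
    table /= table.sum(axis=1, keepdims=True)
    out = table[np.arange(rho.size), np.atleast_1d(x)]
    return out if out.size > 1 else float(out[0])


def sem_joint_pmf(x, rho, a1: float, b1: float) -> np.ndarray:
    """p(x | rho) for SEM counts x in {0,1}: logistic in rho.

    The log-linear form ``p(x|rho) ∝ exp(a_x + b_x rho)`` is only identified
    through the differences ``a_1 - a_0`` and ``b_1 - b_0`` once normalised
    over x, so the x = 0 category is pinned at a_0 = b_0 = 0.
    """
    rho = np.asarray(rho, dtype=float)
    x = np.minimum(np.asarray(x, dtype=np.intp), 1)
    p1 = 1.0 / (1.0 + np.exp(-(a1 + b1 * rho)))
    return np.where(x == 1, p1, 1.0 - p1)


def spindle_negbin_params(rho, a: float, b: float, c: float, d: float):
    """Map (rho, a, b, c, d) to the (n, p) of scipy's negative binomial.

    Mean ``mu = a rho^b``; variance ``mu + c rho^d``.  ``c = 0`` is the
    Poisson limit.  Negative ``c`` (variance below mean) is rejected.
    """
    if c < 0:
        raise ValueError("variance below mean: c must be >= 0")
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("spindle density rho must be positive")
    mu = a * rho ** b
    extra = c * rho ** d
    return mu, extra


def spindle_negbin_logpmf(x, rho, a, b, c, d) -> np.ndarray:
    mu, extra = spindle_negbin_params(rho, a, b, c, d)
    x = np.asarray(x, dtype=float)
    if c == 0 or np.all(extra < 1e-12):
        return stats.poisson.logpmf(x, mu)
    r = mu ** 2 / np.maximum(extra, 1e-12)
    return stats.nbinom.logpmf(x, r, r / (r + mu))


def spindle_negbin_pmf(x, rho, a, b, c, d) -> np.ndarray:
    return np.exp(spindle_negbin_logpmf(x, rho, a, b, c, d))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitters
# ---------------------------------------------------------------------------

def _multistart_minimize(nll, starts, bounds) -> np.ndarray:
    best, best_val = None, np.inf
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-12, "gtol": 1e-10})
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    return best


def fit_emg_powerlaw(x) -> tuple[float, float]:
    """MLE of the two-branch power law on positive samples."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size == 0:
        raise ValueError("no positive EMG samples")
    lx = np.log(x)
    s_lo, s_hi = lx[lx < 0].sum(), lx[lx >= 0].sum()
    n = x.size

    def nll(p):
        a, b = p
        c = 1.0 / (a + 1.0) + 1.0 / (1.0 - b)
        return -(a * s_lo + (b - 2.0) * s_hi - n * np.log(c))

    a, b = _multistart_minimize(
        nll, starts=[(0.5, 0.0), (2.0, -1.0), (0.1, 0.5)],
        bounds=[(-1.0 + 1e-6, 60.0), (-60.0, 1.0 - 1e-6)])
    return float(a), float(b)


def fit_rem_joint(x, rho, n_starts: int = 5, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """MLE of the REM-joint parameters (a_x, b_x for x = 0..3).

    Once the density is normalised over x conditional on rho, the family has
    a near-flat direction (in the low-occupancy regime the sigmoids reduce to
    a softmax, invariant under shared rescaling of a and shifts of b), so the
    x = 0 category is pinned at a_0 = 1, b_0 = 0 and the remaining six
    parameters are estimated.  Returned vectors include the pinned values.
    """
    x = np.minimum(np.asarray(x, dtype=np.intp), 3)
    rho = np.asarray(rho, dtype=float)
    rng = np.random.default_rng(seed)

    def nll(p):
        a = np.concatenate([[1.0], np.exp(p[:3])])
        b = np.concatenate([[0.0], p[3:]])
        pmf = rem_joint_pmf(x, rho, a, b)
        return -np.sum(np.log(np.maximum(pmf, _DENSITY_FLOOR)))

    starts = [np.zeros(6)]
    starts += [np.concatenate([rng.normal(0, 1, 3), rng.normal(0, 1, 3)])
               for _ in range(n_starts - 1)]
    p = _multistart_minimize(nll, starts,
                             bounds=[(-8, 8)] * 3 + [(-10, 10)] * 3)
    return (np.concatenate([[1.0], np.exp(p[:3])]),
            np.concatenate([[0.0], p[3:]]))


def fit_sem_joint(x, rho) -> tuple[float, float]:
    """MLE of the SEM-joint (a_1, b_1): a plain logistic regression on rho."""
    x = np.minimum(np.asarray(x, dtype=np.intp), 1)
    rho = np.asarray(rho, dtype=float)
    if len(np.unique(x)) < 2:
        # degenerate: all-0 or all-1 counts; saturate the intercept
        return (20.0 if x[0] == 1 else -20.0), 0.0

    def nll(p):
        pmf = sem_joint_pmf(x, rho, *p)
        return -np.sum(np.log(np.maximum(pmf, _DENSITY_FLOOR)))

    a1, b1 = _multistart_minimize(nll, starts=[(0.0, 0.0), (1.0, -1.0)],
                                  bounds=[(-30, 30), (-60, 60)])
    return float(a1), float(b1)


def fit_spindle_negbin(x, rho, n_starts: int = 5, seed: int = 0
                       ) -> tuple[float, float, float, float]:
    """MLE of (a, b, c, d) for the spindle negative binomial."""
    x = np.asarray(x, dtype=float)
    rho = np.asarray(rho, dtype=float)
    rng = np.random.default_rng(seed)

    def nll(p):
        a, b, c, d = np.exp(p[0]), p[1], np.exp(p[2]), p[3]
        with np.errstate(all="ignore"):
            ll = spindle_negbin_logpmf(x, rho, a, b, c, d)
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -ll.sum()

    starts = [np.array([np.log(max(x.mean(), 0.1)), 1.0, 0.0, 1.0])]
    starts += [starts[0] + rng.normal(0, 0.5, 4) for _ in range(n_starts - 1)]
    p = _multistart_minimize(nll, starts,
                             bounds=[(-6, 6), (-5, 5), (-10, 6), (-5, 5)])
    return float(np.exp(p[0])), float(p[1]), float(np.exp(p[2])), float(p[3])


# ---------------------------------------------------------------------------
# Emission-family estimators
# ---------------------------------------------------------------------------

class EmissionGroup(BaseEstimator):
    """Base class: one emission group mapping features -> 5 stage densities.

    Subclasses implement ``_fit_stage`` and ``_density``.  Rows whose inputs
    are missing (NaN) yield uniform densities and are flagged via
    ``missing_mask`` on :meth:`stage_densities`.
    """

    #: feature columns this group consumes
    columns: tuple[str, ...] = ()

    def _values(self, df: pd.DataFrame) -> np.ndarray:
        return df.loc[:, list(self.columns)].to_numpy(dtype=float)

    def fit(self, df: pd.DataFrame, stages) -> "EmissionGroup":
        y = stage_codes(stages) if not np.issubdtype(
            np.asarray(stages).dtype, np.integer) else np.asarray(stages)
        vals = self._values(df)
        ok = np.all(np.isfinite(vals), axis=1)
        self.params_ = []
        for s in range(N_STAGES):
            sel = ok & (y == s)
            if not sel.any():
                raise ValueError(f"no training samples for stage {STAGES[s]}")
            self.params_.append(self._fit_stage(vals[sel]))
        return self

    def stage_densities(self, df: pd.DataFrame) -> np.ndarray:
        """(n, 5) conditional densities; uniform rows where inputs are missing."""
        vals = self._values(df)
        ok = np.all(np.isfinite(vals), axis=1)
        out = np.full((len(vals), N_STAGES), 0.2)
        if ok.any():
            for s in range(N_STAGES):
                out[ok, s] = np.maximum(self._density(vals[ok], self.params_[s]),
                                        0.0)
        if (~ok).any():
            logger.debug("%s: %d epochs with missing inputs -> uniform",
                         type(self).__name__, int((~ok).sum()))
        return out


class HistogramEmission(EmissionGroup):
    """Add-one-smoothed normalised histogram on {0..support_max}.

    Values above ``support_max`` clamp into the top bin.
    """

    def __init__(self, column: str, support_max: int, smoothing: float = 1.0):
        self.column = column
        self.support_max = support_max
        self.smoothing = smoothing
        self.columns = (column,)

    def _fit_stage(self, vals):
        x = np.minimum(vals[:, 0].astype(np.intp), self.support_max)
        counts = np.bincount(x, minlength=self.support_max + 1).astype(float)
        counts += self.smoothing
        return counts / counts.sum()

    def _density(self, vals, pmf):
        x = np.minimum(vals[:, 0].astype(np.intp), self.support_max)
        return pmf[x]


class KDE1DEmission(EmissionGroup):
    """Per-stage 1-D Gaussian KDE (Scott's-rule bandwidth)."""

    def __init__(self, column: str, min_samples: int = 5):
        self.column = column
        self.min_samples = min_samples
        self.columns = (column,)

    def _fit_stage(self, vals):
        x = vals[:, 0]
        if x.size < self.min_samples:
            raise ValueError("insufficient samples for KDE")
        if np.ptp(x) == 0:  # degenerate cloud: nudge so the KDE is defined
            x = x + np.linspace(-1e-9, 1e-9, x.size)
        return stats.gaussian_kde(x)

    def _density(self, vals, kde):
        return np.maximum(kde(vals[:, 0]), _DENSITY_FLOOR)


class KDE2DEmission(EmissionGroup):
    """Per-stage 2-D Gaussian KDE over a feature pair."""

    def __init__(self, columns: tuple[str, str], min_samples: int = 30):
        self.columns = tuple(columns)
        self.min_samples = min_samples

    def _fit_stage(self, vals):
        if len(vals) < self.min_samples:
            raise ValueError(
                f"insufficient samples for 2-D KDE (need {self.min_samples})")
        data = vals.T.copy()
        for row in data:  # guard singular covariance
            if np.ptp(row) == 0:
                row += np.linspace(-1e-9, 1e-9, row.size)
        return stats.gaussian_kde(data)

    def _density(self, vals, kde):
        return np.maximum(kde(vals.T), _DENSITY_FLOOR)


class PowerLawEmission(EmissionGroup):
    """Background-EMG two-branch power law, one (a_s, b_s) per stage."""

    def __init__(self, column: str = "emg_background"):
        self.column = column
        self.columns = (column,)

    def _fit_stage(self, vals):
        return fit_emg_powerlaw(vals[:, 0])

    def _density(self, vals, params):
        return emg_powerlaw_pdf(np.maximum(vals[:, 0], 1e-12), *params)


class RemJointEmission(EmissionGroup):
    """REM count x REM density joint family."""

    def __init__(self, count_col: str = "n_rems",
                 rho_col: str = "rem_density", seed: int = 0):
        self.count_col = count_col
        self.rho_col = rho_col
        self.seed = seed
        self.columns = (count_col, rho_col)

    def _fit_stage(self, vals):
        return fit_rem_joint(vals[:, 0], np.maximum(vals[:, 1], 1e-9),
                             seed=self.seed)

    def _density(self, vals, params):
        a, b = params
        return np.atleast_1d(rem_joint_pmf(vals[:, 0],
                                           np.maximum(vals[:, 1], 1e-9), a, b))


class SemJointEmission(EmissionGroup):
    """SEM count x SEM density joint family (logistic in rho)."""

    def __init__(self, count_col: str = "n_sems",
                 rho_col: str = "sem_density"):
        self.count_col = count_col
        self.rho_col = rho_col
        self.columns = (count_col, rho_col)

    def _fit_stage(self, vals):
        return fit_sem_joint(vals[:, 0], vals[:, 1])

    def _density(self, vals, params):
        return sem_joint_pmf(vals[:, 0], vals[:, 1], *params)


class NegBinJointEmission(EmissionGroup):
    """Spindle count x spindle density negative-binomial family."""

    def __init__(self, count_col: str = "n_spindles",
                 rho_col: str = "spindle_density", seed: int = 0):
        self.count_col = count_col
        self.rho_col = rho_col
        self.seed = seed
        self.columns = (count_col, rho_col)

    def _fit_stage(self, vals):
        return fit_spindle_negbin(vals[:, 0], np.maximum(vals[:, 1], 1e-9),
                                  seed=self.seed)

    def _density(self, vals, params):
        return spindle_negbin_pmf(vals[:, 0], np.maximum(vals[:, 1], 1e-9),
                                  *params)


# ---------------------------------------------------------------------------
# Normalisation and the emission vector
# ---------------------------------------------------------------------------

def normalize_emissions(p_by_stage) -> np.ndarray:
    """Normalise stage-conditional densities to emissions summing to 1.

    Accepts a length-5 vector or an (n, 5) matrix.  All-zero rows fall back
    to the uniform distribution (0.2 each) with a warning — the observation
    carries no stage information.
    """
    p = np.atleast_2d(np.asarray(p_by_stage, dtype=float))
    if np.any(p < 0):
        raise ValueError("densities must be non-negative")
    sums = p.sum(axis=1, keepdims=True)
    dead = sums[:, 0] == 0.0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} epoch(s) with all-zero densities; "
                      "falling back to uniform emissions", stacklevel=2)
        p[dead] = 0.2
        sums[dead] = 1.0
    out = p / sums
    return out if np.asarray(p_by_stage).ndim == 2 else out[0]


#: Default group layout: 13 groups x 5 stages = 65 emission features.
def default_emission_groups(seed: int = 0) -> list[tuple[str, EmissionGroup]]:
    groups: list[tuple[str, EmissionGroup]] = [
        (f"orp_{s}", KDE1DEmission(f"orp_{s}")) for s in STAGES]
    groups += [
        ("spindles", NegBinJointEmission(seed=seed)),
        ("rems", RemJointEmission(seed=seed)),
        ("sems", SemJointEmission()),
        ("emg", PowerLawEmission()),
        ("hr", KDE2DEmission(("hr_quantile", "hr_change"))),
        ("sao2", KDE2DEmission(("sao2_mean", "sao2_var"))),
        ("position", HistogramEmission("position_change", support_max=1)),
        ("snores", HistogramEmission("n_snores", support_max=10)),
    ]
    return groups


class EmissionModelSet(BaseEstimator):
    """The ordered collection of emission groups for a staging model.

    ``transform`` maps a per-epoch feature table to the flat emission vector
    (one block of 5 per group, each block summing to exactly 1).
    """

    def __init__(self, groups=None, seed: int = 0):
        self.groups = groups
        self.seed = seed

    def fit(self, df: pd.DataFrame, stages) -> "EmissionModelSet":
        self.groups_ = [(name, g.fit(df, stages)) for name, g in
                        (self.groups if self.groups is not None
                         else default_emission_groups(self.seed))]
        self.group_names_ = [name for name, _ in self.groups_]
        return self

    @property
    def n_features_(self) -> int:
        return N_STAGES * len(self.groups_)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        """Emission matrix of shape (n_epochs, 5 * n_groups)."""
        blocks = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _, g in self.groups_:
                blocks.append(normalize_emissions(g.stage_densities(df)))
        out = np.hstack(blocks)
        # Eq-9 invariant: every group block sums to one per epoch
        for k in range(len(self.groups_)):
            block = out[:, k * N_STAGES:(k + 1) * N_STAGES]
            np.testing.assert_allclose(block.sum(axis=1), 1.0, atol=1e-9)
        return out

    def fit_transform(self, df: pd.DataFrame, stages) -> np.ndarray:
        return self.fit(df, stages).transform(df)
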