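"""QUEST staircases, 4AFC synthetic observers, and psychometric fitting.

Visual acuity is measured with a four-alternative forced-choice Snellen-E
orientation task.  Stimulus sizes are driven by QUEST (Watson & Pelli): a
Bayesian posterior over log10 threshold is updated after every trial and the
next stimulus is placed at the posterior mode.  An eye's threshold estimate
pools five consecutive 20-trial staircases (~100 trials) and fits a
maximum-likelihood cumulative Gaussian on log10 gap size with guess rate
gamma = 0.25; the acuity threshold is the gap size where the fitted function
crosses 62.5% correct (midway between guessing and perfect), with a
bootstrap confidence interval.

Stimulus sizes are quantized to whole raster pixels (0.1 arcmin = 6 arcsec
at the default scale) before presentation, as a pixel display forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "SyntheticObserver",
    "TrialRecord",
    "QuestStaircase",
    "PsychometricFit",
    "FitError",
    "quest_run",
    "pool_runs",
    "fit_psychometric",
    "threshold_vs_nyquist",
    "ORIENTATIONS",
]

ORIENTATIONS = ("up", "down", "left", "right")
GUESS_RATE = 0.25
THRESHOLD_CRITERION = 0.625
PIXEL_ARCSEC = 6.0  # one 0.1-arcmin raster pixel


class FitError(RuntimeError):
    """Psychometric fit could not be computed; message carries diagnostics."""


@dataclass(frozen=True)
class SyntheticObserver:
    """Simulated 4AFC observer with a known psychometric function.

    ``threshold_arcsec`` is the gap size at 62.5% correct; ``slope_sigma``
    the SD of the underlying cumulative Gaussian in log10 units; guessing at
    gamma = 0.25 and a small lapse rate.
    """

    threshold_arcsec: float = 24.0
    slope_sigma: float = 0.08
    lapse: float = 0.01

    def __post_init__(self):
        if self.threshold_arcsec <= 0 or self.slope_sigma <= 0:
            raise ValueError("threshold and slope must be positive")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")

    @property
    def _mean_log10(self) -> float:
        upper = 1.0 - GUESS_RATE - self.lapse
        z0 = norm.ppf((THRESHOLD_CRITERION - GUESS_RATE) / upper)
        return float(np.log10(self.threshold_arcsec) - self.slope_sigma * z0)

    def p_correct(self, gap_arcsec: float) -> float:
        """Probability of a correct orientation report at this gap size."""
        z = (np.log10(gap_arcsec) - self._mean_log10) / self.slope_sigma
        return float(GUESS_RATE + (1.0 - GUESS_RATE - self.lapse) * norm.cdf(z))


@dataclass(frozen=True)
class TrialRecord:
    """One 4AFC trial: presented gap, true and reported orientation."""

    run: int
    trial: int
    gap_arcsec: float
    orientation: str
    response: str
    correct: bool

    def __post_init__(self):
        if self.correct != (self.response == self.orientation):
            raise ValueError("correct flag inconsistent with response")


class QuestStaircase:
    """QUEST (Watson-Pelli) adaptive staircase on log10 gap size.

    The posterior over log10 threshold starts as a Gaussian prior
    (default SD 0.5 centered on 40 arcsec) on a discrete grid and is updated
    with a Weibull trial likelihood with slope ``beta``, guess rate
    ``gamma`` = 0.25 and lapse ``delta``.  The next stimulus is placed at
    the posterior mode.
    """

    def __init__(self, prior_mean_arcsec: float = 40.0,
                 prior_sd_log10: float = 0.5, beta: float = 3.5,
                 delta: float = 0.01, gamma: float = GUESS_RATE,
                 grid: np.ndarray | None = None):
        self.beta, self.delta, self.gamma = beta, delta, gamma
        if grid is None:
            grid = np.linspace(np.log10(2.0), np.log10(300.0), 600)
        self.grid = grid
        prior = norm.pdf(grid, loc=np.log10(prior_mean_arcsec),
                         scale=prior_sd_log10)
        self.posterior = prior / prior.sum()
        self.stimulus_history: list[float] = []
        self.response_history: list[bool] = []

    @property
    def trial_count(self) -> int:
        return len(self.stimulus_history)

    def _p_correct(self, x_log10: float) -> np.ndarray:
        """Weibull psychometric at stimulus x for every candidate threshold."""
        e = np.exp(-np.power(10.0, self.beta * (x_log10 - self.grid)))
        return self.delta * self.gamma + (1.0 - self.delta) * (
            1.0 - (1.0 - self.gamma) * e)

    def next_stimulus(self, quantize_arcsec: float | None = PIXEL_ARCSEC
                      ) -> float:
        """Posterior-mode gap size (arcsec), optionally pixel-quantized."""
        mode = float(self.grid[int(np.argmax(self.posterior))])
        gap = 10.0 ** mode
        if quantize_arcsec:
            gap = max(1.0, round(gap / quantize_arcsec)) * quantize_arcsec
        return gap

    def update(self, gap_arcsec: float, correct: bool) -> None:
        like = self._p_correct(np.log10(gap_arcsec))
        self.posterior = self.posterior * (like if correct else 1.0 - like)
        total = self.posterior.sum()
        if total <= 0:  # pragma: no cover - degenerate numerical corner
            raise FitError("QUEST posterior collapsed to zero")
        self.posterior = self.posterior / total
        self.stimulus_history.append(float(gap_arcsec))
        self.response_history.append(bool(correct))

    def estimate_log10(self) -> float:
        """Posterior-mean estimate of log10 threshold."""
        return float(np.dot(self.grid, self.posterior))


def quest_run(observer: SyntheticObserver, n_trials: int = 20,
              seed: int | np.random.Generator = 0, run: int = 0,
              staircase: QuestStaircase | None = None,
              quantize_arcsec: float | None = PIXEL_ARCSEC,
              p_correct_fn=None) -> list[TrialRecord]:
    """Simulate one QUEST staircase run against a synthetic observer.

    Reproducible under a fixed seed.  ``p_correct_fn`` overrides the
    observer's psychometric function (gap -> probability correct), e.g. to
    couple performance to per-trial sampling density.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sc = staircase if staircase is not None else QuestStaircase()
    pfun = p_correct_fn if p_correct_fn is not None else observer.p_correct
    records = []
    for t in range(n_trials):
        gap = sc.next_stimulus(quantize_arcsec)
        orientation = ORIENTATIONS[rng.integers(4)]
        correct = bool(rng.random() < pfun(gap))
        if correct:
            response = orientation
        else:
            others = [o for o in ORIENTATIONS if o != orientation]
            response = others[rng.integers(3)]
        sc.update(gap, correct)
        records.append(TrialRecord(run=run, trial=t, gap_arcsec=gap,
                                   orientation=orientation, response=response,
                                   correct=correct))
    return records


def pool_runs(runs: list[list[TrialRecord]]) -> list[TrialRecord]:
    """Concatenate consecutive staircase runs of one eye (~5 x 20 trials)."""
    if not runs:
        raise ValueError("no runs to pool")
    indices = [r[0].run for r in runs if r]
    if len(indices) != len(set(indices)):
        raise ValueError("duplicate run indices in pooled runs")
    return [rec for r in runs for rec in r]


@dataclass(frozen=True)
class PsychometricFit:
    """Pooled-trial 4AFC threshold estimate at the 62.5% criterion.

    ``threshold_arcsec`` is the gap where the fitted cumulative Gaussian
    (gamma = 0.25, lapse in [0, 0.06]) crosses 62.5% correct; the CI is a
    nonparametric bootstrap percentile interval.
    """

    threshold_arcsec: float
    mean_log10: float
    slope_sigma: float
    lapse: float
    n_trials: int
    ci95: tuple[float, float] = (float("nan"), float("nan"))

    def p_correct(self, gap_arcsec: float) -> float:
        z = (np.log10(gap_arcsec) - self.mean_log10) / self.slope_sigma
        return float(GUESS_RATE + (1.0 - GUESS_RATE - self.lapse) * norm.cdf(z))


def _nll(params, levels, correct):
    m, s, lam = params
    z = (levels - m) / s
    p = GUESS_RATE + (1.0 - GUESS_RATE - lam) * norm.cdf(z)
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return -np.sum(np.where(correct, np.log(p), np.log1p(-p)))


def _mle(levels: np.ndarray, correct: np.ndarray, lapse_max: float):
    bounds = [(levels.min() - 1.0, levels.max() + 1.0), (0.005, 1.0),
              (0.0, lapse_max)]
    best = None
    for m0 in (np.median(levels), levels.mean() - 0.1, levels.mean() + 0.1):
        for s0 in (0.05, 0.15):
            res = minimize(_nll, x0=[m0, s0, 0.01],
                           args=(levels, correct), method="L-BFGS-B",
                           bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    return best


def fit_psychometric(trials: list[TrialRecord], lapse_max: float = 0.06,
                     n_boot: int = 500, seed: int = 0,
                     criterion: float = THRESHOLD_CRITERION) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit on log10 gap size.

    Requires >= 20 trials over >= 2 distinct levels and a mix of correct and
    incorrect responses.  The threshold is the gap size where the fitted
    probability equals ``criterion`` (0.625); set ``n_boot=0`` to skip the
    bootstrap CI.
    """
    if len(trials) < 20:
        raise FitError(f"need at least 20 trials, got {len(trials)}")
    levels = np.log10([t.gap_arcsec for t in trials])
    correct = np.array([t.correct for t in trials], dtype=bool)
    if np.unique(levels).size < 2:
        raise FitError("need at least 2 distinct stimulus levels")
    if correct.all() or not correct.any():
        raise FitError("all responses identical; psychometric slope undefined")

    res = _mle(levels, correct, lapse_max)
    if not res.success and not np.isfinite(res.fun):
        raise FitError(f"fit failed to converge: {res.message}")
    m, s, lam = res.x

    def _threshold(m, s, lam):
        z = norm.ppf((criterion - GUESS_RATE) / (1.0 - GUESS_RATE - lam))
        return 10.0 ** (m + s * z)

    thr = _threshold(m, s, lam)
    ci = (float("nan"), float("nan"))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = []
        n = len(trials)
        for _ in range(n_boot):
            idx = rng.integers(n, size=n)
            lv, cc = levels[idx], correct[idx]
            if np.unique(lv).size < 2 or cc.all() or not cc.any():
                continue
            r = _mle(lv, cc, lapse_max)
            boot.append(_threshold(*r.x))
        if len(boot) >= max(10, n_boot // 2):
            ci = tuple(np.percentile(boot, [2.5, 97.5]))
    return PsychometricFit(threshold_arcsec=float(thr), mean_log10=float(m),
                           slope_sigma=float(s), lapse=float(lam),
                           n_trials=len(trials), ci95=ci)


def threshold_vs_nyquist(fit: PsychometricFit, landmarks
                         ) -> tuple[float, float]:
    """Acuity threshold normalized to the eye's Nyquist limit.

    Returns (threshold / Nyquist, threshold - Nyquist in arcsec); a ratio
    below 1 means resolution beat the static sampling prediction.
    """
    nyq = landmarks.nyquist_arcsec
    return fit.threshold_arcsec / nyq, fit.threshold_arcsec - nyq
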