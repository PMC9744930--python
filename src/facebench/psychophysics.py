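"""Psychometric analysis: response curves, logistic fits, PSE statistics.

The behavioral summary of an observer (human or network) along a morph
continuum is the psychometric function — the probability of an "Asian"
response as a function of the morph coordinate t in [0, 1].  We fit the
2-parameter logistic

    P(t) = 1 / (1 + exp(-beta * (t - pse)))

by least squares; ``pse`` (point of subjective equality) is where the curve
crosses 0.5 and ``beta`` the steepness.  No lapse parameters: at 21 levels x
20 repetitions they are not identifiable.

Fits are gated before any PSE is reported: the curve must rise (beta > 0),
fit well (R^2 above a threshold), and cross 0.5 inside the morph axis
(pse in [0, 1] — the "large bias" discard).  A model PSE is compared to the
human group benchmark with a one-sample two-tailed t test,
t = (pse - mean) / sem on n - 1 degrees of freedom, with Bonferroni
correction over the experiment's family of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .netlab import TinyCNN, predict_proba
from .stimuli import StimulusSet, resize_with_masks


@dataclass
class ResponseCurve:
    """Per-level probability of the Asian-class response."""

    levels: np.ndarray
    p_asian: np.ndarray
    source: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.p_asian = np.asarray(self.p_asian, dtype=float)
        if self.levels.shape != self.p_asian.shape:
            raise ValueError("one probability per level required")
        if np.any((self.p_asian < -1e-9) | (self.p_asian > 1 + 1e-9)):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class PsychometricFit:
    pse: float
    beta: float
    r_squared: float
    valid: bool = False
    invalid_reason: str = ""


@dataclass(frozen=True)
class HumanBenchmark:
    """Group summary of the human observers (mean PSE, its SEM, group size)."""

    mean: float = 0.362
    sem: float = 0.012
    n: int = 30

    def __post_init__(self) -> None:
        if self.sem <= 0:
            raise ValueError("sem must be positive")

    @property
    def df(self) -> int:
        return self.n - 1


@dataclass
class StatResult:
    t: float
    df: int
    p_uncorrected: float
    p_corrected: float | None = None
    family_size: int | None = None
    significant: bool | None = None  # at alpha = 0.05 after correction


@dataclass
class GateThresholds:
    """Configurable validity-gate thresholds."""

    min_r_squared: float = 0.5
    pse_range: tuple[float, float] = (0.0, 1.0)


def logistic(t: np.ndarray, pse: float, beta: float) -> np.ndarray:
    return expit(beta * (np.asarray(t, dtype=float) - pse))


def response_curve(model: TinyCNN, stimulus_set: StimulusSet) -> ResponseCurve:
    """Evaluate a classifier on a stimulus set, one probability per level.

    Images are resampled to the model's input resolution (with the layout
    rescaled consistently) before prediction.
    """
    probs = []
    for im in stimulus_set.images:
        resized, _ = resize_with_masks(im, stimulus_set.feature_layout,
                                       (model.input_size, model.input_size))
        probs.append(predict_proba(model, resized)[1])
    return ResponseCurve(stimulus_set.levels, np.array(probs),
                         source="model", condition=stimulus_set.condition)


def fit_psychometric(curve: ResponseCurve,
                     gate: GateThresholds | None = None) -> PsychometricFit:
    """Least-squares 2-parameter logistic fit, gated for validity."""
    t, p = curve.levels, curve.p_asian
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct levels")
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    if ss_tot < 1e-16:
        return PsychometricFit(np.nan, np.nan, np.nan, False, "flat_curve")

    def sse(params: np.ndarray) -> float:
        return float(np.sum((logistic(t, *params) - p) ** 2))

    # initial guess: 0.5-crossing by interpolation, slope from the range
    order = np.argsort(t)
    crossings = np.where(np.diff(np.sign(p[order] - 0.5)) != 0)[0]
    pse0 = float(t[order][crossings[0]]) if len(crossings) else float(t[np.argmin(np.abs(p - 0.5))])
    beta0 = 10.0 if p[order][-1] >= p[order][0] else -10.0
    best = None
    for p0 in ([pse0, beta0], [0.5, beta0], [pse0, beta0 / 4], [pse0, beta0 * 4]):
        try:
            popt, _ = optimize.curve_fit(logistic, t, p, p0=p0, maxfev=5000)
        except RuntimeError:
            continue
        if best is None or sse(popt) < sse(best):
            best = popt
    if best is None:  # coarse grid fallback for pathological curves
        grid = [(a, b) for a in np.linspace(-0.5, 1.5, 41)
                for b in np.concatenate([-np.geomspace(1, 200, 12),
                                         np.geomspace(1, 200, 12)])]
        best = np.array(min(grid, key=sse))
    pse, beta = float(best[0]), float(best[1])
    r2 = 1.0 - sse(best) / ss_tot
    fit = PsychometricFit(pse, beta, r2)
    valid, reason = validity_gate(fit, curve, gate)
    return replace(fit, valid=valid, invalid_reason=reason)


def validity_gate(fit: PsychometricFit, curve: ResponseCurve | None = None,
                  gate: GateThresholds | None = None) -> tuple[bool, str]:
    """Decide whether a fit supports a meaningful PSE.

    Criteria, in order: finite parameters, rising curve (beta > 0), adequate
    goodness of fit, and PSE inside the morph axis.  The reason names the
    first criterion that failed.
    """
    gate = GateThresholds() if gate is None else gate
    if not np.isfinite(fit.pse) or not np.isfinite(fit.beta):
        return False, fit.invalid_reason or "degenerate_fit"
    if fit.beta <= 0:
        return False, "non_increasing"
    if fit.r_squared < gate.min_r_squared:
        return False, "poor_fit"
    lo, hi = gate.pse_range
    if not lo <= fit.pse <= hi:
        return False, "pse_out_of_range"
    return True, ""


def pse_ttest(pse: float, bench: HumanBenchmark) -> StatResult:
    """One-sample two-tailed t test of a PSE against the human group."""
    t = (pse - bench.mean) / bench.sem
    p = 2.0 * stats.t.sf(abs(t), bench.df)
    return StatResult(t=float(t), df=bench.df, p_uncorrected=float(p))


def bonferroni(results: list[StatResult], family_size: int,
               alpha: float = 0.05) -> list[StatResult]:
    """Bonferroni correction: p_corrected = min(1, m * p_uncorrected)."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    out = []
    for r in results:
        pc = min(1.0, family_size * r.p_uncorrected)
        out.append(replace(r, p_corrected=pc, family_size=family_size,
                           significant=pc < alpha))
    return out


def curve_from_trials(trials: pd.DataFrame, source: str = "observer") -> ResponseCurve:
    """Collapse a 2AFC trial table to per-level response proportions."""
    grouped = trials.groupby("level")["response"].mean()
    return ResponseCurve(grouped.index.to_numpy(), grouped.to_numpy(), source=source)


@dataclass
class ObserverFits:
    fits: list[PsychometricFit]
    group_mean: float
    group_sem: float
    n_valid: int


def fit_observer_pses(trial_tables: list[pd.DataFrame],
                      gate: GateThresholds | None = None) -> ObserverFits:
    """Fit each observer's proportion curve; summarize valid PSEs.

    Returns the per-observer fits plus the group mean and SEM over the
    observers whose fits passed the validity gate.
    """
    fits = [fit_psychometric(curve_from_trials(tt), gate) for tt in trial_tables]
    pses = np.array([f.pse for f in fits if f.valid])
    if len(pses) == 0:
        raise ValueError("no observer produced a valid psychometric fit")
    sem = float(pses.std(ddof=1) / np.sqrt(len(pses))) if len(pses) > 1 else 0.0
    return ObserverFits(fits, float(pses.mean()), sem, len(pses))
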