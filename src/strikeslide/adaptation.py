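"""Motor-adaptation analysis: spatial error, exponential fits across
trials, and block-transition generalization tests.

Performance on trial ``i`` (spatial error or launch speed) is modelled as

    performance = offset + constant * exp(-(trial - 1) / tau)

where ``offset`` is the asymptotic performance, ``constant`` the magnitude
and direction of the adaptation, and ``tau`` its decay constant in trials.
Fits with R² > 0.75 count as strong evidence of adaptation; in the noisier
group-stratified block-transition analysis a relaxed 0.50 threshold marks
moderate evidence.

Generalization of the internal friction model across blocks ("thumb-up"):
if the cohort's spatial error is statistically indistinguishable from zero
both on the last trial of a block and on the first trial of the next block
(one-sample t tests at a Bonferroni-corrected alpha), the movers carried a
calibrated friction belief across the change in condition.  A paired t
test between the two trials additionally flags abrupt behaviour changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

R2_STRONG = 0.75
R2_MODERATE = 0.50

#: Bonferroni-corrected significance levels used by the cohort analyses.
ALPHA_PER_MATERIAL_6 = 0.05 / 6
ALPHA_PER_MATERIAL_4 = 0.05 / 4
ALPHA_TRANSITION_ONE_SAMPLE = 0.05 / 12
ALPHA_TRANSITION_PAIRED = 0.05 / 4

TAU_BOUNDS = (0.1, 100.0)
_TAU_STARTS = (0.5, 2.0, 8.0, 30.0)  # multi-start grid, trials


@dataclass(frozen=True)
class AdaptationFit:
    offset: float
    constant: float
    tau: float
    r_squared: float
    classification: str  # strong | moderate | none | degenerate

    @property
    def is_adaptation(self) -> bool:
        return self.classification == "strong"


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    significant: bool
    degenerate: bool = False
    n: int = 0


@dataclass(frozen=True)
class TransitionReport:
    block_from: int
    block_to: int
    material: str
    last_trial_error_test: TTestResult
    first_trial_error_test: TTestResult
    between_trial_change_test: TTestResult
    generalization_flag: bool  # the "thumb-up"


def spatial_error(final_front_edge: float, target: float) -> float:
    """Signed final-position error as a percentage of target distance.

    Positive for overshoots, negative for undershoots.
    """
    if target <= 0:
        raise ValueError(f"target distance must be > 0, got {target}")
    return 100.0 * (final_front_edge - target) / target


def _classify(r2: float) -> str:
    if r2 > R2_STRONG:
        return "strong"
    if r2 > R2_MODERATE:
        return "moderate"
    return "none"


def fit_adaptation(series, tau_bounds: tuple[float, float] = TAU_BOUNDS) -> AdaptationFit:
    """Fit the exponential adaptation model to a per-trial series.

    Nonlinear least squares over (offset, constant, tau) with tau bounded
    to ``tau_bounds`` trials.  For each start value of the tau grid, the
    linear parameters are solved exactly (the model is linear in offset
    and constant given tau) before the joint refinement, which makes the
    fit deterministic in the input and equivariant under rescaling of the
    series.  R² is computed against the series mean and reported even
    when negative (classification "none").  A constant series is flagged
    ``degenerate`` — tau is unidentifiable — rather than given arbitrary
    parameters.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) < 4:
        raise ValueError("need a 1-D series of >= 4 values")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    trials = np.arange(1, len(y) + 1, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < 1e-24 * max(1.0, float(np.abs(y).max())) ** 2 or np.ptp(y) == 0:
        return AdaptationFit(offset=float(y.mean()), constant=0.0, tau=math.nan,
                             r_squared=math.nan, classification="degenerate")

    def linear_solve(tau):
        basis = np.exp(-(trials - 1.0) / tau)
        design = np.column_stack([np.ones_like(basis), basis])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return coef  # offset, constant

    def residuals(params):
        offset, constant, tau = params
        return offset + constant * np.exp(-(trials - 1.0) / tau) - y

    best = None
    for tau0 in _TAU_STARTS:
        offset0, constant0 = linear_solve(tau0)
        try:
            res = optimize.least_squares(
                residuals,
                x0=[offset0, constant0, tau0],
                bounds=([-np.inf, -np.inf, tau_bounds[0]], [np.inf, np.inf, tau_bounds[1]]),
                method="trf",
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost - 1e-15 * abs(best.cost):
            best = res
    offset, constant, tau = best.x
    ssr = float(np.sum(best.fun**2))
    r2 = 1.0 - ssr / sst
    return AdaptationFit(offset=float(offset), constant=float(constant),
                         tau=float(tau), r_squared=float(r2),
                         classification=_classify(r2))


def test_error_vs_zero(errors, corrected_alpha: float) -> TTestResult:
    """Two-sided one-sample t test of cohort errors against zero.

    Zero-variance input is flagged degenerate (the t statistic is
    undefined) instead of raising.
    """
    x = np.asarray(errors, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(x) == 0:
        return TTestResult(t=math.nan, p=math.nan, significant=False,
                           degenerate=True, n=len(x))
    res = stats.ttest_1samp(x, 0.0)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                       significant=bool(res.pvalue < corrected_alpha), n=len(x))


test_error_vs_zero.__test__ = False  # a statistics routine, not a pytest case


def _paired_test(last, first, corrected_alpha: float) -> TTestResult:
    d = np.asarray(first, dtype=float) - np.asarray(last, dtype=float)
    if np.ptp(d) == 0:
        return TTestResult(t=math.nan, p=math.nan, significant=False,
                           degenerate=True, n=len(d))
    res = stats.ttest_rel(first, last)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                       significant=bool(res.pvalue < corrected_alpha), n=len(d))


def _transition_pairs(blocks: pd.DataFrame) -> list[tuple[int, int, str]]:
    """Consecutive block pairs sharing a surface material, plus the
    half-session transition where slope, material and distance all change."""
    meta = blocks.sort_values("block").drop_duplicates("block")
    pairs = []
    rows = list(meta.itertuples())
    for a, b in zip(rows, rows[1:]):
        if b.block != a.block + 1:
            continue
        if a.material == b.material:
            pairs.append((a.block, b.block, a.material))
        elif a.target_m != b.target_m:  # the triple-change transition
            pairs.append((a.block, b.block, f"{a.material}->{b.material}"))
    return pairs


def analyze_transitions(
    performance: pd.DataFrame,
    one_sample_alpha: float = ALPHA_TRANSITION_ONE_SAMPLE,
    paired_alpha: float = ALPHA_TRANSITION_PAIRED,
) -> list[TransitionReport]:
    """Block-transition generalization analysis on a tidy cohort table.

    ``performance`` must contain columns ``participant``, ``block``,
    ``trial`` (1-based within block), ``material``, ``target_m`` and
    ``spatial_error_pct``, for a cohort that shares one block design.
    For every consecutive block pair with the same surface material, and
    for the half-session transition where material, slope and target
    distance change simultaneously, the cohort's last-trial and
    first-trial errors are each tested against zero at
    ``one_sample_alpha`` and the change between the two trials with a
    paired test at ``paired_alpha``.  The generalization flag is raised
    iff neither one-sample test is significant.
    """
    required = {"participant", "block", "trial", "material", "target_m",
                "spatial_error_pct"}
    missing = required - set(performance.columns)
    if missing:
        raise ValueError(f"performance table lacks columns: {sorted(missing)}")
    n_participants = performance["participant"].nunique()
    if n_participants < 2:
        raise ValueError("transition tests need >= 2 participants")

    last_trial = performance["trial"].max()
    reports = []
    for b_from, b_to, material in _transition_pairs(performance):
        last = (
            performance.query("block == @b_from and trial == @last_trial")
            .set_index("participant")["spatial_error_pct"]
        )
        first = (
            performance.query("block == @b_to and trial == 1")
            .set_index("participant")["spatial_error_pct"]
        )
        common = last.index.intersection(first.index)
        if len(common) < 2:
            raise ValueError(
                f"blocks {b_from}->{b_to}: fewer than 2 participants with "
                "both boundary trials"
            )
        last, first = last.loc[common], first.loc[common]
        t_last = test_error_vs_zero(last.to_numpy(), one_sample_alpha)
        t_first = test_error_vs_zero(first.to_numpy(), one_sample_alpha)
        t_change = _paired_test(last.to_numpy(), first.to_numpy(), paired_alpha)
        reports.append(
            TransitionReport(
                block_from=b_from,
                block_to=b_to,
                material=material,
                last_trial_error_test=t_last,
                first_trial_error_test=t_first,
                between_trial_change_test=t_change,
                generalization_flag=not (t_last.significant or t_first.significant),
            )
        )
    return reports


def fit_blocks(
    performance: pd.DataFrame,
    value: str = "spatial_error_pct",
    by: tuple[str, ...] = ("block",),
) -> pd.DataFrame:
    """Fit the adaptation model to cohort-mean per-trial series.

    Groups the tidy table by ``by``, averages ``value`` across
    participants per trial, fits :func:`fit_adaptation`, and returns one
    row per group with the fit parameters and classification.
    """
    rows = []
    for key, grp in performance.groupby(list(by)):
        series = grp.groupby("trial")[value].mean().sort_index().to_numpy()
        if len(series) < 4:
            fit = AdaptationFit(offset=float(np.mean(series)), constant=math.nan,
                                tau=math.nan, r_squared=math.nan,
                                classification="degenerate")
        else:
            fit = fit_adaptation(series)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(
            offset=fit.offset, constant=fit.constant, tau=fit.tau,
            r_squared=fit.r_squared, classification=fit.classification,
            n_trials=len(series),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def transitions_table(reports: list[TransitionReport]) -> pd.DataFrame:
    """Flatten transition reports into a tidy table."""
    rows = []
    for r in reports:
        rows.append(
            {
                "block_from": r.block_from,
                "block_to": r.block_to,
                "material": r.material,
                "t_last": r.last_trial_error_test.t,
                "p_last": r.last_trial_error_test.p,
                "sig_last": r.last_trial_error_test.significant,
                "t_first": r.first_trial_error_test.t,
                "p_first": r.first_trial_error_test.p,
                "sig_first": r.first_trial_error_test.significant,
                "t_change": r.between_trial_change_test.t,
                "p_change": r.between_trial_change_test.p,
                "sig_change": r.between_trial_change_test.significant,
                "generalization": r.generalization_flag,
            }
        )
    return pd.DataFrame(rows)
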