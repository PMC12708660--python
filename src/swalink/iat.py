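"""Implicit Association Test (IAT) D-scoring and cohort behavioral summaries.

The race IAT used here has seven blocks and 190 trials: two single-category
learning blocks (20 trials each), two "congruent" test blocks (3-4, 60
trials total), one reversed-assignment practice block (30 trials), and two
"incongruent" test blocks (6-7, 60 trials total).  The D-score divides the
mean correct-trial latency difference (incongruent − congruent) by the
inclusive standard deviation of all included correct trials pooled across
both conditions; the absolute D-score is its magnitude, so bias strength is
captured irrespective of direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ScoringError

#: blocks contributing to each scored condition (1-based block numbers)
CONGRUENT_BLOCKS = (3, 4)
INCONGRUENT_BLOCKS = (6, 7)

#: trials per block for the task as administered
BLOCK_SIZES = {1: 20, 2: 20, 3: 30, 4: 30, 5: 30, 6: 30, 7: 30}

#: absolute-D cutpoints for the conventional bias-strength labels
BIAS_CUTPOINTS = (0.20, 0.49, 0.74)
BIAS_LABELS = ("none", "weak", "moderate", "strong")

REQUIRED_COLUMNS = ("block", "trial", "category", "rt_ms", "correct")


@dataclass(frozen=True)
class IATScoringOptions:
    """Exclusion and variant switches for :func:`score_iat`.

    The defaults follow the task description (correct trials only, one
    pooled D over blocks 3-4 vs 6-7); ``error_penalty_ms`` enables the
    conventional-algorithm variant in which error trials enter the
    condition means at (block mean of correct trials + penalty).
    """

    min_trials: int = 10
    rt_max_ms: float = 10_000.0
    fast_rt_ms: float = 300.0
    fast_fraction_warn: float = 0.10
    error_penalty_ms: float | None = None
    practice_test_split: bool = False


@dataclass(frozen=True)
class DScoreResult:
    subject: str
    d: float
    abs_d: float
    mean_rt_congruent_ms: float
    mean_rt_incongruent_ms: float
    inclusive_sd_ms: float
    n_trials_used: int
    n_excluded: int
    n_errors_congruent: int
    n_errors_incongruent: int
    bias_category: str
    fast_rt_flagged: bool = False
    out_of_range: bool = field(default=False)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def bias_category(abs_d: float) -> str:
    """Label bias strength from |D| (<=0.20 none, <=0.49 weak, <=0.74
    moderate, else strong)."""
    for cut, label in zip(BIAS_CUTPOINTS, BIAS_LABELS):
        if abs_d <= cut:
            return label
    return BIAS_LABELS[-1]


def _check_columns(trials: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ScoringError(f"trial table missing columns: {missing}")
    if (trials["rt_ms"] <= 0).any():
        raise ScoringError("trial table contains non-positive RTs")


def _condition_rts(
    block_trials: pd.DataFrame, options: IATScoringOptions
) -> tuple[np.ndarray, np.ndarray]:
    """(RTs entering the condition mean, correct RTs entering the SD)."""
    correct = block_trials.loc[block_trials["correct"].astype(bool), "rt_ms"].to_numpy(float)
    if options.error_penalty_ms is None:
        return correct, correct
    rts = []
    for _, blk in block_trials.groupby("block"):
        ok = blk["correct"].astype(bool).to_numpy()
        blk_rt = blk["rt_ms"].to_numpy(float)
        if ok.sum() == 0:
            continue
        penal = blk_rt[ok].mean() + options.error_penalty_ms
        rts.append(np.where(ok, blk_rt, penal))
    means_input = np.concatenate(rts) if rts else np.empty(0)
    return means_input, correct


def _pooled_d(
    cong: pd.DataFrame, incong: pd.DataFrame, options: IATScoringOptions
) -> tuple[float, float, float, float]:
    cong_mean_in, cong_sd_in = _condition_rts(cong, options)
    inc_mean_in, inc_sd_in = _condition_rts(incong, options)
    for name, arr in (("congruent", cong_sd_in), ("incongruent", inc_sd_in)):
        if arr.size < options.min_trials:
            raise ScoringError(
                f"only {arr.size} usable correct trials in the {name} condition "
                f"(need >= {options.min_trials})"
            )
    pooled = np.concatenate([cong_sd_in, inc_sd_in])
    sd = float(np.std(pooled, ddof=1))
    if sd <= 0.0:
        raise DegenerateInputError("zero pooled (inclusive) SD of correct RTs")
    m_c = float(cong_mean_in.mean())
    m_i = float(inc_mean_in.mean())
    return (m_i - m_c) / sd, m_c, m_i, sd


def score_iat(
    trials: pd.DataFrame,
    options: IATScoringOptions | None = None,
    subject: str | None = None,
) -> DScoreResult:
    """Compute the IAT D-score for one subject's trial table.

    d = (mean RT incongruent − mean RT congruent) / inclusive SD, where the
    condition means use correct trials from blocks 3-4 (congruent) and 6-7
    (incongruent) and the inclusive SD pools all included correct trials
    across both conditions (n−1 denominator).  RTs above ``rt_max_ms`` are
    dropped first; a subject with more than ``fast_fraction_warn`` of RTs
    under ``fast_rt_ms`` is flagged.  Values of |d| beyond 2 are reported
    with a warning rather than clamped: the conventional ±2 range is an
    empirical property of the score, not part of its formula.
    """
    options = options or IATScoringOptions()
    _check_columns(trials)
    if subject is None:
        subject = str(trials["subject"].iloc[0]) if "subject" in trials.columns else "?"

    test = trials[trials["block"].isin(CONGRUENT_BLOCKS + INCONGRUENT_BLOCKS)]
    slow = test["rt_ms"] > options.rt_max_ms
    n_excluded = int(slow.sum())
    kept = test[~slow]
    fast_frac = float((kept["rt_ms"] < options.fast_rt_ms).mean()) if len(kept) else 0.0
    fast_flag = fast_frac > options.fast_fraction_warn
    if fast_flag:
        warnings.warn(
            f"subject {subject}: {fast_frac:.0%} of test-block RTs below "
            f"{options.fast_rt_ms:.0f} ms", stacklevel=2,
        )

    cong = kept[kept["block"].isin(CONGRUENT_BLOCKS)]
    incong = kept[kept["block"].isin(INCONGRUENT_BLOCKS)]

    if options.practice_test_split:
        ds = []
        for cb, ib in zip(CONGRUENT_BLOCKS, INCONGRUENT_BLOCKS):
            d_half, *_ = _pooled_d(
                cong[cong["block"] == cb], incong[incong["block"] == ib], options
            )
            ds.append(d_half)
        d = float(np.mean(ds))
        _, m_c, m_i, sd = _pooled_d(cong, incong, options)
    else:
        d, m_c, m_i, sd = _pooled_d(cong, incong, options)

    out_of_range = abs(d) > 2.0
    if out_of_range:
        warnings.warn(f"subject {subject}: |D| = {abs(d):.2f} outside [-2, 2]", stacklevel=2)
    n_used = int(cong["correct"].astype(bool).sum() + incong["correct"].astype(bool).sum())
    return DScoreResult(
        subject=subject,
        d=float(d),
        abs_d=float(abs(d)),
        mean_rt_congruent_ms=m_c,
        mean_rt_incongruent_ms=m_i,
        inclusive_sd_ms=sd,
        n_trials_used=n_used,
        n_excluded=n_excluded,
        n_errors_congruent=int((~cong["correct"].astype(bool)).sum()),
        n_errors_incongruent=int((~incong["correct"].astype(bool)).sum()),
        bias_category=bias_category(abs(d)),
        fast_rt_flagged=fast_flag,
        out_of_range=out_of_range,
    )


@dataclass(frozen=True)
class CohortBehaviorSummary:
    n_subjects: int
    mean_abs_d: float
    sd_abs_d: float
    min_abs_d: float
    max_abs_d: float
    mean_d: float
    sd_d: float
    mean_rt_congruent_ms: float
    mean_rt_incongruent_ms: float
    t_rt: float
    df_rt: int
    p_rt: float
    t_errors: float
    df_errors: int
    p_errors: float
    bias_histogram: dict

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _paired_t(diff: np.ndarray) -> tuple[float, int, float]:
    """Paired t = mean(diff) / (sd(diff)/√n), df = n−1."""
    from scipy import stats

    n = diff.size
    sd = float(np.std(diff, ddof=1))
    if sd <= 0.0:
        raise DegenerateInputError("zero variance of paired differences")
    t = float(diff.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return t, n - 1, p


def summarize_cohort_behavior(results: list[DScoreResult]) -> CohortBehaviorSummary:
    """Cohort-level behavior: |D| moments and histogram, paired t statistics
    on condition mean RTs and on error counts (incongruent − congruent)."""
    if len(results) < 2:
        raise ScoringError("cohort summary needs at least 2 subjects")
    abs_d = np.array([r.abs_d for r in results])
    d = np.array([r.d for r in results])
    rt_c = np.array([r.mean_rt_congruent_ms for r in results])
    rt_i = np.array([r.mean_rt_incongruent_ms for r in results])
    err_c = np.array([r.n_errors_congruent for r in results], float)
    err_i = np.array([r.n_errors_incongruent for r in results], float)
    t_rt, df_rt, p_rt = _paired_t(rt_i - rt_c)
    t_err, df_err, p_err = _paired_t(err_i - err_c)
    hist = {label: 0 for label in BIAS_LABELS}
    for r in results:
        hist[r.bias_category] += 1
    return CohortBehaviorSummary(
        n_subjects=len(results),
        mean_abs_d=float(abs_d.mean()),
        sd_abs_d=float(abs_d.std(ddof=1)),
        min_abs_d=float(abs_d.min()),
        max_abs_d=float(abs_d.max()),
        mean_d=float(d.mean()),
        sd_d=float(d.std(ddof=1)),
        mean_rt_congruent_ms=float(rt_c.mean()),
        mean_rt_incongruent_ms=float(rt_i.mean()),
        t_rt=t_rt, df_rt=df_rt, p_rt=p_rt,
        t_errors=t_err, df_errors=df_err, p_errors=p_err,
        bias_histogram=hist,
    )
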