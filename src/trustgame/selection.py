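"""Model scoring (AIC), cohort-level paired comparisons and strategy
classification."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ars import SINGLE_STRATEGIES


class InsufficientDataError(ValueError):
    pass


def aic(sse: float, n: int, k: int) -> float:
    """n * ln(SSE / n) + 2k.

    A perfect fit (sse = 0) yields -inf: a signal that the participant
    should be excluded from comparisons, not an exception.
    """
    if sse < 0:
        raise ValueError("sse must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if sse == 0:
        return -math.inf
    return n * math.log(sse / n) + 2 * k


def score_models(fits: pd.DataFrame) -> pd.DataFrame:
    """Attach AIC to a fits table (participant_id, model, sse, n, k)."""
    scored = fits.copy()
    scored["aic"] = [
        aic(row.sse, int(row.n), int(row.k)) for row in fits.itertuples(index=False)
    ]
    return scored


@dataclass(frozen=True)
class ComparisonResult:
    model_a: str
    model_b: str
    mean_aic_a: float
    mean_aic_b: float
    sd_aic_a: float
    sd_aic_b: float
    t_statistic: float
    df: int
    p_value: float  # one-tailed, direction "model_a has lower AIC"
    cohens_d: float  # paired: |mean difference| / SD of differences
    n_pairs: int
    excluded_ids: tuple[str, ...] = field(default_factory=tuple)


def compare_paired(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> ComparisonResult:
    """One-tailed paired t-test on AIC, testing that model_a fits better.

    Participants with a perfect fit (sse = 0, AIC -inf) under either
    model are excluded first, mirroring the exclusion of
    perfectly-predicted participants.  Deliberately uncorrected for
    multiple tests.
    """
    a = scores_a.set_index("participant_id")
    b = scores_b.set_index("participant_id")
    common = a.index.intersection(b.index)
    if not a.index.equals(b.index):
        a = a.loc[common]
        b = b.loc[common]
    perfect = (a["sse"] == 0) | (b["sse"] == 0)
    excluded = tuple(str(i) for i in common[perfect])
    a = a[~perfect]
    b = b[~perfect]
    n = len(a)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 usable pairs, have {n}")
    aic_a = a["aic"].to_numpy(dtype=float)
    aic_b = b["aic"].to_numpy(dtype=float)
    res = stats.ttest_rel(aic_a, aic_b, alternative="less")
    diff = aic_a - aic_b
    sd_diff = float(np.std(diff, ddof=1))
    d = 0.0 if sd_diff == 0.0 else abs(float(np.mean(diff))) / sd_diff
    t = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(t):  # identical vectors: zero variance of differences
        t, p = 0.0, 0.5
    return ComparisonResult(
        model_a=str(scores_a["model"].iloc[0]),
        model_b=str(scores_b["model"].iloc[0]),
        mean_aic_a=float(np.mean(aic_a)),
        mean_aic_b=float(np.mean(aic_b)),
        sd_aic_a=float(np.std(aic_a, ddof=1)),
        sd_aic_b=float(np.std(aic_b, ddof=1)),
        t_statistic=t,
        df=n - 1,
        p_value=p,
        cohens_d=d,
        n_pairs=n,
        excluded_ids=excluded,
    )


#: Default classification thresholds; the published guidance is only
#: "close to", so interval midpoints are used and remain configurable.
DEFAULT_THRESHOLDS = {"psi_hr": 0.5, "tau_lat": 0.25, "tau_hat": 0.75}


def classify_strategy(
    tau_hat: float, psi_hat: float, thresholds: dict | None = None
) -> str:
    """Map fitted (tau, psi) to a strategy label.

    psi > psi_hr -> HR; else tau < tau_lat -> LAT; tau > tau_hat -> HAT;
    otherwise MT.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    if not (0.0 <= tau_hat <= 1.0 and 0.0 <= psi_hat <= 1.0):
        raise ValueError("tau_hat and psi_hat must lie in [0, 1]")
    if psi_hat > th["psi_hr"]:
        return "HR"
    if tau_hat < th["tau_lat"]:
        return "LAT"
    if tau_hat > th["tau_hat"]:
        return "HAT"
    return "MT"


def classify_cohort(
    ars_scores: pd.DataFrame, thresholds: dict | None = None
) -> pd.DataFrame:
    """Strategy label per participant from their ARS grid fit."""
    rows = []
    for row in ars_scores.itertuples(index=False):
        rows.append(
            {
                "participant_id": row.participant_id,
                "label": classify_strategy(row.tau_hat, row.psi_hat, thresholds),
                "tau_hat": row.tau_hat,
                "psi_hat": row.psi_hat,
            }
        )
    return pd.DataFrame(rows)


def aic_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD AIC per model over participants with finite AIC."""
    rows = []
    for model, group in scores.groupby("model", sort=False):
        finite = group[np.isfinite(group["aic"])]
        rows.append(
            {
                "model": model,
                "mean_aic": float(finite["aic"].mean()) if len(finite) else math.nan,
                "sd_aic": float(finite["aic"].std(ddof=1))
                if len(finite) > 1
                else math.nan,
                "n_finite": len(finite),
                "n_perfect": int((group["sse"] == 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def strategy_prevalence(labels: pd.DataFrame) -> pd.DataFrame:
    counts = labels["label"].value_counts()
    total = int(counts.sum())
    rows = []
    for strategy in SINGLE_STRATEGIES:
        c = int(counts.get(strategy, 0))
        rows.append(
            {"label": strategy, "count": c, "percent": 100.0 * c / total}
        )
    return pd.DataFrame(rows)


def recovery_table(labels: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-participant classification vs generating strategy label."""
    merged = labels.merge(
        truth[["participant_id", "strategy_label", "delta", "tau", "psi"]],
        on="participant_id",
    )
    merged["correct"] = merged["label"] == merged["strategy_label"]
    return merged


def compare_ars_to_strategies(
    scores: pd.DataFrame, strict: bool = False
) -> list[ComparisonResult]:
    """ARS vs each single-strategy model, in the fixed strategy order.

    Unless ``strict``, comparisons left with fewer than 3 usable pairs
    (after perfect-fit exclusions) yield a NaN-statistics placeholder
    instead of raising, so small synthetic cohorts still produce a report.
    """
    ars = scores[scores["model"] == "ARS"]
    results = []
    for strategy in SINGLE_STRATEGIES:
        other = scores[scores["model"] == strategy]
        try:
            results.append(compare_paired(ars, other))
        except InsufficientDataError:
            if strict:
                raise
            results.append(
                ComparisonResult(
                    model_a="ARS",
                    model_b=strategy,
                    mean_aic_a=math.nan,
                    mean_aic_b=math.nan,
                    sd_aic_a=math.nan,
                    sd_aic_b=math.nan,
                    t_statistic=math.nan,
                    df=0,
                    p_value=math.nan,
                    cohens_d=math.nan,
                    n_pairs=0,
                )
            )
    return results


def comparisons_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model_a": r.model_a,
                "model_b": r.model_b,
                "mean_aic_a": r.mean_aic_a,
                "mean_aic_b": r.mean_aic_b,
                "sd_aic_a": r.sd_aic_a,
                "sd_aic_b": r.sd_aic_b,
                "t_statistic": r.t_statistic,
                "df": r.df,
                "p_value": r.p_value,
                "cohens_d": r.cohens_d,
                "n_pairs": r.n_pairs,
                "n_excluded": len(r.excluded_ids),
            }
            for r in results
        ]
    )
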