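"""Known-truth flock-counting quiz analysis.

Observers shown timed images of flocks of known size systematically
undercount, and the error grows with flock size. Given per-respondent
responses to known-truth images, this module computes per-image percent
difference statistics (mean absolute percent difference with a confidence
interval, under/over/exact shares, mean response-to-truth ratio) and compares
respondent groups (experience or confidence level) with a permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "QuizResponse",
    "group_comparison",
    "image_error_stats",
    "load_quiz",
    "write_quiz",
]

EXPERIENCE_LEVELS = ("Expert", "Intermediate", "Novice", "NoExperience")
CONFIDENCE_LEVELS = ("High", "Medium", "Low")

QUIZ_COLUMNS = ["respondent_id", "experience", "confidence", "image_id", "true_count", "response"]


@dataclass(frozen=True)
class QuizResponse:
    """One respondent's count for one known-truth image."""

    respondent_id: str
    experience: str
    confidence: str
    image_id: str
    true_count: int
    response: int

    def __post_init__(self) -> None:
        if self.true_count < 1:
            raise ValueError(f"true_count must be >= 1, got {self.true_count}")
        if self.response < 0:
            raise ValueError(f"response must be >= 0, got {self.response}")

    @property
    def pct_diff(self) -> float:
        """Signed percent difference; a response of 0 yields -100."""
        return 100.0 * (self.response - self.true_count) / self.true_count


def _validate(responses: Sequence[QuizResponse]) -> None:
    seen: set[tuple[str, str]] = set()
    truth: dict[str, int] = {}
    for r in responses:
        key = (r.respondent_id, r.image_id)
        if key in seen:
            raise ValueError(f"duplicate response for {key}")
        seen.add(key)
        if truth.setdefault(r.image_id, r.true_count) != r.true_count:
            raise ValueError(f"image {r.image_id!r} has inconsistent true_count")


def load_quiz(path: str | Path) -> list[QuizResponse]:
    df = pd.read_csv(path, dtype={"respondent_id": str, "image_id": str})
    missing = [c for c in QUIZ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"quiz CSV {path} missing column(s): {', '.join(missing)}")
    responses = [
        QuizResponse(
            respondent_id=str(row["respondent_id"]),
            experience=str(row["experience"]),
            confidence=str(row["confidence"]),
            image_id=str(row["image_id"]),
            true_count=int(row["true_count"]),
            response=int(row["response"]),
        )
        for row in df[QUIZ_COLUMNS].to_dict("records")
    ]
    _validate(responses)
    return responses


def write_quiz(responses: Iterable[QuizResponse], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in responses], columns=QUIZ_COLUMNS).to_csv(path, index=False)


def _abs_pct_ci(values: np.ndarray, conf: float, method: str, rng: np.random.Generator | None):
    """CI for the mean of |%diff|: Student-t by default, bootstrap optional."""
    n = len(values)
    mean = values.mean()
    if n < 2:
        return np.nan, np.nan
    if method == "t":
        sem = values.std(ddof=1) / np.sqrt(n)
        if sem == 0:
            return mean, mean
        lo, hi = stats.t.interval(conf, df=n - 1, loc=mean, scale=sem)
        return lo, hi
    if method == "bootstrap":
        rng = rng or np.random.default_rng(0)
        boots = rng.choice(values, size=(2000, n), replace=True).mean(axis=1)
        alpha = (1 - conf) / 2
        return tuple(np.quantile(boots, [alpha, 1 - alpha]))
    raise ValueError(f"unknown CI method {method!r}")


def image_error_stats(
    responses: Sequence[QuizResponse],
    conf: float = 0.95,
    ci_method: str = "t",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-image counting-error statistics.

    Returns a frame indexed by image_id with the true count, number of
    responses, mean absolute percent difference with its confidence interval
    (absent for single-response images), the shares of under-, over- and
    exactly-counted responses (which partition to 1), and the mean
    response/truth ratio.
    """
    _validate(responses)
    rows = []
    by_image: dict[str, list[QuizResponse]] = {}
    for r in responses:
        by_image.setdefault(r.image_id, []).append(r)
    for image_id in sorted(by_image):
        rs = by_image[image_id]
        true = rs[0].true_count
        abs_pct = np.array([abs(r.pct_diff) for r in rs])
        ratios = np.array([r.response / r.true_count for r in rs])
        lo, hi = _abs_pct_ci(abs_pct, conf, ci_method, rng)
        n = len(rs)
        rows.append(
            {
                "image_id": image_id,
                "true_count": true,
                "n": n,
                "mean_abs_pct_diff": abs_pct.mean(),
                "ci_low": lo,
                "ci_high": hi,
                "undercount_share": sum(r.response < true for r in rs) / n,
                "overcount_share": sum(r.response > true for r in rs) / n,
                "exact_share": sum(r.response == true for r in rs) / n,
                "mean_ratio": ratios.mean(),
            }
        )
    return pd.DataFrame(rows).set_index("image_id")


def _between_group_stat(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Size-weighted variance of group means of |%diff| around the grand mean."""
    grand = values.mean()
    stat = 0.0
    for g in range(n_groups):
        sel = values[codes == g]
        if len(sel):
            stat += len(sel) * (sel.mean() - grand) ** 2
    return stat / len(values)


@dataclass(frozen=True)
class GroupComparison:
    """Group summaries and a permutation test of equal mean |%diff|."""

    by: str
    stats: pd.DataFrame
    statistic: float
    p_value: float
    n_permutations: int


def group_comparison(
    responses: Sequence[QuizResponse],
    by: str = "experience",
    size_strata: Sequence[tuple[int, int | None]] | None = ((1, 100), (101, None)),
    n_permutations: int = 10_000,
    conf: float = 0.95,
    seed: int | None = None,
) -> GroupComparison:
    """Compare respondent groups on mean absolute percent difference.

    Group means (with t-based CIs) are reported per image-size stratum and
    overall; equality of the overall group means is tested with a two-sided
    permutation test that reshuffles group labels across responses. The test
    statistic is the size-weighted between-group variance of means, which for
    two groups is a monotone function of the absolute mean difference.
    """
    if by not in ("experience", "confidence"):
        raise ValueError(f"unknown grouping {by!r}")
    _validate(responses)
    labels = sorted({getattr(r, by) for r in responses})
    values = np.array([abs(r.pct_diff) for r in responses])
    trues = np.array([r.true_count for r in responses])
    codes = np.array([labels.index(getattr(r, by)) for r in responses])

    rows = []
    strata: list[tuple[str, np.ndarray]] = [("all", np.ones(len(values), bool))]
    for lo, hi in size_strata or ():
        mask = (trues >= lo) & (trues <= (hi if hi is not None else np.inf))
        label = f"{lo}+" if hi is None else f"{lo}-{hi}"
        strata.append((label, mask))
    for g, label in enumerate(labels):
        for sname, mask in strata:
            sel = values[(codes == g) & mask]
            if not len(sel):
                continue
            mean = sel.mean()
            if len(sel) >= 2:
                sem = sel.std(ddof=1) / np.sqrt(len(sel))
                lo_ci, hi_ci = (
                    stats.t.interval(conf, df=len(sel) - 1, loc=mean, scale=sem)
                    if sem > 0
                    else (mean, mean)
                )
            else:
                lo_ci = hi_ci = np.nan
            rows.append(
                {
                    "group": label,
                    "stratum": sname,
                    "n": len(sel),
                    "mean_abs_pct_diff": mean,
                    "ci_low": lo_ci,
                    "ci_high": hi_ci,
                }
            )
    stats_df = pd.DataFrame(rows).set_index(["group", "stratum"])

    observed = _between_group_stat(values, codes, len(labels))
    rng = np.random.default_rng(seed)
    # permuting labels over fixed values == permuting values over fixed labels
    order = np.argsort(rng.random((n_permutations, len(values))), axis=1)
    permuted = values[order]
    grand = values.mean()
    stat = np.zeros(n_permutations)
    for g in range(len(labels)):
        sel = permuted[:, codes == g]
        if sel.shape[1]:
            stat += sel.shape[1] * (sel.mean(axis=1) - grand) ** 2
    stat /= len(values)
    exceed = int((stat >= observed - 1e-12).sum())
    p = (exceed + 1) / (n_permutations + 1)
    return GroupComparison(
        by=by, stats=stats_df, statistic=observed, p_value=p, n_permutations=n_permutations
    )
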