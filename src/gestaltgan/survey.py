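"""Survey-based evaluation statistics.

Human experts answer multiple-choice questions in three categories: spotting
the single original among generated portraits, re-identifying the training
individual behind a latent average, and diagnosing the disorder from a
portrait.  Skipped and timed-out answers are excluded; accuracy in the two
above-chance categories is tested with an exact binomial test against the
chance level (one-sided by default — the hypotheses are directional), and
diagnostic accuracy on real vs. generated portraits is compared with a
Pearson chi-square test (no continuity correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("spot_original", "reidentify_training", "diagnose")


@dataclass
class SurveyRecord:
    """One expert answer."""

    session: str
    category: str
    n_options: int
    answered_correctly: bool | None = None
    skipped: bool = False
    timed_out: bool = False
    stimulus_type: str = "generated"  # original | generated

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.n_options < 2:
            raise ValueError("n_options must be >= 2")
        states = [self.answered_correctly is not None, self.skipped, self.timed_out]
        if sum(states) != 1:
            raise ValueError(
                f"record {self.session!r}/{self.category!r} must be exactly one of "
                "answered / skipped / timed out")
        if self.stimulus_type not in ("original", "generated"):
            raise ValueError(f"unknown stimulus type {self.stimulus_type!r}")

    @property
    def chance_p(self) -> float:
        return 1.0 / self.n_options


def filter_answers(records: list[SurveyRecord]):
    """Drop skipped and timed-out records; return (retained, counts)."""
    retained = [r for r in records if r.answered_correctly is not None]
    n_skip = sum(r.skipped for r in records)
    n_timeout = sum(r.timed_out for r in records)
    counts = {
        "total": len(records),
        "skipped": n_skip,
        "timeouts": n_timeout,
        "retained": len(retained),
    }
    assert counts["retained"] == counts["total"] - n_skip - n_timeout
    return retained, counts


def binomial_test(successes: int, n: int, p0: float, alternative: str = "greater") -> float:
    """Exact binomial tail probability.

    Two-sided p-values sum the point masses of all outcomes no more likely
    than the observed one.
    """
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    if alternative not in ("greater", "two_sided"):
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    alt = "greater" if alternative == "greater" else "two-sided"
    return float(stats.binomtest(successes, n, p0, alternative=alt).pvalue)


def chi_square_test(table, correction: bool = False):
    """Pearson chi-square on a 2x2 contingency table (df = 1).

    No Yates continuity correction by default; pass ``correction=True`` to
    apply it.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), float(res.pvalue)


def survey_summary(records: list[SurveyRecord]) -> pd.DataFrame:
    """Per-category accuracy and significance test on filtered answers.

    spot_original and reidentify_training are tested against their chance
    level with a one-sided exact binomial test; diagnose compares accuracy
    on original vs. generated portraits with a chi-square test (both
    stimulus rows also report their own accuracy).
    """
    retained, counts = filter_answers(records)
    rows = []
    for cat in CATEGORIES:
        recs = [r for r in retained if r.category == cat]
        if not recs:
            rows.append({"category": cat, "n": 0, "accuracy": np.nan,
                         "chance_p": np.nan, "test": "none", "p_value": np.nan,
                         "flag": "empty category"})
            continue
        if cat == "diagnose":
            for stim in ("original", "generated"):
                sub = [r for r in recs if r.stimulus_type == stim]
                acc = float(np.mean([r.answered_correctly for r in sub])) if sub else np.nan
                rows.append({"category": f"{cat}[{stim}]", "n": len(sub),
                             "accuracy": acc, "chance_p": np.mean([r.chance_p for r in sub])
                             if sub else np.nan,
                             "test": "chi_square vs other stimulus", "p_value": np.nan,
                             "flag": ""})
            orig = [r for r in recs if r.stimulus_type == "original"]
            gen = [r for r in recs if r.stimulus_type == "generated"]
            if orig and gen:
                table = [
                    [sum(r.answered_correctly for r in orig),
                     sum(not r.answered_correctly for r in orig)],
                    [sum(r.answered_correctly for r in gen),
                     sum(not r.answered_correctly for r in gen)],
                ]
                _, p = chi_square_test(table)
                rows[-1]["p_value"] = p
                rows[-2]["p_value"] = p
        else:
            k = int(sum(r.answered_correctly for r in recs))
            n = len(recs)
            chance = float(np.mean([r.chance_p for r in recs]))
            p = binomial_test(k, n, chance, alternative="greater")
            rows.append({"category": cat, "n": n, "accuracy": k / n,
                         "chance_p": chance, "test": "binomial greater", "p_value": p,
                         "flag": ""})
    df = pd.DataFrame(rows)
    df.attrs["counts"] = counts
    return df


# ---------------------------------------------------------------------------
# CSV IO: session,category,n_options,outcome{correct|wrong|skip|timeout},stimulus


def read_survey_csv(path) -> list[SurveyRecord]:
    df = pd.read_csv(Path(path))
    records = []
    for _, row in df.iterrows():
        outcome = str(row["outcome"])
        records.append(SurveyRecord(
            session=str(row["session"]),
            category=str(row["category"]),
            n_options=int(row["n_options"]),
            answered_correctly=(outcome == "correct") if outcome in ("correct", "wrong") else None,
            skipped=outcome == "skip",
            timed_out=outcome == "timeout",
            stimulus_type=str(row.get("stimulus", "generated")),
        ))
    return records


def write_survey_csv(records: list[SurveyRecord], path) -> None:
    rows = []
    for r in records:
        outcome = ("correct" if r.answered_correctly else "wrong") \
            if r.answered_correctly is not None else ("skip" if r.skipped else "timeout")
        rows.append({"session": r.session, "category": r.category,
                     "n_options": r.n_options, "outcome": outcome,
                     "stimulus": r.stimulus_type})
    pd.DataFrame(rows).to_csv(Path(path), index=False)
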