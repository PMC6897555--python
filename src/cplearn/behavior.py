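"""Learning-curve classification and categorical-perception statistics.

A subject's 400 categorization trials are summarized as percent correct in
consecutive 20-trial windows. The learning criterion is to reach and then
maintain at least 80% correct through the end of training, with the sustained
run starting at least 60 trials before the end; the first trial of the
earliest qualifying window is the subject's *learning point*. Subjects above
criterion from the very first window are Immediate learners (excluded from
before/after ERP contrasts since they have no "before"); subjects who touch
80% but do not sustain it are Borderline; subjects who never reach 80% in any
window are Non-Learners.

Dissimilarity ratings (1–9 scale, 20 within- and 20 between-category pairs,
rated once before and once after training) yield per-subject categorical
perception statistics:

    diffW     = Wpost − Wpre    (within-category change; compression if < 0)
    diffB     = Bpost − Bpre    (between-category change; separation if > 0)
    global_cp = diffB − diffW   (joint CP index)

Effect sizes for paired contrasts use d = t/sqrt(df+1), i.e. t/sqrt(n) for a
paired t statistic with df = n−1. Spearman correlations are reported with
Fisher-z 95% confidence intervals, z ± 1.96/sqrt(n−3) back-transformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialLog",
    "LearningAssessment",
    "RatingTable",
    "CPStats",
    "EffectSize",
    "CorrelationResult",
    "window_accuracy",
    "classify_learner",
    "block_summaries",
    "cp_stats",
    "cohens_d_from_t",
    "paired_cohens_d",
    "spearman_fisher",
    "split_trials",
]

LEARNING_CRITERION = 0.80
WINDOW_WIDTH = 20
MIN_REMAINING_TRIALS = 60


@dataclass(frozen=True)
class TrialLog:
    """One subject's categorization trial log."""

    subject_id: str
    trials: pd.DataFrame  # columns: trial, stimulus_id, category, response, correct, rt

    def __post_init__(self):
        required = {"trial", "stimulus_id", "category", "response", "correct", "rt"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial log missing columns: {sorted(missing)}")
        t = self.trials["trial"].to_numpy()
        if not np.array_equal(t, np.arange(1, len(t) + 1)):
            raise ValueError("trial indices must be contiguous and 1-based")
        if (self.trials["rt"] <= 0).any():
            raise ValueError("reaction times must be positive")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def correct(self) -> np.ndarray:
        return self.trials["correct"].to_numpy().astype(int)

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path, subject_id: str | None = None) -> "TrialLog":
        df = pd.read_csv(path, sep="\t")
        sid = subject_id if subject_id is not None else str(path)
        return cls(subject_id=sid, trials=df)


@dataclass(frozen=True)
class LearningAssessment:
    subject_id: str
    status: str  # Immediate | Learner | Borderline | NonLearner
    learning_point: int | None
    window_accuracy: tuple

    def __post_init__(self):
        if self.status not in ("Immediate", "Learner", "Borderline", "NonLearner"):
            raise ValueError(f"unknown status {self.status!r}")
        has_lp = self.learning_point is not None
        if has_lp != (self.status in ("Immediate", "Learner")):
            raise ValueError("learning_point defined iff Immediate or Learner")
        if self.status == "Immediate" and self.learning_point != 1:
            raise ValueError("Immediate learners have learning_point 1")


@dataclass(frozen=True)
class RatingTable:
    """Pre/post dissimilarity ratings for one subject (long format)."""

    subject_id: str
    ratings: pd.DataFrame  # columns: pair, pair_type, phase, rating

    def __post_init__(self):
        required = {"pair", "pair_type", "phase", "rating"}
        missing = required - set(self.ratings.columns)
        if missing:
            raise ValueError(f"rating table missing columns: {sorted(missing)}")
        r = self.ratings["rating"]
        if ((r < 1) | (r > 9)).any():
            raise ValueError("ratings must lie in 1..9")

    def to_csv(self, path) -> None:
        self.ratings.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path, subject_id: str | None = None) -> "RatingTable":
        df = pd.read_csv(path, sep="\t")
        sid = subject_id if subject_id is not None else str(path)
        return cls(subject_id=sid, ratings=df)


@dataclass(frozen=True)
class CPStats:
    subject_id: str
    w_pre: float
    w_post: float
    b_pre: float
    b_post: float

    @property
    def diff_w(self) -> float:
        return self.w_post - self.w_pre

    @property
    def diff_b(self) -> float:
        return self.b_post - self.b_pre

    @property
    def global_cp(self) -> float:
        return self.diff_b - self.diff_w


@dataclass(frozen=True)
class EffectSize:
    d: float
    t: float
    df: int
    kind: str = "paired"


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    fisher_z: float
    ci95: tuple
    p: float


def window_accuracy(log: TrialLog, width: int = WINDOW_WIDTH) -> np.ndarray:
    """Percent correct in each consecutive non-overlapping ``width``-trial run."""
    correct = log.correct
    if len(correct) % width != 0:
        raise ValueError(f"n_trials ({len(correct)}) not divisible by width ({width})")
    return correct.reshape(-1, width).mean(axis=1)


def classify_learner(
    acc: Sequence[float],
    subject_id: str = "",
    width: int = WINDOW_WIDTH,
    criterion: float = LEARNING_CRITERION,
    min_remaining_trials: int = MIN_REMAINING_TRIALS,
) -> LearningAssessment:
    """Classify a window-accuracy series against the sustained 80% criterion.

    A subject is a Learner if some window b has accuracy >= criterion in every
    window from b to the end and the sustained run spans at least
    ``min_remaining_trials`` trials; the learning point is the first trial of
    window b. Learners with b = 1 are Immediate. Otherwise the subject is
    Borderline if any single window reached the criterion, else a Non-Learner.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.size == 0:
        raise ValueError("empty accuracy series")
    n_blocks = acc.size
    above = acc >= criterion
    # earliest block from which every later block is above criterion
    sustained_from = None
    for b in range(n_blocks - 1, -1, -1):
        if above[b]:
            sustained_from = b
        else:
            break
    if sustained_from is not None:
        remaining = (n_blocks - sustained_from) * width
        if remaining >= min_remaining_trials:
            lp = sustained_from * width + 1
            status = "Immediate" if sustained_from == 0 else "Learner"
            return LearningAssessment(
                subject_id=subject_id,
                status=status,
                learning_point=lp,
                window_accuracy=tuple(acc),
            )
    status = "Borderline" if above.any() else "NonLearner"
    return LearningAssessment(
        subject_id=subject_id, status=status, learning_point=None,
        window_accuracy=tuple(acc),
    )


def block_summaries(log: TrialLog, block: int = 100) -> pd.DataFrame:
    """Per-100-trial-block accuracy and mean reaction time."""
    n = log.n_trials
    if n % block != 0:
        raise ValueError(f"n_trials ({n}) not divisible by block ({block})")
    df = log.trials.copy()
    df["block"] = (df["trial"] - 1) // block + 1
    out = df.groupby("block").agg(accuracy=("correct", "mean"), mean_rt=("rt", "mean"))
    return out.reset_index()


def cp_stats(table: RatingTable) -> CPStats:
    """Per-subject W/B means per phase and the derived CP statistics."""
    df = table.ratings
    means = {}
    for phase in ("pre", "post"):
        for ptype in ("within", "between"):
            sel = df[(df["phase"] == phase) & (df["pair_type"] == ptype)]["rating"]
            if sel.empty:
                raise ValueError(f"no {ptype} ratings in phase {phase!r}")
            means[(phase, ptype)] = float(sel.mean())
    return CPStats(
        subject_id=table.subject_id,
        w_pre=means[("pre", "within")],
        w_post=means[("post", "within")],
        b_pre=means[("pre", "between")],
        b_post=means[("post", "between")],
    )


def cohens_d_from_t(t: float, df: int, kind: str = "paired") -> EffectSize:
    """Paired-design Cohen's d from a t statistic: d = t / sqrt(df + 1)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return EffectSize(d=t / math.sqrt(df + 1), t=t, df=df, kind=kind)


def paired_cohens_d(x: Sequence[float], y: Sequence[float]) -> EffectSize:
    """Cohen's d for paired samples from the raw data: mean(diff)/sd(diff).

    Identical to ``cohens_d_from_t`` applied to the paired t statistic of the
    same samples, since t = mean(diff)/(sd(diff)/sqrt(n)).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    t = d.mean() / (sd / math.sqrt(n))
    return EffectSize(d=d.mean() / sd, t=float(t), df=n - 1, kind="paired")


def spearman_fisher(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with a Fisher-z 95% confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    z = math.atanh(max(min(rho, 1 - 1e-15), -1 + 1e-15))
    half = 1.96 / math.sqrt(n - 3)
    ci = (math.tanh(z - half), math.tanh(z + half))
    return CorrelationResult(rho=rho, n=n, fisher_z=z, ci95=ci, p=float(p))


def split_trials(
    assessment: LearningAssessment, n_trials: int
) -> tuple[np.ndarray, np.ndarray]:
    """Partition 1-based trial indices into before/after learning sets.

    Learners split at the learning point (before = trials strictly earlier);
    Non-Learners and Borderlines split in half to control for mere-exposure
    effects. Immediate learners have an empty "before" set and are flagged for
    exclusion from before/after ERP contrasts.
    """
    trials = np.arange(1, n_trials + 1)
    if assessment.status == "Immediate":
        raise ValueError(
            "Immediate learners have no before-learning trials; "
            "excluded from before/after contrasts"
        )
    if assessment.status == "Learner":
        cut = assessment.learning_point
    else:
        cut = n_trials // 2 + 1
    return trials[: cut - 1], trials[cut - 1 :]
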