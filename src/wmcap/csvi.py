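"""Capacity estimation from the Compound Stimuli Visual Information task.

A CSVI trial presents a compound stimulus with ``level`` relevant features
(2-8 of 9 trained ones); the participant reports every feature detected, and
the score is the number of correct feature reports.  Under the occupancy
model the number of correct reports at level ``n`` is Bose-Einstein
distributed with ``r`` units of attention.  ``r`` depends on capacity ``k``
and the presentation regime: with long presentation the participant is
assumed to attend ``k`` times (attentional saturation), giving r = k**2;
brief presentations permit a fixed small number ``a`` of attending acts,
giving r = a*k.

Capacity is estimated per participant by exhaustive integer maximum
likelihood over k in 1..9 (9 = number of trainable features).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bose_einstein import BoseEinsteinSpec, be_distribution, be_mean

__all__ = [
    "AttendingActsSpec",
    "SATURATION",
    "CSVIResponseCounts",
    "CapacityEstimate",
    "balls_for_condition",
    "expected_level_means",
    "csvi_log_likelihood",
    "estimate_k",
    "compare_models",
    "LevelFitReport",
    "ratio_analysis",
    "read_csvi_trials",
    "write_csvi_trials",
    "counts_from_trials",
]

EPS_FLOOR = 1e-6  # probability floor for outcomes impossible under the model
K_MAX_DEFAULT = 9


@dataclass(frozen=True)
class AttendingActsSpec:
    """Number of attending acts assumed for a presentation condition.

    mode="saturation": the participant attends k times (r = k**2); the long,
    5-s presentation regime.  mode="fixed": a set number of acts (r = acts*k);
    the brief-presentation regimes use 1, 2 or 3 acts.
    """

    mode: str
    acts: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("saturation", "fixed"):
            raise ValueError(f"mode must be 'saturation' or 'fixed', got {self.mode!r}")
        if self.mode == "fixed":
            if not isinstance(self.acts, (int, np.integer)) or self.acts < 1:
                raise ValueError(f"fixed mode needs acts >= 1, got {self.acts!r}")

    @classmethod
    def parse(cls, text: str) -> "AttendingActsSpec":
        """Parse 'saturation' or 'fixed:N'."""
        if text == "saturation":
            return cls("saturation")
        if text.startswith("fixed:"):
            return cls("fixed", int(text.split(":", 1)[1]))
        raise ValueError(f"cannot parse attending-acts spec {text!r}")

    def label(self) -> str:
        return "saturation" if self.mode == "saturation" else f"fixed:{self.acts}"


SATURATION = AttendingActsSpec("saturation")


def balls_for_condition(k: int, spec: AttendingActsSpec) -> int:
    """Units of attention r available for a stimulus given capacity k."""
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"k must be an integer >= 1, got {k!r}")
    if spec.mode == "saturation":
        return int(k) * int(k)
    return int(spec.acts) * int(k)


def expected_level_means(
    k: int,
    spec: AttendingActsSpec,
    levels,
) -> dict[int, float]:
    """Expected correct reports per trial at each level, E[x] of B-E(n=level, r)."""
    r = balls_for_condition(k, spec)
    return {int(lv): be_mean(BoseEinsteinSpec(int(lv), r)) for lv in levels}


@dataclass
class CSVIResponseCounts:
    """Per-level histograms of number-correct per trial for one participant.

    ``counts[level]`` is an array of length level+1: counts[level][x] trials
    with exactly x correct reports, x = 0..level.
    """

    counts: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty response counts")
        clean: dict[int, np.ndarray] = {}
        for level, arr in self.counts.items():
            level = int(level)
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 1 or arr.shape[0] != level + 1:
                raise ValueError(
                    f"level {level} histogram must have length {level + 1}, got {arr.shape}"
                )
            if (arr < 0).any():
                raise ValueError(f"negative count at level {level}")
            clean[level] = arr
        self.counts = clean

    @property
    def levels(self) -> list[int]:
        return sorted(self.counts)

    @property
    def n_trials(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))

    @classmethod
    def from_trials(cls, levels, n_correct) -> "CSVIResponseCounts":
        """Aggregate per-trial (level, n_correct) pairs into histograms."""
        levels = np.asarray(levels, dtype=np.int64)
        n_correct = np.asarray(n_correct, dtype=np.int64)
        if levels.shape != n_correct.shape or levels.size == 0:
            raise ValueError("levels and n_correct must be equal-length and non-empty")
        counts: dict[int, np.ndarray] = {}
        for lv in np.unique(levels):
            x = n_correct[levels == lv]
            counts[int(lv)] = np.bincount(x, minlength=int(lv) + 1)
        return cls(counts)


@dataclass
class CapacityEstimate:
    """Integer-ML capacity estimate with its likelihood profile."""

    k_hat: int
    log_likelihood: float
    per_level_expected_means: dict[int, float]
    profile: dict[int, float] = field(repr=False)


def _level_log_pmf(level: int, r: int) -> np.ndarray:
    """log pmf over x = 0..level with the epsilon floor applied."""
    dist = be_distribution(BoseEinsteinSpec(level, r))
    p = np.full(level + 1, EPS_FLOOR)
    for x, prob in zip(dist.support, dist.probabilities):
        if x <= level:
            p[x] = max(prob, EPS_FLOOR)
    return np.log(p)


def csvi_log_likelihood(
    counts: CSVIResponseCounts,
    k: int,
    spec: AttendingActsSpec,
) -> float:
    """Log likelihood of the per-level histograms under capacity k.

    Trials are treated as i.i.d. within level and levels as independent;
    outcomes impossible under the model (x = 0, or x beyond min(n, r))
    contribute log(EPS_FLOOR) rather than -inf, so the integer grid search
    stays well defined on real data containing lapses.
    """
    r = balls_for_condition(k, spec)
    total = 0.0
    for level, hist in counts.counts.items():
        total += float(hist @ _level_log_pmf(level, r))
    return total


def estimate_k(
    counts: CSVIResponseCounts,
    spec: AttendingActsSpec,
    k_max: int = K_MAX_DEFAULT,
) -> CapacityEstimate:
    """Exhaustive integer ML over k = 1..k_max; ties broken toward smaller k."""
    profile = {k: csvi_log_likelihood(counts, k, spec) for k in range(1, k_max + 1)}
    k_hat = max(profile, key=lambda k: (profile[k], -k))
    return CapacityEstimate(
        k_hat=k_hat,
        log_likelihood=profile[k_hat],
        per_level_expected_means=expected_level_means(k_hat, spec, counts.levels),
        profile=profile,
    )


@dataclass
class LevelFitReport:
    """Goodness-of-fit of the occupancy and binomial models at one level."""

    level: int
    be_chi2: float
    be_df: int
    be_pvalue: float
    binom_chi2: float
    binom_df: int
    binom_pvalue: float
    binom_p_hat: float
    degenerate: bool


def _merge_cells(observed: np.ndarray, expected: np.ndarray):
    """Merge adjacent low-expectation cells from both tails until all >= 5."""
    obs = list(observed.astype(float))
    exp_ = list(expected.astype(float))
    # merge upward from the left, then downward from the right
    i = 0
    while i < len(exp_) - 1:
        if exp_[i] < 5:
            exp_[i + 1] += exp_[i]
            obs[i + 1] += obs[i]
            del exp_[i], obs[i]
        else:
            i += 1
    while len(exp_) > 1 and exp_[-1] < 5:
        exp_[-2] += exp_[-1]
        obs[-2] += obs[-1]
        del exp_[-1], obs[-1]
    return np.array(obs), np.array(exp_)


def compare_models(
    counts: CSVIResponseCounts,
    k_hat: int,
    spec: AttendingActsSpec,
) -> dict[int, LevelFitReport]:
    """Pearson chi-square fit of the occupancy model vs a binomial alternative.

    Intended for data pooled across participants at each level.  The
    occupancy expectation uses the supplied k and attending-acts regime
    (d.f. = cells - 1, k fixed externally); the binomial alternative is
    Binomial(n=level, p_hat) with the per-level MLE p_hat = total correct /
    (level * trials) (d.f. = cells - 2).  Cells with expected count < 5 are
    merged from the tails; a level that collapses to fewer than two cells is
    reported as degenerate.
    """
    r = balls_for_condition(k_hat, spec)
    reports: dict[int, LevelFitReport] = {}
    for level, hist in counts.counts.items():
        n_trials = int(hist.sum())
        x = np.arange(level + 1)
        be_p = np.exp(_level_log_pmf(level, r))
        be_p = be_p / be_p.sum()
        p_hat = float((hist @ x) / (level * n_trials)) if n_trials else 0.0
        binom_p = stats.binom.pmf(x, level, p_hat)

        def _chi2(model_p: np.ndarray):
            obs, exp_ = _merge_cells(hist, n_trials * model_p)
            if len(obs) < 2:
                return math.nan, 0, math.nan, True
            stat = float(((obs - exp_) ** 2 / exp_).sum())
            return stat, len(obs) - 1, math.nan, False

        be_stat, be_cells_m1, _, be_degen = _chi2(be_p)
        bi_stat, bi_cells_m1, _, bi_degen = _chi2(binom_p)
        be_df = be_cells_m1
        binom_df = max(bi_cells_m1 - 1, 0)  # p_hat estimated from the data
        degenerate = be_degen or bi_degen or be_df < 1 or binom_df < 1
        reports[level] = LevelFitReport(
            level=level,
            be_chi2=be_stat,
            be_df=be_df,
            be_pvalue=float(stats.chi2.sf(be_stat, be_df)) if not degenerate else math.nan,
            binom_chi2=bi_stat,
            binom_df=binom_df,
            binom_pvalue=(
                float(stats.chi2.sf(bi_stat, binom_df)) if not degenerate else math.nan
            ),
            binom_p_hat=p_hat,
            degenerate=degenerate,
        )
    return reports


def ratio_analysis(
    observed_long: dict[int, float],
    observed_short: dict[int, float],
    expected_long: dict[int, float],
    expected_short: dict[int, float],
) -> dict:
    """Short/long ratios per level and their observed-vs-expected correlation.

    The short-to-long ratio of mean correct reports falls with level, and the
    occupancy model predicts the shape of that decline; the Pearson
    correlation between observed and model-expected ratio vectors quantifies
    the agreement.
    """
    levels = sorted(observed_long)
    for other in (observed_short, expected_long, expected_short):
        if sorted(other) != levels:
            raise ValueError("all four inputs must cover the same level set")
    for lv in levels:
        if observed_long[lv] <= 0 or expected_long[lv] <= 0:
            raise ValueError(f"non-positive long-condition mean at level {lv}")
    obs_ratios = {lv: observed_short[lv] / observed_long[lv] for lv in levels}
    exp_ratios = {lv: expected_short[lv] / expected_long[lv] for lv in levels}
    obs = np.array([obs_ratios[lv] for lv in levels])
    exp_ = np.array([exp_ratios[lv] for lv in levels])
    r, _ = stats.pearsonr(obs, exp_)
    return {"obs_ratios": obs_ratios, "exp_ratios": exp_ratios, "pearson_r": float(r)}


# --- trial CSV dialect: participant_id, condition, level, n_correct -----------

CSVI_COLUMNS = ["participant_id", "condition", "level", "n_correct"]


def read_csvi_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CSVI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSVI trial file missing columns {missing}")
    return df


def write_csvi_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=CSVI_COLUMNS)


def counts_from_trials(
    df: pd.DataFrame,
    condition: str | None = None,
    pool_participants: bool = False,
):
    """Aggregate a trial table to CSVIResponseCounts.

    Returns {participant_id: CSVIResponseCounts}, or a single pooled
    CSVIResponseCounts when ``pool_participants`` is set.
    """
    if condition is not None:
        df = df[df["condition"] == condition]
    if df.empty:
        raise ValueError("no trials after filtering")
    if pool_participants:
        return CSVIResponseCounts.from_trials(df["level"], df["n_correct"])
    return {
        pid: CSVIResponseCounts.from_trials(sub["level"], sub["n_correct"])
        for pid, sub in df.groupby("participant_id")
    }
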