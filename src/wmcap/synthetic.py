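"""Synthetic cohorts emulating the study designs.

Generates trial tables in the same CSV dialects the estimators consume, so
every stage of the pipeline is testable without the deposited data:

* CSVI cohorts — integer capacities drawn from a rounded truncated normal on
  [1, 9] (population mean 6.5, s.d. 1.5 by default, matching adult samples);
  per-trial correct-report counts drawn from the occupancy model with the
  condition's attending-acts regime.
* VAT cohorts — continuous capacities from a truncated normal (>= 1), z and
  g from truncated normals on [0, 1]; per-trial change flag Bernoulli(0.5)
  and responses drawn from the three-parameter model's hit / false-alarm
  probabilities.

Presets mirror the designs of the five experiments: CSVI with 8 trials per
level 2-8 and long (saturation) vs brief (1-3 attending acts) conditions;
VAT with 80 trials per set size (6/8/10/12 for adults, 3/6/8/10 for
adolescents) in short and long presentation conditions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .bose_einstein import BoseEinsteinSpec, be_sample
from .csvi import AttendingActsSpec, balls_for_condition

__all__ = [
    "CSVICondition",
    "VATCondition",
    "ScenarioSpec",
    "simulate_csvi_cohort",
    "simulate_vat_cohort",
    "scenario_presets",
    "PRESET_NAMES",
]

LEVELS = tuple(range(2, 9))


@dataclass(frozen=True)
class CSVICondition:
    label: str
    acts: AttendingActsSpec


@dataclass(frozen=True)
class VATCondition:
    label: str
    set_sizes: tuple[int, ...]
    trials_per_size: int

    def __post_init__(self) -> None:
        if self.trials_per_size < 1:
            raise ValueError("trials_per_size must be >= 1")
        if not self.set_sizes or any(n < 1 for n in self.set_sizes):
            raise ValueError("set sizes must be positive")


@dataclass
class ScenarioSpec:
    """One simulated study: task, conditions, cohort, parameter populations."""

    task: str
    conditions: list
    n_participants: int
    seed: int = 0
    # CSVI design/population
    levels: tuple[int, ...] = LEVELS
    trials_per_level: int = 8
    k_mean: float = 6.5
    k_sd: float = 1.5
    k_range: tuple[int, int] = (1, 9)
    # VAT population
    k_lower: float = 1.0
    z_mean: float = 0.94
    z_sd: float = 0.03
    g_mean: float = 0.48
    g_sd: float = 0.13

    def __post_init__(self) -> None:
        if self.task not in ("csvi", "vat"):
            raise ValueError(f"task must be 'csvi' or 'vat', got {self.task!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition required")
        want = CSVICondition if self.task == "csvi" else VATCondition
        if not all(isinstance(c, want) for c in self.conditions):
            raise ValueError(f"{self.task} scenario requires {want.__name__} conditions")
        if self.task == "csvi":
            if self.trials_per_level < 1:
                raise ValueError("trials_per_level must be >= 1")
            lo, hi = self.k_range
            if not 1 <= lo <= hi:
                raise ValueError("invalid k_range")
        if self.k_sd <= 0 or self.z_sd < 0 or self.g_sd < 0:
            raise ValueError("dispersion parameters must be positive")

    def to_yaml(self) -> str:
        payload = asdict(self)
        payload["conditions"] = [
            (
                {"label": c.label, "acts": c.acts.label()}
                if self.task == "csvi"
                else {
                    "label": c.label,
                    "set_sizes": list(c.set_sizes),
                    "trials_per_size": c.trials_per_size,
                }
            )
            for c in self.conditions
        ]
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioSpec":
        payload = yaml.safe_load(text)
        raw_conditions = payload.pop("conditions")
        if payload.get("task") == "csvi":
            conditions = [
                CSVICondition(c["label"], AttendingActsSpec.parse(c["acts"]))
                for c in raw_conditions
            ]
        else:
            conditions = [
                VATCondition(c["label"], tuple(c["set_sizes"]), c["trials_per_size"])
                for c in raw_conditions
            ]
        for key in ("levels", "k_range"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(conditions=conditions, **payload)


def _truncated_normal(rng, mean, sd, lower, upper, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lower, upper)))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return dist.ppf(rng.random(size))


def simulate_csvi_cohort(spec: ScenarioSpec, rng=None):
    """Simulate CSVI trials; returns (trial DataFrame, truth DataFrame).

    Capacities are integer draws (rounded truncated normal on k_range); each
    trial's correct-report count is an occupancy-model draw with
    n = level and r set by the condition's attending-acts regime.
    """
    if spec.task != "csvi":
        raise ValueError("scenario task must be 'csvi'")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lo, hi = spec.k_range
    k_true = np.clip(
        np.rint(_truncated_normal(rng, spec.k_mean, spec.k_sd, lo - 0.5, hi + 0.5, spec.n_participants)),
        lo,
        hi,
    ).astype(int)
    records = []
    for i in range(spec.n_participants):
        pid = f"p{i + 1:03d}"
        for cond in spec.conditions:
            r = balls_for_condition(int(k_true[i]), cond.acts)
            for level in spec.levels:
                draws = be_sample(
                    BoseEinsteinSpec(int(level), r), rng, size=spec.trials_per_level
                )
                records.extend(
                    (pid, cond.label, int(level), int(x)) for x in draws
                )
    trials = pd.DataFrame(
        records, columns=["participant_id", "condition", "level", "n_correct"]
    )
    truth = pd.DataFrame(
        {
            "participant_id": [f"p{i + 1:03d}" for i in range(spec.n_participants)],
            "k_true": k_true,
        }
    )
    return trials, truth


def simulate_vat_cohort(spec: ScenarioSpec, rng=None):
    """Simulate VAT trials; returns (trial DataFrame, truth DataFrame).

    Per condition, each participant gets (k, z, g) drawn from the scenario's
    truncated-normal populations; change trials occur with probability .5 and
    the response follows the model's hit / false-alarm probabilities.
    """
    if spec.task != "vat":
        raise ValueError("scenario task must be 'vat'")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    P = spec.n_participants
    pids = [f"p{i + 1:03d}" for i in range(P)]
    records = []
    truth_rows = []
    for cond in spec.conditions:
        k_true = _truncated_normal(rng, spec.k_mean, spec.k_sd, spec.k_lower, np.inf, P)
        z_true = _truncated_normal(rng, spec.z_mean, spec.z_sd, 0.0, 1.0, P)
        g_true = _truncated_normal(rng, spec.g_mean, spec.g_sd, 0.0, 1.0, P)
        for i, pid in enumerate(pids):
            truth_rows.append((pid, cond.label, k_true[i], z_true[i], g_true[i]))
            for n in cond.set_sizes:
                m = min(k_true[i], n) / n
                p_hit = z_true[i] * (m + (1 - m) * g_true[i]) + (1 - z_true[i]) * g_true[i]
                p_fa = z_true[i] * (1 - m) * g_true[i] + (1 - z_true[i]) * g_true[i]
                t = cond.trials_per_size
                is_change = (rng.random(t) < 0.5).astype(int)
                p = np.where(is_change == 1, p_hit, p_fa)
                resp = (rng.random(t) < p).astype(int)
                records.extend(
                    (pid, cond.label, int(n), int(ch), int(rc))
                    for ch, rc in zip(is_change, resp)
                )
    trials = pd.DataFrame(
        records,
        columns=["participant_id", "condition", "set_size", "is_change", "response_change"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["participant_id", "condition", "k_true", "z_true", "g_true"]
    )
    return trials, truth


PRESET_NAMES = ("exp1a", "exp1b", "exp1c", "exp2", "exp3")


def scenario_presets(name: str, seed: int = 0) -> ScenarioSpec:
    """Design constants of the five experiments with default populations.

    CSVI presets: 20 adults, 8 trials per level 2-8, long (saturation) plus
    a brief condition with 2 / 1 / 3 attending acts; capacity population
    mean 6.5, s.d. 1.5 on integers 1-9.  VAT presets: short-presentation
    populations from the reported short-condition estimates (adults:
    k ~ 5.6 +/- 0.7, z ~ 0.81, g ~ 0.40; adolescents: k ~ 4.4 +/- 0.6,
    z ~ 0.94, g ~ 0.48), 80 trials per set size.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; valid: {', '.join(PRESET_NAMES)}")
    if name.startswith("exp1"):
        acts = {"exp1a": 2, "exp1b": 1, "exp1c": 3}[name]
        return ScenarioSpec(
            task="csvi",
            conditions=[
                CSVICondition("long", AttendingActsSpec("saturation")),
                CSVICondition("short", AttendingActsSpec("fixed", acts)),
            ],
            n_participants=20,
            trials_per_level=8,
            k_mean=6.5,
            k_sd=1.5,
            seed=seed,
        )
    if name == "exp2":
        return ScenarioSpec(
            task="vat",
            conditions=[
                VATCondition("short", (6, 8, 10, 12), 80),
                VATCondition("long", (6, 8, 10, 12), 80),
            ],
            n_participants=50,
            k_mean=5.6,
            k_sd=0.71,
            z_mean=0.81,
            z_sd=0.08,
            g_mean=0.40,
            g_sd=0.13,
            seed=seed,
        )
    return ScenarioSpec(
        task="vat",
        conditions=[
            VATCondition("short", (3, 6, 8, 10), 80),
            VATCondition("long", (3, 6, 8, 10), 80),
        ],
        n_participants=24,
        k_mean=4.4,
        k_sd=0.6,
        z_mean=0.94,
        z_sd=0.03,
        g_mean=0.48,
        g_sd=0.13,
        seed=seed,
    )
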