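"""Synthetic patient-cohort generator.

Stands in for the private 600-patient record database: reproduces the
published demographic grid (treatment method x sex x age band) exactly, and
draws per-patient operation sequences from a simple per-method generative
model — a primary intervention (two-stage methods: spacer installation
followed after a configurable delay by the second-stage exchange), monthly
competing relapse/death Bernoulli events (relapse evaluated first), optional
unrelated surgeries, category-level operation cost distributions, and
per-interval utility increments.  All randomness flows through one seeded
generator, so a config (including its seed) maps to one byte-identical
cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping

import numpy as np

from .records import (
    Cohort,
    OperationCategory,
    OperationEvent,
    PatientRecord,
    SECOND_STAGE_LABEL,
    SPACER_INSTALLING_LABELS,
    TreatmentMethod,
    classify_operation,
    validate_record,
)

__all__ = [
    "ConfigError",
    "MethodParams",
    "CohortConfig",
    "STUDY_DEMOGRAPHIC_GRID",
    "AGE_BANDS",
    "EXCLUDED_GROUP_LABEL",
    "age_band",
    "grid_label",
    "sample_operation_sequence",
    "generate_cohort",
    "cohort_marginals",
]


class ConfigError(ValueError):
    """Invalid cohort configuration."""


AGE_BANDS = ("<20", "21-30", "31-40", "41-50", "51-60", "61-70", "71-80", "81-90", ">90")

_BAND_RANGES = {
    "<20": (5.0, 20.0),
    "21-30": (21.0, 31.0),
    "31-40": (31.0, 41.0),
    "41-50": (41.0, 51.0),
    "51-60": (51.0, 61.0),
    "61-70": (61.0, 71.0),
    "71-80": (71.0, 81.0),
    "81-90": (81.0, 91.0),
    ">90": (91.0, 100.0),
}


def age_band(age_years: float) -> str:
    """Band of a (completed-years) age; bands are closed integer ranges."""
    a = int(age_years)
    if a < 21:
        return "<20"
    if a > 90:
        return ">90"
    for band in AGE_BANDS[1:-1]:
        lo, hi = _BAND_RANGES[band]
        if lo <= a < hi:
            return band
    return ">90"


#: Row label for the historical one-stage retrospective group: present in the
#: demographic grid (3 patients) but excluded from every analysis.
EXCLUDED_GROUP_LABEL = "1-stage-retro"

# Published demographic grid: (row label, sex) -> counts per age band.
_GRID_ROWS: dict[tuple[str, str], tuple[int, ...]] = {
    # bands:              <20 21-30 31-40 41-50 51-60 61-70 71-80 81-90 >90
    ("2-stage>2mth", "M"): (0, 3, 20, 33, 59, 50, 26, 5, 0),
    ("2-stage>2mth", "F"): (1, 2, 17, 17, 46, 46, 36, 6, 0),
    (EXCLUDED_GROUP_LABEL, "M"): (0, 0, 0, 0, 0, 0, 0, 1, 0),
    (EXCLUDED_GROUP_LABEL, "F"): (0, 0, 0, 0, 0, 0, 1, 1, 0),
    ("2-stage-2-3wk", "M"): (0, 0, 2, 4, 1, 3, 1, 0, 0),
    ("2-stage-2-3wk", "F"): (0, 0, 0, 0, 1, 1, 1, 0, 0),
    ("2-stage-6-8wk", "M"): (0, 0, 8, 8, 9, 6, 0, 1, 0),
    ("2-stage-6-8wk", "F"): (0, 0, 0, 2, 5, 10, 2, 0, 0),
    ("1-stage", "M"): (0, 0, 1, 4, 4, 11, 9, 3, 1),
    ("1-stage", "F"): (0, 0, 0, 1, 6, 14, 13, 11, 0),
    ("RA", "M"): (0, 0, 0, 1, 2, 4, 0, 1, 0),
    ("RA", "F"): (0, 0, 0, 1, 0, 2, 2, 0, 0),
    ("re-THR-PE", "M"): (0, 1, 4, 2, 5, 3, 3, 2, 0),
    ("re-THR-PE", "F"): (0, 0, 1, 3, 10, 9, 8, 0, 0),
    ("Partial-I", "M"): (0, 0, 0, 0, 0, 0, 0, 0, 0),
    ("Partial-I", "F"): (0, 0, 1, 1, 3, 2, 1, 3, 0),
    ("Partial-II", "M"): (0, 0, 2, 3, 0, 0, 2, 0, 0),
    ("Partial-II", "F"): (0, 0, 1, 2, 0, 2, 0, 0, 0),
}

#: Default demographic grid: (row label, sex, age band) -> patient count.
STUDY_DEMOGRAPHIC_GRID: dict[tuple[str, str, str], int] = {
    (label, sex, band): n
    for (label, sex), counts in _GRID_ROWS.items()
    for band, n in zip(AGE_BANDS, counts)
    if n > 0
}


def grid_label(method: TreatmentMethod, cohort: Cohort) -> str:
    """Demographic-grid row label for a record's method/cohort pair."""
    if method is TreatmentMethod.ONE_STAGE and cohort is Cohort.RETROSPECTIVE:
        return EXCLUDED_GROUP_LABEL
    return method.label


def _resolve_label(label: str) -> tuple[TreatmentMethod, Cohort]:
    if label == EXCLUDED_GROUP_LABEL:
        return TreatmentMethod.ONE_STAGE, Cohort.RETROSPECTIVE
    m = TreatmentMethod.from_label(label)
    return m, m.cohort


@dataclass(frozen=True)
class MethodParams:
    """Generative parameters of one treatment method's disease course."""

    primary_op_label: str
    second_stage_delay_mean: float | None = None  # months; None = not two-stage
    second_stage_delay_sd: float = 0.5
    relapse_prob_per_month: float = 0.02
    death_hazard_per_month: float = 0.004
    non_pji_op_prob_per_month: float = 0.004
    relapse_resolution_prob: float = 0.7
    relapse_op_label: str = "Debridement"

    def validate(self) -> None:
        for name in (
            "relapse_prob_per_month",
            "non_pji_op_prob_per_month",
            "relapse_resolution_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.death_hazard_per_month < 0:
            raise ConfigError("death hazard must be >= 0")
        if self.second_stage_delay_mean is not None and self.second_stage_delay_mean <= 0:
            raise ConfigError("second-stage delay must be positive")
        classify_operation(self.primary_op_label)
        classify_operation(self.relapse_op_label)


def _default_method_params() -> dict[str, MethodParams]:
    two_stage = dict(
        primary_op_label="Debridement + spacer installation",
        relapse_op_label="Debridement + spacer reinstallation",
    )
    return {
        "re-THR-PE": MethodParams(
            primary_op_label="EP components replacement + debridement",
            relapse_prob_per_month=0.03,
        ),
        "2-stage>2mth": MethodParams(**two_stage, second_stage_delay_mean=3.5,
                                     second_stage_delay_sd=1.0),
        "2-stage-2-3wk": MethodParams(**two_stage, second_stage_delay_mean=0.7,
                                      second_stage_delay_sd=0.2),
        "2-stage-6-8wk": MethodParams(**two_stage, second_stage_delay_mean=1.6,
                                      second_stage_delay_sd=0.3),
        "1-stage": MethodParams(primary_op_label="Debridement + full EP replacement"),
        EXCLUDED_GROUP_LABEL: MethodParams(
            primary_op_label="Debridement + full EP replacement"
        ),
        "RA": MethodParams(primary_op_label="Debridement",
                           relapse_prob_per_month=0.01),
        "Partial-I": MethodParams(
            primary_op_label="EP components replacement + debridement"
        ),
        "Partial-II": MethodParams(**two_stage, second_stage_delay_mean=3.0,
                                   second_stage_delay_sd=0.8),
    }


# Operation cost distributions (rubles) by generalized category: mean and
# coefficient of variation of a clipped-normal draw.
_DEFAULT_COST_PARAMS: dict[str, tuple[float, float]] = {
    "pji": (90_000.0, 0.25),
    "second_stage": (130_000.0, 0.2),
    "non_pji": (35_000.0, 0.3),
}


@dataclass
class CohortConfig:
    """Full configuration of a synthetic cohort (a pure function of which,
    including the seed, the generated records are)."""

    demographic_counts: dict[tuple[str, str, str], int] = field(
        default_factory=lambda: dict(STUDY_DEMOGRAPHIC_GRID)
    )
    method_params: dict[str, MethodParams] = field(default_factory=_default_method_params)
    cost_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COST_PARAMS)
    )
    utility_weight_mean: float = 0.6   # health-state weight behind interval QALY draws
    utility_weight_sd: float = 0.1
    horizon_months: int = 36
    manifestation_windows: dict[Cohort, tuple[date, date]] = field(
        default_factory=lambda: {
            Cohort.RETROSPECTIVE: (date(2005, 1, 1), date(2015, 12, 31)),
            Cohort.PROSPECTIVE: (date(2016, 1, 1), date(2017, 12, 31)),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.horizon_months < 1:
            raise ConfigError("horizon_months must be a positive integer")
        for key, n in self.demographic_counts.items():
            label, sex, band = key
            if n < 0:
                raise ConfigError(f"negative count for {key}")
            if sex not in ("M", "F"):
                raise ConfigError(f"bad sex in grid key {key}")
            if band not in AGE_BANDS:
                raise ConfigError(f"unknown age band in grid key {key}")
            _resolve_label(label)
            if label not in self.method_params:
                raise ConfigError(f"no generative parameters for method {label!r}")
        for params in self.method_params.values():
            params.validate()
        for cat, (mean, cv) in self.cost_params.items():
            if mean < 0 or cv < 0:
                raise ConfigError(f"cost parameters for {cat!r} must be non-negative")
        if not 0 <= self.utility_weight_mean <= 1:
            raise ConfigError("utility_weight_mean must be in [0, 1]")

    def to_dict(self) -> dict:
        """Plain-data form of the config (YAML/JSON serializable)."""
        return {
            "demographic_counts": {
                f"{l}|{s}|{b}": n for (l, s, b), n in self.demographic_counts.items()
            },
            "method_params": {
                label: dataclasses.asdict(p) for label, p in self.method_params.items()
            },
            "cost_params": {k: list(v) for k, v in self.cost_params.items()},
            "utility_weight_mean": self.utility_weight_mean,
            "utility_weight_sd": self.utility_weight_sd,
            "horizon_months": self.horizon_months,
            "manifestation_windows": {
                c.value: [a.isoformat(), b.isoformat()]
                for c, (a, b) in self.manifestation_windows.items()
            },
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        cfg = cls()
        if "demographic_counts" in data:
            counts = {}
            for key, n in data["demographic_counts"].items():
                label, sex, band = key.split("|")
                counts[(label, sex, band)] = int(n)
            cfg.demographic_counts = counts
        if "method_params" in data:
            cfg.method_params = {
                label: MethodParams(**p) for label, p in data["method_params"].items()
            }
        if "cost_params" in data:
            cfg.cost_params = {k: tuple(v) for k, v in data["cost_params"].items()}
        for name in ("utility_weight_mean", "utility_weight_sd", "horizon_months", "seed"):
            if name in data:
                setattr(cfg, name, data[name])
        if "manifestation_windows" in data:
            cfg.manifestation_windows = {
                Cohort(c): (date.fromisoformat(a), date.fromisoformat(b))
                for c, (a, b) in data["manifestation_windows"].items()
            }
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, source) -> "CohortConfig":
        """Load a config from a YAML path or stream."""
        import yaml

        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data or {})


def _cost_category(label: str) -> str:
    op = classify_operation(label)
    if op.is_second_stage:
        return "second_stage"
    if op.category is OperationCategory.NO_PJI:
        return "non_pji"
    return "pji"


def sample_operation_sequence(
    method: TreatmentMethod,
    params: MethodParams,
    rng: np.random.Generator,
    manifestation_date: date = date(2016, 1, 1),
    horizon_months: int = 36,
    cost_params: Mapping[str, tuple[float, float]] | None = None,
    utility_weight: tuple[float, float] = (0.6, 0.1),
) -> dict:
    """Draw one patient's operation sequence and outcome fields.

    Month-by-month simulation: the primary intervention happens in month 0;
    from month 1 on, a scheduled second stage (if due and no active PJI),
    then relapse, an unrelated operation, and death are evaluated in that
    order.  Death terminates the sequence; at most 10 operations are
    recorded.  Returns a dict with ``operations``, ``last_status``,
    ``death_date``, ``censor_date`` and ``utility_increments``.
    """
    params.validate()
    cost_params = dict(cost_params or _DEFAULT_COST_PARAMS)

    def draw_cost(label: str) -> float:
        mean, cv = cost_params[_cost_category(label)]
        return float(max(0.0, rng.normal(mean, mean * cv)))

    ops: list[OperationEvent] = []
    utils: list[float] = []
    last_event_day = 0

    def add_op(label: str, day: int) -> None:
        nonlocal last_event_day
        day = max(day, last_event_day + 1)
        d = manifestation_date + timedelta(days=day)
        ops.append(OperationEvent(d, classify_operation(label), draw_cost(label)))
        # QALY gained over the interval ending at this operation
        w = float(np.clip(rng.normal(*utility_weight), 0.0, 1.0))
        utils.append((day - last_event_day) / 365.25 * w)
        last_event_day = day

    def delay_months() -> int:
        d = rng.normal(params.second_stage_delay_mean, params.second_stage_delay_sd)
        return max(1, int(round(d)))

    # month 0: primary intervention
    add_op(params.primary_op_label, int(rng.integers(3, 28)))
    pending_second: int | None = None
    if params.primary_op_label in SPACER_INSTALLING_LABELS:
        pending_second = delay_months()
    pji_active = False  # PJI present and untreated (failed course)
    death_date: date | None = None

    for m in range(1, horizon_months):
        day_cursor = 30 * m + int(rng.integers(1, 10))
        if (
            pending_second is not None
            and m >= pending_second
            and not pji_active
            and len(ops) < 10
        ):
            add_op(SECOND_STAGE_LABEL, day_cursor)
            day_cursor = last_event_day + int(rng.integers(1, 8))
            pending_second = None
        if not pji_active and rng.random() < params.relapse_prob_per_month:
            if len(ops) < 10:
                add_op(params.relapse_op_label, day_cursor)
                day_cursor = last_event_day + int(rng.integers(1, 8))
                if params.relapse_op_label in SPACER_INSTALLING_LABELS:
                    pending_second = m + delay_months()
                elif rng.random() >= params.relapse_resolution_prob:
                    pji_active = True
            else:
                pji_active = True
        if (
            not pji_active
            and len(ops) < 10
            and rng.random() < params.non_pji_op_prob_per_month
        ):
            add_op("Other: (suturing, etc.)", day_cursor)
        if rng.random() < params.death_hazard_per_month:
            death_day = max(30 * m + int(rng.integers(10, 30)), last_event_day + 1)
            death_date = manifestation_date + timedelta(days=death_day)
            break

    # a spacer still in place means the course is unfinished but PJI-free
    last_status = "PJI_PRESENT" if pji_active else "NO_PJI"
    censor_date = manifestation_date + timedelta(days=30 * horizon_months)
    if death_date is not None and death_date > censor_date:
        censor_date = death_date
    return {
        "operations": tuple(ops),
        "utility_increments": tuple(utils),
        "last_status": last_status,
        "death_date": death_date,
        "censor_date": censor_date,
    }


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate a validated synthetic cohort reproducing the demographic grid
    exactly; deterministic in the config (including the seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    counter = 0
    for key in sorted(config.demographic_counts):
        label, sex, band = key
        method, cohort = _resolve_label(label)
        lo, hi = _BAND_RANGES[band]
        w_start, w_end = config.manifestation_windows[cohort]
        window_days = (w_end - w_start).days
        for _ in range(config.demographic_counts[key]):
            counter += 1
            manifestation = w_start + timedelta(days=int(rng.integers(0, window_days + 1)))
            # keep clear of band edges so the rounding through a birthdate
            # cannot shift the recovered age into a neighboring band
            age = float(rng.uniform(lo + 0.05, hi - 0.05))
            birth = manifestation - timedelta(days=int(age * 365.25))
            drawn = sample_operation_sequence(
                method,
                config.method_params[label],
                rng,
                manifestation_date=manifestation,
                horizon_months=config.horizon_months,
                cost_params=config.cost_params,
                utility_weight=(config.utility_weight_mean, config.utility_weight_sd),
            )
            record = PatientRecord(
                id=f"P{counter:04d}",
                birthdate=birth,
                sex=sex,
                method=method,
                manifestation_date=manifestation,
                cohort=cohort,
                **drawn,
            )
            violations = validate_record(record)
            if violations:  # pragma: no cover - generator contract
                raise RuntimeError(f"generator produced invalid record: {violations}")
            records.append(record)
    return records


def cohort_marginals(records) -> dict[tuple[str, str, str], int]:
    """Observed (grid label, sex, age band) counts of a record collection."""
    out: dict[tuple[str, str, str], int] = {}
    for r in records:
        key = (grid_label(r.method, r.cohort), r.sex, age_band(r.age_at_manifestation))
        out[key] = out.get(key, 0) + 1
    return out
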