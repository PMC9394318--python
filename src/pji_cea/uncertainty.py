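"""Subsample-bootstrap confidence intervals for record-set estimators.

Uncertainty in every estimated probability or cost comes from one mechanism:
draw ``n`` random subsamples of the record database (by default 10 subsamples
of 80%, without replacement), re-run the estimator on each, and form the
Student-t interval

    x̄ ± t_{α/2, n−1} · S / √n

over the ``n`` re-estimates, where ``S`` is their sample standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = ["IntervalEstimate", "t_interval", "subsample_estimates", "subsample_ci"]


@dataclass(frozen=True)
class IntervalEstimate:
    mean: float
    sd: float
    n: int
    alpha: float
    lower: float
    upper: float

    @property
    def half_width(self) -> float:
        return (self.upper - self.lower) / 2.0


def t_interval(
    values: Sequence[float], alpha: float = 0.05, clip: tuple[float, float] | None = None
) -> IntervalEstimate:
    """Student-t interval over re-estimates; ``clip`` bounds the interval
    (e.g. ``(0, 1)`` for probabilities, whose t-interval can overshoot)."""
    x = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 estimates for a t-interval, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(stats.t.ppf(1 - alpha / 2, n - 1)) * sd / math.sqrt(n)
    lower, upper = mean - half, mean + half
    if clip is not None:
        lower = min(max(lower, clip[0]), clip[1])
        upper = min(max(upper, clip[0]), clip[1])
        mean_c = min(max(mean, clip[0]), clip[1])
        lower, upper = min(lower, mean_c), max(upper, mean_c)
    return IntervalEstimate(mean=mean, sd=sd, n=n, alpha=alpha, lower=lower, upper=upper)


class SubsampleEstimatorError(RuntimeError):
    """Estimator failure on a particular subsample."""


def subsample_estimates(
    records: Sequence,
    estimator: Callable[[list], float],
    n_subsamples: int = 10,
    fraction: float = 0.8,
    rng: np.random.Generator | int | None = None,
    replace: bool = False,
) -> list[float]:
    """Apply ``estimator`` to ``n_subsamples`` random subsets of the records.

    Subsets have size ``floor(fraction * N)`` and are drawn without
    replacement by default (m-out-of-n subsampling); ``replace=True`` gives
    the classical bootstrap variant.
    """
    if n_subsamples < 2:
        raise ValueError("n_subsamples must be >= 2 (sample sd is undefined otherwise)")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    rng = np.random.default_rng(rng)
    m = max(1, int(math.floor(fraction * len(records))))
    out: list[float] = []
    for k in range(n_subsamples):
        idx = rng.choice(len(records), size=m, replace=replace)
        subset = [records[i] for i in idx]
        try:
            out.append(float(estimator(subset)))
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise SubsampleEstimatorError(
                f"estimator failed on subsample {k}: {exc}"
            ) from exc
    return out


def subsample_ci(
    records: Sequence,
    estimator: Callable[[list], float],
    n_subsamples: int = 10,
    fraction: float = 0.8,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    replace: bool = False,
    clip: tuple[float, float] | None = None,
) -> IntervalEstimate:
    """Subsample-bootstrap t-interval for a scalar record-set estimator."""
    values = subsample_estimates(
        records, estimator, n_subsamples=n_subsamples, fraction=fraction, rng=rng, replace=replace
    )
    return t_interval(values, alpha=alpha, clip=clip)
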