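"""Posterior summaries and decisions: HDI, ROPE rule, contrasts, Cohen's d.

The highest-density interval (HDI) of a sample is the shortest contiguous
interval containing the requested posterior mass; every value inside it is
more probable than any value outside.  Significance of an epoch contrast is
decided by comparing its 95% HDI with a region of practical equivalence
(ROPE) around zero: an effect is *credibly different* when the HDI lies
wholly outside the ROPE, *practically equivalent* when it lies wholly
inside, and *undecided* otherwise.

Effect size is a posterior Cohen's d: for each MCMC draw, the cell-mean
difference divided by the residual SD of that draw (the model's single
pooled SD), yielding a d sample whose HDI is reported.  An empirical
two-group pooled-SD variant is available via ``d_method='empirical'``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .hier_bayes import ModelData, PosteriorSamples

Decision = Literal["credibly_different", "practically_equivalent", "undecided"]


@dataclass(frozen=True)
class Interval:
    """A posterior interval [low, high] holding `mass` probability."""

    low: float
    high: float
    mass: float = 0.95

    def __post_init__(self) -> None:
        if not (self.low <= self.high):
            raise ValueError(f"low {self.low} > high {self.high}")

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, x: float) -> bool:
        return self.low <= x <= self.high


def hdi(samples: np.ndarray, mass: float = 0.95) -> Interval:
    """Shortest contiguous interval holding ``ceil(mass * n)`` samples.

    Ties between equal-width windows are broken toward the smallest lower
    endpoint.  Requires at least 2 finite samples and 0 < mass < 1.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("hdi requires at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("hdi requires finite samples")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(x)
    n = x.size
    k = math.ceil(mass * n)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first = leftmost minimum
    return Interval(low=float(x[i]), high=float(x[i + k - 1]), mass=mass)


def rope_decision(interval: Interval, rope_halfwidth: float) -> Decision:
    """Classify an interval against the ROPE [-h, +h] around zero."""
    if rope_halfwidth < 0:
        raise ValueError("rope_halfwidth must be >= 0")
    h = rope_halfwidth
    if interval.low > h or interval.high < -h:
        return "credibly_different"
    if -h <= interval.low and interval.high <= h:
        return "practically_equivalent"
    return "undecided"


@dataclass
class ContrastResult:
    """Posterior samples and decision for the contrast epoch e1 - e2."""

    e1: int
    e2: int
    diff_samples: np.ndarray
    diff_hdi: Interval
    d_samples: np.ndarray
    d_hdi: Interval
    decision: Decision
    rope_halfwidth: float
    n_excluded: int = 0
    subject_id: str | None = None  # set for per-fish scope

    @property
    def diff_mean(self) -> float:
        return float(self.diff_samples.mean())

    @property
    def d_mean(self) -> float:
        return float(self.d_samples.mean())


def _check_epoch(posterior: PosteriorSamples, e: int) -> None:
    if not 1 <= e <= posterior.n_epochs:
        raise ValueError(
            f"epoch {e} not in the model (1..{posterior.n_epochs})"
        )


def _pooled_sd_empirical(data: ModelData, e1: int, e2: int) -> float:
    x1 = data.errors[data.epoch_idx == e1 - 1]
    x2 = data.errors[data.epoch_idx == e2 - 1]
    if x1.size < 2 or x2.size < 2:
        raise ValueError("empirical pooled SD needs >= 2 trials per epoch")
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    return float(
        np.sqrt(((x1.size - 1) * v1 + (x2.size - 1) * v2) / (x1.size + x2.size - 2))
    )


def cohens_d_posterior(
    posterior: PosteriorSamples,
    e1: int,
    e2: int,
    scope: str = "pooled",
    subject: int | None = None,
    d_method: str = "residual",
    data: ModelData | None = None,
    mass: float = 0.95,
) -> tuple[np.ndarray, Interval, int]:
    """Per-draw Cohen's d of the epoch contrast, with its HDI.

    Returns ``(d_samples, d_hdi, n_excluded)`` where ``n_excluded`` counts
    draws dropped for a non-positive pooled SD (never propagated as NaN).
    """
    _check_epoch(posterior, e1)
    _check_epoch(posterior, e2)
    m = posterior.cell_means()
    diff = m[:, :, e1 - 1, :] - m[:, :, e2 - 1, :]
    if scope == "pooled":
        diff = diff.mean(axis=-1)
    elif scope == "per_fish":
        if subject is None:
            raise ValueError("per_fish scope requires a subject index")
        diff = diff[:, :, subject]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    diff = diff.reshape(-1)
    if d_method == "residual":
        sd = posterior.sigma_draws()
    elif d_method == "empirical":
        if data is None:
            raise ValueError("d_method='empirical' requires the ModelData")
        sd = np.full(diff.size, _pooled_sd_empirical(data, e1, e2))
    else:
        raise ValueError(f"unknown d_method {d_method!r}")
    ok = sd > 0
    n_excluded = int((~ok).sum())
    d = diff[ok] / sd[ok]
    return d, hdi(d, mass), n_excluded


def epoch_contrast(
    posterior: PosteriorSamples,
    e1: int,
    e2: int,
    scope: str = "pooled",
    rope_mode: str = "relative",
    rope_value: float = 0.05,
    d_method: str = "residual",
    data: ModelData | None = None,
    mass: float = 0.95,
):
    """Posterior contrast of epochs e1 - e2 with HDI, ROPE decision and d.

    ``scope='pooled'`` averages the per-draw cell-mean difference over
    subjects and returns one :class:`ContrastResult`; ``scope='per_fish'``
    returns a dict mapping subject id to its own result.

    The ROPE halfwidth is either ``rope_value`` millimetres
    (``rope_mode='absolute'``) or ``rope_value`` times the posterior-mean
    absolute contrast (``rope_mode='relative'``, default 5%).
    """
    _check_epoch(posterior, e1)
    _check_epoch(posterior, e2)
    if scope == "per_fish":
        ids = posterior.subject_ids or tuple(
            f"subject{i + 1}" for i in range(posterior.n_subjects)
        )
        return {
            ids[s]: _one_contrast(
                posterior, e1, e2, "per_fish", s, rope_mode, rope_value,
                d_method, data, mass, subject_id=ids[s],
            )
            for s in range(posterior.n_subjects)
        }
    if scope != "pooled":
        raise ValueError(f"unknown scope {scope!r}")
    return _one_contrast(
        posterior, e1, e2, "pooled", None, rope_mode, rope_value,
        d_method, data, mass,
    )


def _one_contrast(
    posterior, e1, e2, scope, subject, rope_mode, rope_value,
    d_method, data, mass, subject_id=None,
) -> ContrastResult:
    m = posterior.cell_means()
    diff = m[:, :, e1 - 1, :] - m[:, :, e2 - 1, :]
    diff = diff.mean(axis=-1) if scope == "pooled" else diff[:, :, subject]
    diff = diff.reshape(-1)
    interval = hdi(diff, mass)
    if rope_mode == "absolute":
        h = float(rope_value)
    elif rope_mode == "relative":
        h = float(rope_value) * abs(float(diff.mean()))
    else:
        raise ValueError(f"unknown rope_mode {rope_mode!r}")
    d, d_interval, n_excl = cohens_d_posterior(
        posterior, e1, e2, scope=scope, subject=subject,
        d_method=d_method, data=data, mass=mass,
    )
    return ContrastResult(
        e1=e1,
        e2=e2,
        diff_samples=diff,
        diff_hdi=interval,
        d_samples=d,
        d_hdi=d_interval,
        decision=rope_decision(interval, h),
        rope_halfwidth=h,
        n_excluded=n_excl,
        subject_id=subject_id,
    )
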