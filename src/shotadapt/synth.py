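"""Synthetic shot-error generator for the airflow-perturbation paradigms.

The generator emulates the statistical structure the analysis assumes: a
jump-decay adaptation trajectory.  At airflow onset the mean error jumps to
``perturbation_shift`` millimetres and then decays geometrically at
``learning_rate`` per trial as the fish builds an internal compensation
``c_t = shift - m_t``.  When the airflow is removed the compensation is
expressed as an opposite-sign aftereffect ``-aftereffect_fraction * c_last``
that washes out at the same rate.  In the direction-reversal design the
carried-over compensation either *adds* to the new perturbation effect
(egocentric generalization: the correction is tied to the fish's body axis,
so after a 180-degree turn it pushes the jet the wrong way) or *subtracts*
from it (allocentric: the correction is tied to the room frame and remains
appropriate).

Default magnitudes are calibrated so that simulated epoch contrasts land in
the ranges the analysis is designed to resolve: ~5 mm at onset, ~2x that
after an egocentric reversal, ~3.3 mm aftereffect, and an onset effect size
(Cohen's d) near 1.4.

Randomness is counter-split: each (fish, session) owns a private stream keyed
by ``(seed, fish index, session index)``, so enlarging the cohort never
perturbs earlier fish's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .trials import (
    DESIGN_BLOCK_BOUNDS,
    Session,
    SessionSet,
    Trial,
)

#: sessions completed per fish in the two cohorts
EXP1_COHORT_SESSIONS = (15, 15, 8, 7, 7, 2, 1)
EXP2_COHORT_SESSIONS = (15, 4, 8)

REVERSAL_MODES = ("egocentric", "allocentric")


@dataclass(frozen=True)
class AdaptationParams:
    """Parameters of the jump-decay adaptation model (all lengths in mm).

    baseline_sd
        SD of shot errors with no airflow.
    perturbation_shift
        Mean error on the first trial after airflow onset.
    learning_rate
        Per-trial fractional reduction of the residual error, in (0, 1).
    aftereffect_fraction
        Fraction of the accumulated compensation expressed as an
        opposite-sign error when the airflow is removed, in [0, 1].
    reversal_mode
        How compensation generalizes across the 180-degree turn
        ('egocentric' adds to the new effect, 'allocentric' subtracts).
    trial_noise_sd
        SD of trial-to-trial noise around the mean trajectory during
        perturbation and washout.
    """

    baseline_sd: float = 3.2
    perturbation_shift: float = 5.0
    learning_rate: float = 0.2
    aftereffect_fraction: float = 0.7
    reversal_mode: str = "egocentric"
    trial_noise_sd: float = 3.2

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0 or self.trial_noise_sd < 0:
            raise ValueError("noise SDs must be positive")
        if not 0.0 < self.learning_rate < 1.0:
            raise ValueError("learning_rate must be in (0, 1)")
        if not 0.0 <= self.aftereffect_fraction <= 1.0:
            raise ValueError("aftereffect_fraction must be in [0, 1]")
        if self.reversal_mode not in REVERSAL_MODES:
            raise ValueError(f"reversal_mode must be one of {REVERSAL_MODES}")


def _decay(start: float, rate: float, n: int) -> np.ndarray:
    """Geometric decay start, start*(1-rate), ... of length n."""
    return start * (1.0 - rate) ** np.arange(n)


def mean_trajectory(
    design: str, params: AdaptationParams, block_lengths: tuple[int, ...]
) -> np.ndarray:
    """Noise-free mean error for each trial given the phase block lengths.

    ``block_lengths`` is (baseline, perturbation, washout) for exp1 and
    (baseline, perturbation, perturbation_reversed, washout) for exp2.
    """
    shift, lr = params.perturbation_shift, params.learning_rate
    if design == "exp1":
        b, p, w = block_lengths
        pert = _decay(shift, lr, p)
        c_last = shift - pert[-1] if p else 0.0
        wash = _decay(-params.aftereffect_fraction * c_last, lr, w)
        return np.concatenate([np.zeros(b), pert, wash])
    b, p, r, w = block_lengths
    pert = _decay(shift, lr, p)
    c_last = shift - pert[-1] if p else 0.0
    if params.reversal_mode == "egocentric":
        start = shift + c_last
    else:
        start = shift - c_last
    rev = _decay(start, lr, r)
    c_last_rev = shift - rev[-1] if r else 0.0
    wash = _decay(-params.aftereffect_fraction * c_last_rev, lr, w)
    return np.concatenate([np.zeros(b), pert, rev, wash])


def _draw_block_lengths(
    design: str, rng: np.random.Generator
) -> tuple[int, ...]:
    bounds = DESIGN_BLOCK_BOUNDS[design]
    order = (
        ("baseline", "perturbation", "washout")
        if design == "exp1"
        else ("baseline", "perturbation", "perturbation_reversed", "washout")
    )
    out = []
    for phase in order:
        lo, hi = bounds[phase]
        if hi is None:
            hi = lo + 5
        out.append(int(rng.integers(lo, hi + 1)))
    return tuple(out)


def simulate_session(
    design: str,
    params: AdaptationParams,
    rng: np.random.Generator,
    *,
    fish_id: str = "fish1",
    session_id: str = "s1",
    airflow_direction: str = "with_shot",
    mean_offset: float = 0.0,
    block_lengths: tuple[int, ...] | None = None,
) -> Session:
    """Simulate one session; block lengths drawn uniformly within bounds."""
    if design not in DESIGN_BLOCK_BOUNDS:
        raise ValueError(f"unknown design {design!r}")
    if block_lengths is None:
        block_lengths = _draw_block_lengths(design, rng)
    means = mean_trajectory(design, params, block_lengths)
    b = block_lengths[0]
    sds = np.full(means.size, params.trial_noise_sd)
    sds[:b] = params.baseline_sd
    errors = means + mean_offset + rng.normal(0.0, 1.0, means.size) * sds
    phases = (
        ["baseline"] * block_lengths[0]
        + ["perturbation"] * block_lengths[1]
        + (
            ["perturbation_reversed"] * block_lengths[2]
            if design == "exp2"
            else []
        )
        + ["washout"] * block_lengths[-1]
    )
    trials = tuple(
        Trial(
            fish_id=fish_id,
            session_id=session_id,
            trial_index=i + 1,
            phase=ph,
            error_mm=float(e),
        )
        for i, (ph, e) in enumerate(zip(phases, errors))
    )
    return Session(
        fish_id=fish_id,
        session_id=session_id,
        design=design,
        airflow_direction=airflow_direction,
        trials=trials,
    )


def _session_rng(seed: int, fish_i: int, sess_j: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(fish_i, sess_j))
    )


def simulate_experiment(
    design: str,
    params: AdaptationParams | None = None,
    *,
    n_fish: int = 7,
    sessions_per_fish: int | tuple[int, ...] = EXP1_COHORT_SESSIONS,
    fish_effect_sd: float = 1.0,
    seed: int = 0,
) -> SessionSet:
    """Simulate a cohort with per-fish random mean offsets.

    Fish offsets are Normal(0, fish_effect_sd) and shift every trial mean of
    that fish, mirroring the subject term of the hierarchical error model.
    Fully reproducible from ``seed``; each (fish, session) has a private
    stream so cohorts of different sizes share their common prefix.
    """
    if params is None:
        params = AdaptationParams()
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    if isinstance(sessions_per_fish, int):
        counts = (sessions_per_fish,) * n_fish
    else:
        counts = tuple(sessions_per_fish)
        if len(counts) != n_fish:
            raise ValueError(
                f"sessions_per_fish has {len(counts)} entries for "
                f"{n_fish} fish"
            )
    sessions = []
    for i in range(n_fish):
        off_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i, 1_000_003))
        )
        offset = float(off_rng.normal(0.0, fish_effect_sd)) if fish_effect_sd else 0.0
        direction = "with_shot" if i % 2 == 0 else "against_shot"
        for j in range(counts[i]):
            sessions.append(
                simulate_session(
                    design,
                    params,
                    _session_rng(seed, i, j),
                    fish_id=f"fish{i + 1}",
                    session_id=f"s{j + 1}",
                    airflow_direction=direction,
                    mean_offset=offset,
                )
            )
    return SessionSet(tuple(sessions))


def null_params(params: AdaptationParams | None = None) -> AdaptationParams:
    """The same generator with the perturbation shift forced to zero."""
    base = params or AdaptationParams()
    return replace(base, perturbation_shift=0.0)
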