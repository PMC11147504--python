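"""End-to-end pipeline: annotate, fit, summarize, plot, log.

``run_pipeline`` takes a :class:`RunConfig` (one data source: a session CSV
*or* synthetic-generator settings), runs epoch assignment, the hierarchical
Bayesian fit, the contrast/ROPE report, and the mixed-effects cross-check,
and writes a reproducible artifact bundle: annotated CSV, posterior archive,
contrast table, frequentist JSON report, two figures (per-fish error-by-trial
curves; epoch means with 95% HDIs), and a run log with seeds and versions.
All outputs are deterministic given the config and seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .epochs import annotate_sessions, assign_epochs
from .freq_model import DESIGN_CONTRAST_PAIRS, anova_eta2, fit_mixed, posthoc
from .hier_bayes import (
    ModelSpec,
    build_model_data,
    convergence_diagnostics,
    sample_posterior,
)
from .inference import epoch_contrast
from .synth import AdaptationParams, simulate_experiment
from .trials import SessionSet, read_sessions, write_sessions


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One run: data source, design, sampler and ROPE settings, outputs."""

    out_dir: str | Path = "shotadapt_out"
    design: str = "exp1"
    input_path: str | Path | None = None
    synth: dict[str, Any] | None = None
    n_chains: int = 3
    n_samples: int = 10_000
    burn_in: int = 2_000
    rope_mode: str = "relative"
    rope_value: float = 0.05
    seed: int = 0
    pairs: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synth is None):
            raise ValueError(
                "exactly one data source required: input_path xor synth"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pairs" in raw and raw["pairs"] is not None:
            raw["pairs"] = tuple(tuple(p) for p in raw["pairs"])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage-named re-raise
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("load_data")
def _load(config: RunConfig) -> SessionSet:
    if config.input_path is not None:
        return read_sessions(config.input_path)
    synth = dict(config.synth or {})
    param_fields = {
        k: synth.pop(k)
        for k in list(synth)
        if k in AdaptationParams.__dataclass_fields__
    }
    params = AdaptationParams(**param_fields)
    synth.setdefault("seed", config.seed)
    return simulate_experiment(config.design, params, **synth)


def _contrast_table(posterior, pairs, config, data) -> pd.DataFrame:
    rows = []
    for e1, e2 in pairs:
        c = epoch_contrast(
            posterior, e1, e2,
            rope_mode=config.rope_mode, rope_value=config.rope_value,
            data=data,
        )
        rows.append(
            {
                "pair": f"{e1}:{e2}",
                "diff_mean": c.diff_mean,
                "diff_low": c.diff_hdi.low,
                "diff_high": c.diff_hdi.high,
                "d_mean": c.d_mean,
                "d_low": c.d_hdi.low,
                "d_high": c.d_hdi.high,
                "rope_halfwidth": c.rope_halfwidth,
                "decision": c.decision,
            }
        )
    return pd.DataFrame(rows)


def _plot_trials(sessions: SessionSet, path: Path) -> None:
    """Per-fish mean error by trial position, aligned on perturbation onset."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for fish in sessions.fish_ids:
        aligned: dict[int, list[float]] = {}
        for s in sessions:
            if s.fish_id != fish:
                continue
            onset = next(
                (i for i, t in enumerate(s.trials) if t.phase != "baseline"),
                len(s.trials),
            )
            for i, t in enumerate(s.trials):
                aligned.setdefault(i - onset, []).append(t.error_mm)
        xs = sorted(aligned)
        ax.plot(xs, [np.mean(aligned[x]) for x in xs], label=fish, lw=1)
    ax.axvline(0, color="k", ls="--", lw=0.8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("trial relative to airflow onset")
    ax.set_ylabel("mean error (mm)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_epochs(posterior, path: Path) -> None:
    """Pooled epoch cell means with 95% HDIs."""
    from .inference import hdi

    m = posterior.cell_means().mean(axis=-1)  # pooled over subjects
    fig, ax = plt.subplots(figsize=(6, 4))
    epochs = np.arange(1, posterior.n_epochs + 1)
    means, lows, highs = [], [], []
    for e in epochs:
        draws = m[:, :, e - 1].reshape(-1)
        iv = hdi(draws)
        means.append(draws.mean())
        lows.append(iv.low)
        highs.append(iv.high)
    means = np.array(means)
    ax.errorbar(
        epochs, means,
        yerr=[means - np.array(lows), np.array(highs) - means],
        fmt="o", capsize=3, color="tab:blue",
    )
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("epoch")
    ax.set_ylabel("error (mm), posterior mean and 95% HDI")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis; returns a dict of artifact paths.

    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts written by earlier stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    sessions = _load(config)
    if config.synth is not None:
        artifacts["sessions"] = out / "sessions.csv"
        write_sessions(sessions, artifacts["sessions"])

    try:
        annotated = annotate_sessions(sessions)
        artifacts["annotated"] = out / "annotated.csv"
        annotated.to_csv(artifacts["annotated"], index=False, float_format="%.6g")
    except Exception as exc:
        raise PipelineError(f"stage 'annotate' failed: {exc}") from exc

    try:
        labels = [assign_epochs(s) for s in sessions.sessions]
        data = build_model_data(sessions, labels=labels)
        spec = ModelSpec(
            n_chains=config.n_chains,
            n_samples=config.n_samples,
            burn_in=config.burn_in,
            seed=config.seed,
        )
        posterior = sample_posterior(data, spec)
        artifacts["posterior"] = out / "posterior.npz"
        posterior.save(artifacts["posterior"])
        diags = convergence_diagnostics(posterior)
        artifacts["diagnostics"] = out / "diagnostics.csv"
        diags.to_csv(artifacts["diagnostics"], float_format="%.6g")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'bayes_fit' failed: {exc}") from exc

    try:
        pairs = config.pairs or DESIGN_CONTRAST_PAIRS[config.design]
        table = _contrast_table(posterior, pairs, config, data)
        artifacts["contrasts"] = out / "contrasts.csv"
        table.to_csv(artifacts["contrasts"], index=False, float_format="%.6g")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'contrasts' failed: {exc}") from exc

    try:
        mixed = fit_mixed(data)
        anova = anova_eta2(mixed)
        ph = posthoc(mixed, pairs)
        report = {
            "design": config.design,
            "F": anova.F,
            "p": anova.p,
            "eta2": anova.eta2,
            "df_num": anova.df_num,
            "df_den": anova.df_den,
            "singular": mixed.singular,
            "random_intercept_var": mixed.random_intercept_var,
            "posthoc": ph.to_dict(orient="records"),
        }
        artifacts["freq_report"] = out / "freq_report.json"
        artifacts["freq_report"].write_text(json.dumps(report, indent=2))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'mixed_model' failed: {exc}") from exc

    try:
        artifacts["fig_trials"] = out / "fig_trials.png"
        _plot_trials(sessions, artifacts["fig_trials"])
        artifacts["fig_epochs"] = out / "fig_epochs.png"
        _plot_epochs(posterior, artifacts["fig_epochs"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'figures' failed: {exc}") from exc

    log = {
        "shotadapt_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "design": config.design,
        "n_chains": config.n_chains,
        "n_samples": config.n_samples,
        "burn_in": config.burn_in,
        "rope_mode": config.rope_mode,
        "rope_value": config.rope_value,
        "source": "synth" if config.synth is not None else str(config.input_path),
        "n_trials": data.n_trials,
        "n_fish": data.n_subjects,
    }
    artifacts["run_log"] = out / "run_log.json"
    artifacts["run_log"].write_text(json.dumps(log, indent=2, sort_keys=True))
    return artifacts
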