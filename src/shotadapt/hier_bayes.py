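"""Hierarchical Bayesian model of per-trial shot error, fit by Gibbs sampling.

The trial error (mm) is modelled as

    error ~ Normal(a_baseline + a_epoch[e] + a_subject[s]
                   + a_interaction[e, s],  sigma^2)

with a hierarchical second level: each group of coefficients is itself
normal around a hyper-mean with a hyper-variance,

    a_baseline       ~ N(mu_baseline,    v_baseline)
    a_epoch[e]       ~ N(mu_epoch,       v_epoch)
    a_subject[s]     ~ N(mu_subject,     v_subject)
    a_interaction[.] ~ N(mu_interaction, v_interaction)

Hyper-means get broad normal priors N(0, 1000^2); hyper-variances get broad
gamma priors Gamma(0.001, 0.001) on the precision scale; the residual SD
sigma gets a broad uniform prior on (0, 100) mm.  All full conditionals are
then conjugate (normal-normal and gamma-precision), except sigma, whose
uniform-on-SD prior translates to a truncated gamma on the precision; the
sampler is a plain systematic-scan Gibbs sampler.

The additive coefficients are individually unidentifiable (no sum-to-zero
constraints are imposed); only the cell means

    m[e, s] = a_baseline + a_epoch[e] + a_subject[s] + a_interaction[e, s]

and their contrasts are identified, and all downstream inference uses those.

``HierarchicalShotModel`` wraps the sampler as a scikit-learn style
estimator; ``sample_posterior`` is the functional entry point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .epochs import N_EPOCHS, assign_epochs
from .trials import SessionSet

_VAR_GROUPS = ("baseline", "epoch", "subject", "interaction")


@dataclass(frozen=True)
class ModelData:
    """Flat trial-level design: errors with dense epoch/subject indices."""

    errors: np.ndarray
    epoch_idx: np.ndarray  # 0-based, in [0, n_epochs)
    subject_idx: np.ndarray  # 0-based, in [0, n_subjects)
    n_epochs: int
    n_subjects: int
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        e = np.asarray(self.errors, dtype=float)
        ei = np.asarray(self.epoch_idx, dtype=np.int64)
        si = np.asarray(self.subject_idx, dtype=np.int64)
        if not (e.shape == ei.shape == si.shape) or e.ndim != 1:
            raise ValueError("errors, epoch_idx, subject_idx must be equal-length 1-D")
        if e.size and not np.all(np.isfinite(e)):
            raise ValueError("errors contain non-finite values")
        if e.size and (ei.min() < 0 or ei.max() >= self.n_epochs):
            raise ValueError("epoch_idx out of range")
        if e.size and (si.min() < 0 or si.max() >= self.n_subjects):
            raise ValueError("subject_idx out of range")
        object.__setattr__(self, "errors", e)
        object.__setattr__(self, "epoch_idx", ei)
        object.__setattr__(self, "subject_idx", si)

    @property
    def n_trials(self) -> int:
        return int(self.errors.size)

    def to_dataframe(self) -> pd.DataFrame:
        ids = self.subject_ids or tuple(
            f"subject{i + 1}" for i in range(self.n_subjects)
        )
        return pd.DataFrame(
            {
                "error_mm": self.errors,
                "epoch": self.epoch_idx + 1,
                "fish_id": [ids[i] for i in self.subject_idx],
            }
        )


def build_model_data(
    sessions: SessionSet,
    labels: list[np.ndarray] | np.ndarray | None = None,
    n_epochs: int | None = None,
) -> ModelData:
    """Pool all sessions of each fish under one subject index.

    ``labels`` are 1-based epoch labels, either one array per session or a
    single flat array over all trials in session order; by default they are
    computed with :func:`shotadapt.epochs.assign_epochs`.  ``n_epochs``
    defaults to the design's epoch count (6 or 9) even if some epochs are
    empty in the data.
    """
    if len(sessions) == 0:
        raise ValueError("empty SessionSet")
    designs = {s.design for s in sessions}
    if n_epochs is None:
        if len(designs) > 1:
            raise ValueError(f"mixed designs {designs}; pass n_epochs explicitly")
        n_epochs = N_EPOCHS[designs.pop()]
    if labels is None:
        labels = [assign_epochs(s) for s in sessions.sessions]
    if isinstance(labels, np.ndarray):
        flat = np.asarray(labels, dtype=np.int64)
    else:
        if len(labels) != len(sessions):
            raise ValueError("one label array per session required")
        for s, lab in zip(sessions.sessions, labels):
            if len(lab) != len(s):
                raise ValueError(
                    f"label length {len(lab)} != session length {len(s)} "
                    f"for session {s.session_id!r}"
                )
        flat = np.concatenate([np.asarray(l, dtype=np.int64) for l in labels])
    errors = np.concatenate([np.asarray(s.errors, dtype=float) for s in sessions])
    if flat.size != errors.size:
        raise ValueError(
            f"{flat.size} labels for {errors.size} trials"
        )
    fish_ids = sessions.fish_ids
    fish_index = {f: i for i, f in enumerate(fish_ids)}
    subject_idx = np.concatenate(
        [np.full(len(s), fish_index[s.fish_id], dtype=np.int64) for s in sessions]
    )
    return ModelData(
        errors=errors,
        epoch_idx=flat - 1,
        subject_idx=subject_idx,
        n_epochs=int(n_epochs),
        n_subjects=len(fish_ids),
        subject_ids=tuple(fish_ids),
    )


@dataclass(frozen=True)
class ModelSpec:
    """Priors and sampler settings.

    ``prior_scale`` is a sensitivity switch: it multiplies the hyper-mean
    prior SD and the sigma upper bound (x10 broader / x0.1 narrower).
    ``fixed_sigma2`` and ``fixed_hyper_vars`` clamp the corresponding
    variances instead of sampling them (used for conjugate cross-checks).
    """

    n_chains: int = 3
    n_samples: int = 10_000
    burn_in: int = 2_000
    thin: int = 1
    hyper_mean_sd: float = 1000.0
    hyper_var_shape: float = 1e-3
    hyper_var_rate: float = 1e-3
    sigma_upper: float = 100.0
    prior_scale: float = 1.0
    fixed_sigma2: float | None = None
    fixed_hyper_vars: float | Mapping[str, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 for convergence checks")
        if self.n_samples < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("invalid sampler settings")
        for v in (
            self.hyper_mean_sd,
            self.hyper_var_shape,
            self.hyper_var_rate,
            self.sigma_upper,
            self.prior_scale,
        ):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("prior hyperparameters must be finite and > 0")

    @property
    def mean_sd(self) -> float:
        return self.hyper_mean_sd * self.prior_scale

    @property
    def sd_upper(self) -> float:
        return self.sigma_upper * self.prior_scale

    def fixed_var(self, group: str) -> float | None:
        fv = self.fixed_hyper_vars
        if fv is None:
            return None
        if isinstance(fv, Mapping):
            return fv.get(group)
        return float(fv)


@dataclass
class PosteriorSamples:
    """Per-chain MCMC draws of all model parameters.

    Arrays are shaped (chains, draws) for scalars, (chains, draws, E) for
    epoch coefficients, (chains, draws, S) for subject coefficients and
    (chains, draws, E, S) for the interaction.
    """

    a_baseline: np.ndarray
    a_epoch: np.ndarray
    a_subject: np.ndarray
    a_interaction: np.ndarray
    sigma2: np.ndarray
    hyper_means: dict[str, np.ndarray]
    hyper_vars: dict[str, np.ndarray]
    n_epochs: int
    n_subjects: int
    subject_ids: tuple[str, ...] = ()
    spec: ModelSpec | None = None

    @property
    def n_chains(self) -> int:
        return self.a_baseline.shape[0]

    @property
    def n_draws(self) -> int:
        return self.a_baseline.shape[1]

    def cell_means(self) -> np.ndarray:
        """Identifiable per-draw cell means m[e, s], shape (C, D, E, S)."""
        return (
            self.a_baseline[..., None, None]
            + self.a_epoch[..., :, None]
            + self.a_subject[..., None, :]
            + self.a_interaction
        )

    def sigma_draws(self) -> np.ndarray:
        """Flattened residual-SD draws, shape (C*D,)."""
        return np.sqrt(self.sigma2.reshape(-1))

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Every monitored scalar as a (chains, draws) array.

        Includes the raw (unidentified) coefficients and, under
        ``epoch_mean[e]``, the identifiable subject-averaged cell means that
        downstream inference actually uses.
        """
        out = {"a_baseline": self.a_baseline, "sigma2": self.sigma2}
        pooled = self.cell_means().mean(axis=-1)
        for e in range(self.n_epochs):
            out[f"a_epoch[{e + 1}]"] = self.a_epoch[:, :, e]
            out[f"epoch_mean[{e + 1}]"] = pooled[:, :, e]
        for s in range(self.n_subjects):
            out[f"a_subject[{s + 1}]"] = self.a_subject[:, :, s]
        for g in _VAR_GROUPS:
            out[f"mu_{g}"] = self.hyper_means[g]
            out[f"var_{g}"] = self.hyper_vars[g]
        return out

    def to_inference_data(self) -> az.InferenceData:
        data = {
            "a_baseline": self.a_baseline,
            "a_epoch": self.a_epoch,
            "a_subject": self.a_subject,
            "a_interaction": self.a_interaction,
            "sigma2": self.sigma2,
        }
        for g in _VAR_GROUPS:
            data[f"mu_{g}"] = self.hyper_means[g]
            data[f"var_{g}"] = self.hyper_vars[g]
        return az.from_dict(
            posterior=data,
            dims={
                "a_epoch": ["epoch"],
                "a_subject": ["subject"],
                "a_interaction": ["epoch", "subject"],
            },
            coords={
                "epoch": np.arange(1, self.n_epochs + 1),
                "subject": np.arange(1, self.n_subjects + 1),
            },
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "a_baseline": self.a_baseline,
            "a_epoch": self.a_epoch,
            "a_subject": self.a_subject,
            "a_interaction": self.a_interaction,
            "sigma2": self.sigma2,
            "n_epochs": np.int64(self.n_epochs),
            "n_subjects": np.int64(self.n_subjects),
            "subject_ids": np.asarray(self.subject_ids, dtype=object),
        }
        for g in _VAR_GROUPS:
            payload[f"mu_{g}"] = self.hyper_means[g]
            payload[f"var_{g}"] = self.hyper_vars[g]
        np.savez_compressed(path, **payload, allow_pickle=True)

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                a_baseline=z["a_baseline"],
                a_epoch=z["a_epoch"],
                a_subject=z["a_subject"],
                a_interaction=z["a_interaction"],
                sigma2=z["sigma2"],
                hyper_means={g: z[f"mu_{g}"] for g in _VAR_GROUPS},
                hyper_vars={g: z[f"var_{g}"] for g in _VAR_GROUPS},
                n_epochs=int(z["n_epochs"]),
                n_subjects=int(z["n_subjects"]),
                subject_ids=tuple(z["subject_ids"].tolist()),
            )


def _normal_draw(rng, prior_mean, prior_var, lik_sum, lik_n, lik_var):
    """Conjugate normal update: prior N(m, v), likelihood sum/n at variance s2.

    Vectorized over the leading dimension of the arguments.
    """
    prec = lik_n / lik_var + 1.0 / prior_var
    mean = (lik_sum / lik_var + prior_mean / prior_var) / prec
    return mean + rng.standard_normal(np.shape(mean)) / np.sqrt(prec)


def _draw_sigma2(rng, ss: float, n: int, sd_upper: float) -> float:
    """sigma^2 conditional under sigma ~ Uniform(0, sd_upper).

    In precision tau = 1/sigma^2 the conditional is Gamma((n-1)/2, ss/2)
    truncated to tau >= sd_upper^-2.
    """
    tau_min = sd_upper**-2
    if n == 0:
        return float(rng.uniform(0.0, sd_upper)) ** 2
    if n == 1:
        # shape-zero gamma; fall back to grid inverse-CDF on sigma
        grid = np.linspace(sd_upper / 4096.0, sd_upper, 4096)
        logp = -np.log(grid) - ss / (2.0 * grid**2)
        p = np.exp(logp - logp.max())
        cdf = np.cumsum(p)
        u = rng.uniform(0.0, cdf[-1])
        return float(grid[np.searchsorted(cdf, u)]) ** 2
    shape = 0.5 * (n - 1)
    rate = 0.5 * ss
    for _ in range(100):
        tau = rng.gamma(shape, 1.0 / rate)
        if tau >= tau_min:
            return 1.0 / tau
    # pathological: inverse-CDF on the truncated region
    lo = stats.gamma.cdf(tau_min, shape, scale=1.0 / rate)
    u = rng.uniform(lo, 1.0)
    tau = float(stats.gamma.ppf(u, shape, scale=1.0 / rate))
    return 1.0 / max(tau, tau_min)


def _run_chain(
    data: ModelData, spec: ModelSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    y = data.errors
    n = y.size
    E, S = data.n_epochs, data.n_subjects
    ei, si = data.epoch_idx, data.subject_idx
    ci = ei * S + si
    n_e = np.bincount(ei, minlength=E).astype(float)
    n_s = np.bincount(si, minlength=S).astype(float)
    n_c = np.bincount(ci, minlength=E * S).astype(float)

    mean_var = spec.mean_sd**2
    g_shape, g_rate = spec.hyper_var_shape, spec.hyper_var_rate
    group_sizes = {"baseline": 1, "epoch": E, "subject": S, "interaction": E * S}

    # overdispersed initialization around data moments
    ybar = float(y.mean()) if n else 0.0
    ysd = float(y.std()) if n > 1 else 1.0
    ysd = max(ysd, 1e-3)
    a0 = ybar + rng.normal(0.0, ysd)
    a_e = rng.normal(0.0, ysd, E)
    a_s = rng.normal(0.0, ysd, S)
    a_c = rng.normal(0.0, ysd, E * S)
    sigma2 = (
        spec.fixed_sigma2
        if spec.fixed_sigma2 is not None
        else float(ysd**2 * np.exp(rng.normal(0.0, 0.5)))
    )
    mu = {g: 0.0 for g in _VAR_GROUPS}
    var = {}
    for g in _VAR_GROUPS:
        fv = spec.fixed_var(g)
        var[g] = fv if fv is not None else float(ysd**2)

    D = spec.n_samples
    out = {
        "a_baseline": np.empty(D),
        "a_epoch": np.empty((D, E)),
        "a_subject": np.empty((D, S)),
        "a_interaction": np.empty((D, E * S)),
        "sigma2": np.empty(D),
    }
    for g in _VAR_GROUPS:
        out[f"mu_{g}"] = np.empty(D)
        out[f"var_{g}"] = np.empty(D)

    n_iter = spec.burn_in + D * spec.thin
    kept = 0
    for it in range(n_iter):
        # --- first-level coefficients ---
        if n:
            r = y - a_e[ei] - a_s[si] - a_c[ci]
            a0 = float(
                _normal_draw(rng, mu["baseline"], var["baseline"], r.sum(), n, sigma2)
            )
            r = y - a0 - a_s[si] - a_c[ci]
            a_e = _normal_draw(
                rng, mu["epoch"], var["epoch"],
                np.bincount(ei, weights=r, minlength=E), n_e, sigma2,
            )
            r = y - a0 - a_e[ei] - a_c[ci]
            a_s = _normal_draw(
                rng, mu["subject"], var["subject"],
                np.bincount(si, weights=r, minlength=S), n_s, sigma2,
            )
            r = y - a0 - a_e[ei] - a_s[si]
            a_c = _normal_draw(
                rng, mu["interaction"], var["interaction"],
                np.bincount(ci, weights=r, minlength=E * S), n_c, sigma2,
            )
        else:  # prior-only: ancestral draws from the hierarchy
            a0 = float(rng.normal(mu["baseline"], np.sqrt(var["baseline"])))
            a_e = rng.normal(mu["epoch"], np.sqrt(var["epoch"]), E)
            a_s = rng.normal(mu["subject"], np.sqrt(var["subject"]), S)
            a_c = rng.normal(mu["interaction"], np.sqrt(var["interaction"]), E * S)

        # --- residual variance ---
        if spec.fixed_sigma2 is None:
            if n:
                resid = y - a0 - a_e[ei] - a_s[si] - a_c[ci]
                sigma2 = _draw_sigma2(rng, float(resid @ resid), n, spec.sd_upper)
            else:
                sigma2 = _draw_sigma2(rng, 0.0, 0, spec.sd_upper)

        # --- hyper-means and hyper-variances ---
        groups = {
            "baseline": np.array([a0]),
            "epoch": a_e,
            "subject": a_s,
            "interaction": a_c,
        }
        for g, vals in groups.items():
            k = group_sizes[g]
            mu[g] = float(
                _normal_draw(rng, 0.0, mean_var, vals.sum(), k, var[g])
            )
            if spec.fixed_var(g) is None:
                dev = vals - mu[g]
                tau = rng.gamma(g_shape + 0.5 * k, 1.0 / (g_rate + 0.5 * dev @ dev))
                # the broad gamma prior puts mass on precisions that underflow
                # to 0.0; floor keeps the variance finite
                var[g] = 1.0 / max(tau, 1e-60)

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            out["a_baseline"][kept] = a0
            out["a_epoch"][kept] = a_e
            out["a_subject"][kept] = a_s
            out["a_interaction"][kept] = a_c
            out["sigma2"][kept] = sigma2
            for g in _VAR_GROUPS:
                out[f"mu_{g}"][kept] = mu[g]
                out[f"var_{g}"][kept] = var[g]
            kept += 1
    assert kept == D
    return out


def sample_posterior(data: ModelData, spec: ModelSpec) -> PosteriorSamples:
    """Draw from the joint posterior by Gibbs sampling, one chain at a time."""
    if data.n_trials and not np.all(np.isfinite(data.errors)):
        raise ValueError("non-finite errors: likelihood undefined")
    root = np.random.SeedSequence(spec.seed)
    chains = [
        _run_chain(data, spec, np.random.default_rng(ss))
        for ss in root.spawn(spec.n_chains)
    ]
    E, S = data.n_epochs, data.n_subjects

    def stack(key):
        return np.stack([c[key] for c in chains])

    return PosteriorSamples(
        a_baseline=stack("a_baseline"),
        a_epoch=stack("a_epoch"),
        a_subject=stack("a_subject"),
        a_interaction=stack("a_interaction").reshape(
            spec.n_chains, spec.n_samples, E, S
        ),
        sigma2=stack("sigma2"),
        hyper_means={g: stack(f"mu_{g}") for g in _VAR_GROUPS},
        hyper_vars={g: stack(f"var_{g}") for g in _VAR_GROUPS},
        n_epochs=E,
        n_subjects=S,
        subject_ids=data.subject_ids,
        spec=spec,
    )


RHAT_THRESHOLD = 1.01


def convergence_diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """Split-R-hat and effective sample size for every monitored scalar.

    Returns a DataFrame indexed by parameter with columns ``rhat``, ``ess``,
    ``zero_variance`` and ``converged``.  Parameters whose chains are all
    constant get ``zero_variance=True`` with rhat 1.0 (a point mass has
    trivially converged) instead of NaN.  R-hat values above 1.01 are flagged
    (``converged=False``), never raised on.
    """
    if samples.n_chains < 2:
        raise ValueError("convergence diagnostics require >= 2 chains")
    rows = []
    for name, arr in samples.scalar_draws().items():
        if np.ptp(arr) == 0.0:
            rows.append((name, 1.0, float(arr.size), True, True))
            continue
        rhat = float(az.rhat(arr.copy()))
        ess = float(az.ess(arr.copy()))
        rows.append((name, rhat, ess, False, bool(rhat <= RHAT_THRESHOLD)))
    return pd.DataFrame(
        rows, columns=["parameter", "rhat", "ess", "zero_variance", "converged"]
    ).set_index("parameter")


class HierarchicalShotModel(BaseEstimator):
    """Scikit-learn style front end to the hierarchical error model.

    Parameters mirror :class:`ModelSpec`.  ``fit`` accepts either a
    :class:`ModelData` (with ``y=None``), a :class:`SessionSet`, a DataFrame
    with ``error_mm``/``epoch``/``fish_id`` columns, or an ``(n, 2)`` integer
    array of (1-based epoch label, 0-based subject index) columns with the
    errors in ``y``.

    Attributes set by ``fit`` (trailing underscore): ``posterior_``,
    ``data_``, ``diagnostics_``, ``n_flagged_``.
    """

    def __init__(
        self,
        n_chains: int = 3,
        n_samples: int = 10_000,
        burn_in: int = 2_000,
        thin: int = 1,
        hyper_mean_sd: float = 1000.0,
        hyper_var_shape: float = 1e-3,
        hyper_var_rate: float = 1e-3,
        sigma_upper: float = 100.0,
        prior_scale: float = 1.0,
        fixed_sigma2: float | None = None,
        fixed_hyper_vars: float | Mapping[str, float] | None = None,
        seed: int | None = None,
        n_epochs: int | None = None,
    ):
        self.n_chains = n_chains
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.thin = thin
        self.hyper_mean_sd = hyper_mean_sd
        self.hyper_var_shape = hyper_var_shape
        self.hyper_var_rate = hyper_var_rate
        self.sigma_upper = sigma_upper
        self.prior_scale = prior_scale
        self.fixed_sigma2 = fixed_sigma2
        self.fixed_hyper_vars = fixed_hyper_vars
        self.seed = seed
        self.n_epochs = n_epochs

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            n_chains=self.n_chains,
            n_samples=self.n_samples,
            burn_in=self.burn_in,
            thin=self.thin,
            hyper_mean_sd=self.hyper_mean_sd,
            hyper_var_shape=self.hyper_var_shape,
            hyper_var_rate=self.hyper_var_rate,
            sigma_upper=self.sigma_upper,
            prior_scale=self.prior_scale,
            fixed_sigma2=self.fixed_sigma2,
            fixed_hyper_vars=self.fixed_hyper_vars,
            seed=self.seed,
        )

    def _as_model_data(self, X, y) -> ModelData:
        if isinstance(X, ModelData):
            return X
        if isinstance(X, SessionSet):
            return build_model_data(X, n_epochs=self.n_epochs)
        if isinstance(X, pd.DataFrame):
            fish = X["fish_id"].astype(str).to_numpy()
            ids = list(dict.fromkeys(fish))
            index = {f: i for i, f in enumerate(ids)}
            epochs = X["epoch"].to_numpy(dtype=np.int64)
            return ModelData(
                errors=X["error_mm"].to_numpy(dtype=float),
                epoch_idx=epochs - 1,
                subject_idx=np.array([index[f] for f in fish]),
                n_epochs=self.n_epochs or int(epochs.max()),
                n_subjects=len(ids),
                subject_ids=tuple(ids),
            )
        X = np.asarray(X)
        if y is None:
            raise ValueError("y (errors) required with array input")
        epochs = X[:, 0].astype(np.int64)
        subjects = X[:, 1].astype(np.int64)
        return ModelData(
            errors=np.asarray(y, dtype=float),
            epoch_idx=epochs - 1,
            subject_idx=subjects,
            n_epochs=self.n_epochs or int(epochs.max()),
            n_subjects=int(subjects.max()) + 1,
        )

    def fit(self, X, y=None):
        data = self._as_model_data(X, y)
        self.data_ = data
        self.posterior_ = sample_posterior(data, self._spec())
        self.diagnostics_ = convergence_diagnostics(self.posterior_)
        self.n_flagged_ = int((~self.diagnostics_["converged"]).sum())
        return self

    def predict(self, X, y=None):
        """Posterior-mean cell mean m[e, s] for each (epoch, subject) row."""
        if not hasattr(self, "posterior_"):
            raise RuntimeError("fit the model first")
        data = self._as_model_data(X, np.zeros(np.asarray(X).shape[0]) if not isinstance(X, (ModelData, SessionSet, pd.DataFrame)) else None)
        m = self.posterior_.cell_means().mean(axis=(0, 1))
        return m[data.epoch_idx, data.subject_idx]

    def score(self, X, y=None):
        """Negative mean squared error of posterior-mean cell predictions."""
        data = self._as_model_data(X, y)
        m = self.posterior_.cell_means().mean(axis=(0, 1))
        pred = m[data.epoch_idx, data.subject_idx]
        return -float(np.mean((data.errors - pred) ** 2))
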