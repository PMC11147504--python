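"""Frequentist cross-check: mixed-effects model, ANOVA eta^2, post hoc tests.

The shot error is regressed on the epoch factor (fixed effect) with a
random intercept per fish, fit by REML through statsmodels' ``MixedLM``.
The epoch factor is tested with a Wald F statistic; effect size is the
classical eta^2 (between-epoch sum of squares over total sum of squares;
a partial variant is available).  Post hoc epoch-pair comparisons use
two-sample t tests on fish-intercept-adjusted observations with Bonferroni
adjustment over the declared family, and empirical pooled-SD Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.formula.api as smf

from .hier_bayes import ModelData

#: epoch pairs whose transitions are compared, per design
DESIGN_CONTRAST_PAIRS = {
    "exp1": ((1, 2), (2, 4), (4, 5)),
    "exp2": ((1, 2), (2, 4), (4, 5), (5, 7), (7, 8)),
}


@dataclass
class MixedFit:
    """REML fit of error ~ C(epoch) + (1 | fish)."""

    result: object  # statsmodels MixedLMResults
    data: ModelData
    singular: bool
    epoch_levels: tuple[int, ...]
    fixed_epoch_means: dict[int, float]
    random_intercept_var: float

    def adjusted_errors(self) -> np.ndarray:
        """Observations minus the fitted per-fish random intercept."""
        re = self.result.random_effects
        ids = self.data.subject_ids or tuple(
            f"subject{i + 1}" for i in range(self.data.n_subjects)
        )
        offsets = np.array(
            [float(np.asarray(re[f]).ravel()[0]) if f in re else 0.0 for f in ids]
        )
        return self.data.errors - offsets[self.data.subject_idx]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    eta2: float
    df_num: int
    df_den: int


def fit_mixed(data: ModelData | pd.DataFrame) -> MixedFit:
    """Fit the epoch fixed-effect / fish random-intercept model by REML.

    A singular fit (random-intercept variance pinned at zero or a
    convergence warning) sets ``singular=True``; estimates are still
    returned.
    """
    if isinstance(data, pd.DataFrame):
        df = data.rename(columns={"epoch": "epoch", "error_mm": "error_mm"})
        fish = df["fish_id"].astype(str)
        ids = tuple(dict.fromkeys(fish))
        index = {f: i for i, f in enumerate(ids)}
        data = ModelData(
            errors=df["error_mm"].to_numpy(dtype=float),
            epoch_idx=df["epoch"].to_numpy(dtype=np.int64) - 1,
            subject_idx=np.array([index[f] for f in fish]),
            n_epochs=int(df["epoch"].max()),
            n_subjects=len(ids),
            subject_ids=ids,
        )
    present = np.unique(data.epoch_idx) + 1
    if present.size < 2:
        raise ValueError("mixed model needs >= 2 non-empty epochs")
    if data.n_subjects < 2:
        raise ValueError("mixed model needs >= 2 fish")
    df = data.to_dataframe().rename(columns={"fish_id": "fish"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("error_mm ~ C(epoch)", df, groups=df["fish"])
        result = model.fit(reml=True)
    re_var = float(np.asarray(result.cov_re).ravel()[0])
    # boundary (zero) random-intercept variance or failed optimization
    singular = re_var < 1e-8 or not bool(getattr(result, "converged", True))
    intercept = float(result.fe_params["Intercept"])
    means = {}
    for e in present:
        if e == present[0]:
            means[int(e)] = intercept
        else:
            means[int(e)] = intercept + float(result.fe_params[f"C(epoch)[T.{e}]"])
    return MixedFit(
        result=result,
        data=data,
        singular=singular,
        epoch_levels=tuple(int(e) for e in present),
        fixed_epoch_means=means,
        random_intercept_var=re_var,
    )


def anova_eta2(fit: MixedFit, partial: bool = False) -> AnovaResult:
    """Wald F test of the epoch factor plus eta^2.

    eta^2 is classical: between-epoch sum of squares over total sum of
    squares of the observations.  With ``partial=True`` the denominator is
    the epoch plus residual (within-epoch) sum of squares instead.
    """
    result = fit.result
    names = list(result.fe_params.index)
    epoch_names = [n for n in names if n.startswith("C(epoch)")]
    q = len(epoch_names)
    # joint Wald test of all epoch dummies
    constraint = ", ".join(f"{n} = 0" for n in epoch_names)
    wald = result.wald_test(constraint, scalar=True)
    chi2 = float(np.asarray(wald.statistic).ravel()[0])
    F = chi2 / q
    df_den = max(fit.data.n_trials - len(names) - 1, 1)
    p = float(stats.f.sf(F, q, df_den))

    y = fit.data.errors
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_epoch = 0.0
    ss_within = 0.0
    for e in fit.epoch_levels:
        ye = y[fit.data.epoch_idx == e - 1]
        ss_epoch += ye.size * (ye.mean() - grand) ** 2
        ss_within += float(((ye - ye.mean()) ** 2).sum())
    if partial:
        denom = ss_epoch + ss_within
    else:
        denom = ss_total
    eta2 = ss_epoch / denom if denom > 0 else 0.0
    return AnovaResult(F=F, p=p, eta2=float(eta2), df_num=q, df_den=df_den)


def posthoc(
    fit: MixedFit, pairs: tuple[tuple[int, int], ...] | list[tuple[int, int]]
) -> pd.DataFrame:
    """Pairwise epoch t tests with Bonferroni adjustment and Cohen's d.

    The family size is the number of tested pairs.  Observations are
    adjusted for the fitted fish random intercepts before comparison;
    Cohen's d uses the empirical pooled SD of the two epochs.  Pairs with an
    empty epoch are flagged, not dropped.
    """
    adj = fit.adjusted_errors()
    family = len(pairs)
    rows = []
    for e1, e2 in pairs:
        x1 = adj[fit.data.epoch_idx == e1 - 1]
        x2 = adj[fit.data.epoch_idx == e2 - 1]
        if x1.size < 2 or x2.size < 2:
            rows.append((e1, e2, np.nan, np.nan, np.nan, np.nan, "empty_epoch"))
            continue
        t, p = stats.ttest_ind(x1, x2, equal_var=True)
        v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
        pooled = np.sqrt(
            ((x1.size - 1) * v1 + (x2.size - 1) * v2) / (x1.size + x2.size - 2)
        )
        d = (x1.mean() - x2.mean()) / pooled if pooled > 0 else 0.0
        p_adj = min(1.0, float(p) * family)
        rows.append((e1, e2, float(t), float(p), p_adj, float(d), "ok"))
    return pd.DataFrame(
        rows, columns=["epoch_1", "epoch_2", "t", "p_raw", "p_adj", "cohens_d", "flag"]
    )


class MixedEffectsShotModel(BaseEstimator):
    """Scikit-learn style wrapper around the mixed-effects cross-check.

    ``fit`` accepts a :class:`ModelData` or an annotated DataFrame with
    ``error_mm``, ``epoch`` and ``fish_id`` columns.  Fitted attributes:
    ``fit_``, ``anova_``, ``singular_``, ``random_intercept_var_``.
    """

    def __init__(self, partial_eta2: bool = False):
        self.partial_eta2 = partial_eta2

    def fit(self, X, y=None):
        self.fit_ = fit_mixed(X)
        self.anova_ = anova_eta2(self.fit_, partial=self.partial_eta2)
        self.singular_ = self.fit_.singular
        self.random_intercept_var_ = self.fit_.random_intercept_var
        return self

    def predict(self, X=None):
        """Fitted epoch means (fixed effects only), as a dict epoch -> mm."""
        if not hasattr(self, "fit_"):
            raise RuntimeError("fit the model first")
        return dict(self.fit_.fixed_epoch_means)

    def posthoc(self, pairs):
        return posthoc(self.fit_, pairs)
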