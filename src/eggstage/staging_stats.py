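"""Statistical staging layer.

Chamber growth is exponential, so the natural log of chamber area (LS) is
linear in stage; oocyte fraction (OS) and aspect ratio (CR) also drift
monotonically.  Three tools connect features to stages:

* ordinary least squares of a feature on stage (slope, R², 95% CI band);
* a cumulative-link (proportional-odds) ordinal regression per feature,
  P(stage > k | x) = logistic(βx − α_k), whose intercept/slope quotients
  α_k/β are the feature cutoffs between consecutive stages;
* the stage-8/9 rule: fit a Gaussian to the Δ-distance scores of each
  stage group and classify at the intersection of the two densities —
  equivalent to the likelihood-ratio rule between the fitted Gaussians.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .errors import FitError

FEATURE_COLUMNS = ("log_size", "oocyte_fraction", "chamber_ratio", "delta_to_uniform")


@dataclass
class FeatureVector:
    """Scalar features of one chamber; ``oocyte_fraction`` may be None
    (undefined before stage 6)."""

    log_size: float
    chamber_ratio: float | None = None
    oocyte_fraction: float | None = None
    delta_to_uniform: float | None = None

    def get(self, name: str):
        return getattr(self, name)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    stage_grid: np.ndarray        # sorted unique stages
    ci_lower: np.ndarray          # pointwise 95% CI of the predicted mean
    ci_upper: np.ndarray


@dataclass
class StageModel:
    """Fitted cumulative-logit model for one feature."""

    feature_name: str
    coefficient: float                 # β (> 0 when the feature grows with stage)
    intercepts: np.ndarray             # α_k for k = first_stage .. last_stage-1
    stage_range: list[int]             # contiguous modeled stages
    link: str = "logit"
    flags: dict = field(default_factory=dict)

    def _cdf(self, z):
        if self.link == "logit":
            return expit(z)
        if self.link == "probit":
            return stats.norm.cdf(z)
        raise ValueError(f"unknown link {self.link!r}")

    def prob_greater(self, x: float) -> np.ndarray:
        """P(stage > k | x) for each boundary k."""
        return self._cdf(self.coefficient * x - self.intercepts)

    def stage_probabilities(self, x: float) -> np.ndarray:
        """Per-stage probability vector over ``stage_range``."""
        g = self.prob_greater(x)
        upper = np.concatenate([[1.0], g])
        lower = np.concatenate([g, [0.0]])
        p = np.clip(upper - lower, 0.0, None)
        return p / p.sum()

    def to_json(self) -> dict:
        return {
            "feature_name": self.feature_name,
            "coefficient": self.coefficient,
            "intercepts": self.intercepts.tolist(),
            "stage_range": self.stage_range,
            "link": self.link,
        }

    @classmethod
    def from_json(cls, d: dict) -> "StageModel":
        return cls(
            feature_name=d["feature_name"],
            coefficient=float(d["coefficient"]),
            intercepts=np.asarray(d["intercepts"], dtype=float),
            stage_range=[int(s) for s in d["stage_range"]],
            link=d.get("link", "logit"),
        )


@dataclass
class StagePrediction:
    stage: int
    probabilities: np.ndarray
    stage_range: list[int]
    cutoffs_used: dict
    label: str | None = None           # optional "10A"/"10B" refinement


@dataclass
class GaussianCutoff:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    cutoff: float
    t_statistic: float
    p_value: float
    df: float
    flags: dict = field(default_factory=dict)


def fit_stage_linear(stages, feature) -> LinearFit:
    """OLS of a feature on stage, with R² and the 95% CI of the mean."""
    stages = np.asarray(stages, dtype=float)
    feature = np.asarray(feature, dtype=float)
    if stages.shape != feature.shape:
        raise ValueError("stages and feature must have equal length")
    if len(np.unique(stages)) < 3:
        raise FitError("need >=3 distinct stages for a meaningful regression")
    X = sm.add_constant(stages)
    res = sm.OLS(feature, X).fit()
    grid = np.unique(stages)
    pred = res.get_prediction(sm.add_constant(grid))
    ci = pred.conf_int(alpha=0.05)
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        stage_grid=grid,
        ci_lower=ci[:, 0],
        ci_upper=ci[:, 1],
    )


def _prepare_ordinal(stages, feature):
    stages = np.asarray(stages)
    feature = np.asarray(feature, dtype=float)
    keep = np.isfinite(feature)
    stages, feature = stages[keep], feature[keep]
    uniq, counts = np.unique(stages, return_counts=True)
    if len(uniq) < 2:
        raise FitError("ordinal regression needs >=2 stages")
    if (counts < 2).any():
        raise FitError("each stage needs >=2 samples")
    endog = pd.Series(pd.Categorical(stages, categories=list(uniq), ordered=True))
    return endog, feature, [int(u) for u in uniq]


def fit_ordinal(stages, feature, feature_name: str = "log_size",
                link: str = "logit") -> StageModel:
    """Maximum-likelihood cumulative-link model of stage on one feature.

    Under complete separation the unpenalized MLE diverges; a small ridge
    penalty on the parameters is then applied and the model flagged.
    """
    endog, x, stage_range = _prepare_ordinal(stages, feature)
    model = OrderedModel(endog, x[:, None], distr=link)
    # complete separation: every adjacent stage pair cleanly split on x —
    # the unpenalized MLE then diverges even if the optimizer stops early
    codes = np.asarray(endog.cat.codes)
    separated = all(x[codes == k].max() < x[codes == k + 1].min()
                    for k in range(len(stage_range) - 1))
    with np.errstate(over="ignore"):
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    params = np.asarray(res.params, dtype=float)
    converged = bool(res.mle_retvals.get("converged", True))
    flags = {}
    if separated or not converged or not np.all(np.isfinite(params)) or np.abs(params[0]) > 50:
        # separation: refit with an L2 penalty to keep estimates finite
        n = len(x)

        def penalized(p):
            with np.errstate(over="ignore", invalid="ignore"):
                ll = model.loglike(p)
            if not np.isfinite(ll):
                return 1e12
            return -ll + 0.01 * n * np.sum(p[: 1] ** 2)

        start = np.nan_to_num(np.asarray(params, dtype=float), nan=0.0,
                              posinf=10.0, neginf=-10.0)
        opt = optimize.minimize(penalized, start, method="Nelder-Mead",
                                options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10})
        params = opt.x
        flags["separation_penalized"] = True
    thresholds = model.transform_threshold_params(np.asarray(params))[1:-1]
    return StageModel(
        feature_name=feature_name,
        coefficient=float(np.asarray(params)[0]),
        intercepts=np.asarray(thresholds, dtype=float),
        stage_range=stage_range,
        link=link,
        flags=flags,
    )


def stage_cutoffs(model: StageModel, resolution: float = 0.1) -> dict:
    """Feature value at each stage boundary: x* = α_k / β (P(stage > k) = ½).

    A boundary is reported as unavailable (None) when the gap between its
    adjacent intercepts is below ``resolution`` × the median gap — stages
    whose feature distributions the model cannot tell apart, as happens for
    chamber size between stages 11 and 12.
    """
    if model.coefficient <= 0:
        raise FitError("feature does not increase with stage (β <= 0)")
    cuts = model.intercepts / model.coefficient
    gaps = np.diff(model.intercepts)
    med = float(np.median(gaps)) if len(gaps) else 0.0
    out = {}
    for k, (lo, hi) in enumerate(zip(model.stage_range[:-1], model.stage_range[1:])):
        unavailable = False
        if med > 0:
            near = []
            if k > 0:
                near.append(gaps[k - 1])
            if k < len(gaps):
                near.append(gaps[k])
            unavailable = bool(near) and min(near) < resolution * med
        out[(lo, hi)] = None if unavailable else float(cuts[k])
    return out


def classify_stage(models: list[StageModel] | StageModel,
                   features: FeatureVector) -> StagePrediction:
    """Predict the stage of one chamber from its feature vector.

    The chamber-size model is primary (size is the most stable feature);
    when other models are supplied and their features are defined, their
    per-stage probabilities are averaged in log space.  Models covering a
    sub-range of stages contribute only over that sub-range.
    """
    if isinstance(models, StageModel):
        models = [models]
    by_name = {m.feature_name: m for m in models}
    if "log_size" not in by_name:
        raise FitError("classify_stage requires a log_size model")
    full_range = by_name["log_size"].stage_range
    logp = np.zeros(len(full_range))
    n_used = np.zeros(len(full_range))
    used = []
    for m in models:
        x = features.get(m.feature_name)
        if x is None or not np.isfinite(x):
            continue
        p = m.stage_probabilities(float(x))
        for j, s in enumerate(m.stage_range):
            if s in full_range:
                i = full_range.index(s)
                logp[i] += np.log(max(p[j], 1e-300))
                n_used[i] += 1
        used.append(m.feature_name)
    if "log_size" not in used:
        raise FitError("log_size feature is missing")
    logp = np.where(n_used > 0, logp / np.maximum(n_used, 1), -np.inf)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    cutoffs = {f"{m.feature_name}": {f"{a}-{b}": c for (a, b), c in stage_cutoffs(m).items()}
               for m in models if m.feature_name in used and m.coefficient > 0}
    return StagePrediction(
        stage=int(full_range[int(np.argmax(probs))]),
        probabilities=probs,
        stage_range=full_range,
        cutoffs_used=cutoffs,
    )


def refine_stage_10(prediction: StagePrediction, centripetal) -> StagePrediction:
    """Split a predicted stage 10 into 10A/10B using the centripetal
    migration detector result."""
    if prediction.stage == 10 and getattr(centripetal, "applicable", False):
        prediction.label = "10B" if centripetal.is_stage_10B else "10A"
    else:
        prediction.label = str(prediction.stage)
    return prediction


def two_sample_ttest(group_a, group_b, equal_var: bool = True):
    """Two-sample t test (pooled variance by default, Welch optional).

    Returns (t, df, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise FitError("each group needs >=2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise FitError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def gaussian_intercept_rule(group_a, group_b, equal_var: bool = True) -> GaussianCutoff:
    """Decision cutoff at the intersection of two fitted Gaussian densities.

    Each group is summarized by its sample mean and SD; the cutoff is the
    root of N(x; m_a, s_a) = N(x; m_b, s_b) lying between the means (for
    equal SDs, the midpoint).  Between the means, thresholding at this
    point is exactly the likelihood-ratio rule for the two fitted
    Gaussians.  If no root falls between the means (pathological SDs) the
    midpoint is used and the result flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise FitError("each group needs >=2 observations")
    m1, s1 = float(a.mean()), float(a.std(ddof=1))
    m2, s2 = float(b.mean()), float(b.std(ddof=1))
    if s1 <= 0 or s2 <= 0:
        raise FitError("group SD must be positive")
    flags = {}
    lo, hi = min(m1, m2), max(m1, m2)
    if abs(s1 - s2) < 1e-12 * max(s1, s2):
        cutoff = 0.5 * (m1 + m2)
    else:
        # equal log-densities: quadratic A x² + B x + C = 0
        A = 1.0 / s1**2 - 1.0 / s2**2
        B = -2.0 * (m1 / s1**2 - m2 / s2**2)
        C = m1**2 / s1**2 - m2**2 / s2**2 - 2.0 * np.log(s2 / s1)
        disc = B * B - 4 * A * C
        roots = []
        if disc >= 0:
            sq = np.sqrt(disc)
            roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
        between = [r for r in roots if lo <= r <= hi]
        if between:
            cutoff = float(between[0])
        else:
            cutoff = 0.5 * (m1 + m2)
            flags["no_root_between_means"] = True
    t, df, p = two_sample_ttest(a, b, equal_var=equal_var)
    return GaussianCutoff(mean_a=m1, sd_a=s1, mean_b=m2, sd_b=s2,
                          cutoff=float(cutoff), t_statistic=t, p_value=p,
                          df=df, flags=flags)


def save_models(models: list[StageModel], path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_json() for m in models], fh, indent=2)


def load_models(path) -> list[StageModel]:
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    return [StageModel.from_json(d) for d in data]
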