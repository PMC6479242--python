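"""Average bioequivalence (ABE) for crossover designs.

The analysis follows the FDA (2001) average-bioequivalence convention: the
exposure metric is Ln-transformed and modelled with sequence, period and
treatment as fixed effects and subject as a random effect.  For balanced
complete data this mixed model coincides with the fixed-subject-effects OLS
crossover ANOVA, which is what we fit there (sequence is absorbed by the
subject effects); incomplete data (a subject missing a treatment) fall back
to REML via statsmodels MixedLM.

Reported quantities per contrast: back-transformed (geometric) least-squares
means, their ratio, the 90% CI exp(diff +/- t_{0.95,df} * SE), the
intrasubject CV 100*sqrt(exp(sigma^2_within)-1), and the 0.8-1.25 verdict
(inclusive limits).  For a 3-treatment Latin square all pairwise contrasts
come from the single model fit, unadjusted for multiplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .study_data import CrossoverStudy

__all__ = [
    "BEResult",
    "BE_LIMITS",
    "fit_crossover_model",
    "ratio_of_geometric_means",
    "equivalence_verdict",
    "intra_cv_pct_from_variance",
    "metric_table",
]

#: Regulatory average-bioequivalence limits for the geometric mean ratio.
BE_LIMITS = (0.8, 1.25)


@dataclass
class BEResult:
    """One treatment contrast for one Ln-analysed exposure metric."""

    metric: str
    test: str
    reference: str
    gls_mean_test: float
    gls_mean_reference: float
    ratio: float
    ci90_low: float
    ci90_high: float
    intra_cv_pct: float
    df: float
    bioequivalent: bool


def ratio_of_geometric_means(gls_test: float, gls_reference: float) -> float:
    """Test/reference ratio of geometric least-squares means."""
    if gls_test <= 0 or gls_reference <= 0:
        raise ValueError("geometric LS means must be > 0")
    return gls_test / gls_reference


def equivalence_verdict(
    ci_low: float, ci_high: float, limits: tuple[float, float] = BE_LIMITS
) -> bool:
    """True iff the CI lies within the limits (boundaries inclusive)."""
    if ci_low > ci_high:
        raise ValueError("ci_low must be <= ci_high")
    return limits[0] <= ci_low and ci_high <= limits[1]


def intra_cv_pct_from_variance(sigma2_within: float) -> float:
    """Intrasubject CV%% from the within-subject log-scale variance."""
    if sigma2_within < 0:
        raise ValueError("variance must be >= 0")
    return 100.0 * math.sqrt(math.exp(sigma2_within) - 1.0)


def metric_table(
    study: CrossoverStudy, metric_values: Mapping[tuple[str, str], float] | pd.DataFrame
) -> pd.DataFrame:
    """Assemble the long modelling table subject/sequence/period/treatment/value.

    ``metric_values`` is either a mapping (subject_id, treatment) -> value or
    a DataFrame already holding columns subject/treatment/value (sequence and
    period are then pulled from the study design).
    """
    design = pd.DataFrame(
        [
            (p.subject_id, p.sequence, p.period, p.treatment)
            for p in study.profiles
        ],
        columns=["subject", "sequence", "period", "treatment"],
    )
    if isinstance(metric_values, pd.DataFrame):
        vals = metric_values[["subject", "treatment", "value"]]
    else:
        vals = pd.DataFrame(
            [(s, t, v) for (s, t), v in metric_values.items()],
            columns=["subject", "treatment", "value"],
        )
    merged = design.merge(vals, on=["subject", "treatment"], how="inner")
    return merged.dropna(subset=["value"])


def _ls_means_ols(data: pd.DataFrame) -> tuple[dict[str, float], pd.DataFrame, float, float]:
    """Fixed-effects crossover ANOVA on ln(value).

    Returns (log LS means per treatment, covariance of treatment-effect
    coefficients indexed by treatment, residual variance, residual df).
    Baseline treatment has coefficient 0 with zero (co)variance.
    """
    y = np.log(data["value"].to_numpy(dtype=float))
    subj = pd.get_dummies(data["subject"], drop_first=True, dtype=float)
    per = pd.get_dummies(data["period"].astype(str), drop_first=True, dtype=float)
    trt_d = pd.get_dummies(data["treatment"], drop_first=True, dtype=float)
    treatments = sorted(data["treatment"].unique())
    X = np.column_stack(
        [np.ones(len(data)), subj.to_numpy(), per.to_numpy(), trt_d.to_numpy()]
    )
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(X.T @ X)

    n_sub, n_per = subj.shape[1], per.shape[1]
    # LS mean(T) = b0 + mean over all subject levels + mean over all period
    # levels + treatment effect (baseline level contributes 0)
    base = beta[0]
    base += beta[1 : 1 + n_sub].sum() / (n_sub + 1)
    base += beta[1 + n_sub : 1 + n_sub + n_per].sum() / (n_per + 1)
    trt_cols = {t: 1 + n_sub + n_per + i for i, t in enumerate(trt_d.columns)}
    ls = {}
    for t in treatments:
        ls[t] = float(base + (beta[trt_cols[t]] if t in trt_cols else 0.0))

    cov = pd.DataFrame(0.0, index=treatments, columns=treatments)
    for a in treatments:
        for b in treatments:
            if a in trt_cols and b in trt_cols:
                cov.loc[a, b] = s2 * xtx_inv[trt_cols[a], trt_cols[b]]
    return ls, cov, s2, float(df)


def _ls_means_mixed(data: pd.DataFrame) -> tuple[dict[str, float], pd.DataFrame, float, float]:
    """REML mixed model (subject random; sequence/period/treatment fixed)."""
    import statsmodels.formula.api as smf

    d = data.copy()
    d["lny"] = np.log(d["value"].astype(float))
    d["period"] = d["period"].astype(str)
    model = smf.mixedlm("lny ~ C(sequence) + C(period) + C(treatment)", d, groups=d["subject"])
    fit = model.fit(reml=True, method=["lbfgs", "powell"])

    treatments = sorted(d["treatment"].unique())
    params = fit.fe_params
    cov_fe = fit.cov_params().loc[params.index, params.index]

    def level_coefs(prefix: str) -> list[float]:
        return [params[k] for k in params.index if k.startswith(prefix)]

    base = params["Intercept"]
    for pref in ("C(sequence)", "C(period)"):
        coefs = level_coefs(pref)
        base += sum(coefs) / (len(coefs) + 1)  # +1 for the zero baseline level
    names = {t: f"C(treatment)[T.{t}]" for t in treatments}
    ls = {
        t: float(base + (params[names[t]] if names[t] in params.index else 0.0))
        for t in treatments
    }
    cov = pd.DataFrame(0.0, index=treatments, columns=treatments)
    for a in treatments:
        for b in treatments:
            if names[a] in params.index and names[b] in params.index:
                cov.loc[a, b] = cov_fe.loc[names[a], names[b]]

    # within-subject df by containment counting; equals the fixed-effects
    # residual df (n-2 for 2x2, 2n-4 for the 3x3 Latin square) when balanced
    df = len(d) - d["subject"].nunique() - (d["period"].nunique() - 1) - (len(treatments) - 1)
    return ls, cov, float(fit.scale), float(max(df, 1))


def fit_crossover_model(
    study: CrossoverStudy | None,
    metric_values: Mapping[tuple[str, str], float] | pd.DataFrame,
    contrast: tuple[str, str],
    metric: str = "value",
    limits: tuple[float, float] = BE_LIMITS,
) -> BEResult:
    """Fit the crossover ABE model and evaluate one test/reference contrast.

    Parameters
    ----------
    study
        Supplies the design (sequence/period per subject x treatment).  May
        be None when ``metric_values`` is a DataFrame that already carries
        subject/sequence/period/treatment/value columns.
    metric_values
        Positive metric values per subject x treatment.
    contrast
        ``(test, reference)`` treatment codes.
    """
    test, reference = contrast
    if study is not None:
        data = metric_table(study, metric_values)
    else:
        if not isinstance(metric_values, pd.DataFrame):
            raise ValueError("need a study or a full design DataFrame")
        data = metric_values.dropna(subset=["value"]).copy()

    present = set(data["treatment"].unique())
    if test not in present or reference not in present:
        raise ValueError(f"contrast {contrast} not present in data (have {sorted(present)})")
    if (data["value"] <= 0).any():
        raise ValueError("metric values must be > 0 for Ln-transform")

    counts = data.groupby(["subject", "treatment"]).size()
    if (counts > 1).any():
        raise ValueError("more than one value per subject x treatment")
    n_trt = data["treatment"].nunique()
    complete = (data.groupby("subject")["treatment"].nunique() == n_trt).all()

    if complete:
        ls, cov, s2, df = _ls_means_ols(data)
    else:
        ls, cov, s2, df = _ls_means_mixed(data)

    diff = ls[test] - ls[reference]
    se = math.sqrt(cov.loc[test, test] + cov.loc[reference, reference] - 2 * cov.loc[test, reference])
    tcrit = stats.t.ppf(0.95, df)
    lo, hi = math.exp(diff - tcrit * se), math.exp(diff + tcrit * se)
    gls_t, gls_r = math.exp(ls[test]), math.exp(ls[reference])
    return BEResult(
        metric=metric,
        test=test,
        reference=reference,
        gls_mean_test=gls_t,
        gls_mean_reference=gls_r,
        ratio=ratio_of_geometric_means(gls_t, gls_r),
        ci90_low=lo,
        ci90_high=hi,
        intra_cv_pct=intra_cv_pct_from_variance(s2),
        df=df,
        bioequivalent=equivalence_verdict(lo, hi, limits),
    )
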