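import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pkbridge import (
    BE_LIMITS,
    equivalence_verdict,
    fit_crossover_model,
    intra_cv_pct_from_variance,
    ratio_of_geometric_means,
)


def two_by_two_frame(values):
    """Build a 2x2 crossover table from {subject: (sequence, value_A, value_B)}."""
    rows = []
    for subj, (seq, va, vb) in values.items():
        for period, trt in enumerate(seq, start=1):
            rows.append(
                {
                    "subject": subj,
                    "sequence": seq,
                    "period": period,
                    "treatment": trt,
                    "value": va if trt == "A" else vb,
                }
            )
    return pd.DataFrame(rows)


def crossover_anova_oracle(df, test="A", reference="B"):
    """Closed-form 2x2 crossover ANOVA on ln(value) via sequence differences.

    Independent of the model-matrix implementation: the treatment effect is
    half the difference of the mean period-1-minus-period-2 log differences
    between sequences, with the pooled within-sequence variance of those
    differences providing the standard error (df = n1 + n2 - 2).
    """
    d = df.copy()
    d["lny"] = np.log(d["value"])
    wide = d.pivot_table(index=["subject", "sequence"], columns="period", values="lny")
    wide["diff"] = wide[1] - wide[2]
    seqs = sorted({s for _, s in wide.index})
    assert len(seqs) == 2
    g1 = wide.xs(seqs[0], level="sequence")["diff"]  # test-first sequence order
    g2 = wide.xs(seqs[1], level="sequence")["diff"]
    # sign: in the sequence starting with `test`, diff = +delta + period term
    first1 = seqs[0][0] if len(seqs[0]) == 2 else seqs[0].split("-")[0]
    if first1 != test:
        g1, g2 = g2, g1
    delta = 0.5 * (g1.mean() - g2.mean())
    s2d = ((g1 - g1.mean()) ** 2.0).sum() + ((g2 - g2.mean()) ** 2.0).sum()
    dfree = len(g1) + len(g2) - 2
    s2d /= dfree
    se = math.sqrt(s2d / 4 * (1 / len(g1) + 1 / len(g2)))
    tcrit = stats.t.ppf(0.95, dfree)
    return (
        math.exp(delta),
        math.exp(delta - tcrit * se),
        math.exp(delta + tcrit * se),
        s2d / 2,  # sigma^2_within
        dfree,
    )


class TestRatioAndVerdict:
    @pytest.mark.parametrize(
        "gls_t,gls_r,printed",
        [(11.25, 12.99, 0.866), (1.107, 1.498, 0.739), (12.71, 12.99, 0.978)],
    )
    def test_printed_table_ratios(self, gls_t, gls_r, printed):
        assert round(ratio_of_geometric_means(gls_t, gls_r), 3) == printed

    def test_identity_ratio(self):
        assert ratio_of_geometric_means(3.7, 3.7) == 1.0

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            ratio_of_geometric_means(0.0, 1.0)

    @pytest.mark.parametrize(
        "lo,hi,expected",
        [((0.869), 1.102, True), (0.769, 0.975, False), (0.8, 1.25, True)],
    )
    def test_equivalence_verdict(self, lo, hi, expected):
        assert equivalence_verdict(lo, hi, BE_LIMITS) is expected

    def test_intra_cv_exact_at_20_percent(self):
        assert intra_cv_pct_from_variance(math.log(1.04)) == pytest.approx(20.0, abs=1e-12)


class TestCrossoverModel:
    def test_degenerate_common_log_difference(self):
        # every subject's A/B log-ratio identical, no noise: ratio is exact
        # and the CI collapses to a point
        vals = {
            f"S{i}": ("AB" if i % 2 else "BA", 10.0 * 1.1, 10.0) for i in range(1, 9)
        }
        # vary subject levels but keep the A/B ratio fixed at 1.1
        vals = {
            s: (seq, (3.0 + i) * 1.1, (3.0 + i))
            for i, (s, (seq, _, _)) in enumerate(vals.items())
        }
        df = two_by_two_frame(vals)
        res = fit_crossover_model(None, df, ("A", "B"))
        assert res.ratio == pytest.approx(1.1, rel=1e-12)
        assert res.ci90_high - res.ci90_low == pytest.approx(0.0, abs=1e-9)
        assert res.intra_cv_pct == pytest.approx(0.0, abs=1e-6)

    def test_matches_closed_form_anova_oracle(self):
        rng = np.random.default_rng(42)
        vals = {}
        for i in range(8):
            seq = "AB" if i < 4 else "BA"
            base = math.exp(rng.normal(2.0, 0.4))
            vals[f"S{i:02d}"] = (
                seq,
                base * math.exp(rng.normal(0.05, 0.15)),
                base * math.exp(rng.normal(0.0, 0.15)),
            )
        df = two_by_two_frame(vals)
        res = fit_crossover_model(None, df, ("A", "B"))
        ratio, lo, hi, s2w, dfree = crossover_anova_oracle(df)
        assert res.ratio == pytest.approx(ratio, abs=1e-8)
        assert res.ci90_low == pytest.approx(lo, abs=1e-8)
        assert res.ci90_high == pytest.approx(hi, abs=1e-8)
        assert res.intra_cv_pct == pytest.approx(intra_cv_pct_from_variance(s2w), abs=1e-8)
        assert res.df == dfree

    def _random_frame(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        vals = {}
        for i in range(n):
            seq = "AB" if i % 2 == 0 else "BA"
            base = math.exp(rng.normal(1.0, 0.3))
            vals[f"S{i:02d}"] = (
                seq,
                base * math.exp(rng.normal(-0.1, 0.2)),
                base * math.exp(rng.normal(0.0, 0.2)),
            )
        return two_by_two_frame(vals)

    def test_antisymmetry_of_contrast(self):
        df = self._random_frame(seed=1)
        ab = fit_crossover_model(None, df, ("A", "B"))
        ba = fit_crossover_model(None, df, ("B", "A"))
        assert ab.ratio * ba.ratio == pytest.approx(1.0, abs=1e-10)
        assert ab.ci90_low == pytest.approx(1.0 / ba.ci90_high, abs=1e-10)
        assert ab.ci90_high == pytest.approx(1.0 / ba.ci90_low, abs=1e-10)

    def test_scale_invariance(self):
        df = self._random_frame(seed=2)
        res0 = fit_crossover_model(None, df, ("A", "B"))
        k = 7.5
        df2 = df.copy()
        df2.loc[df2.treatment == "A", "value"] *= k
        res1 = fit_crossover_model(None, df2, ("A", "B"))
        assert res1.gls_mean_test == pytest.approx(k * res0.gls_mean_test, rel=1e-12)
        assert res1.ratio == pytest.approx(k * res0.ratio, rel=1e-12)

    def test_period_effect_does_not_bias_treatment_ratio(self):
        df = self._random_frame(seed=3)
        res0 = fit_crossover_model(None, df, ("A", "B"))
        df2 = df.copy()
        df2.loc[df2.period == 2, "value"] *= math.exp(0.7)  # constant period shift
        res1 = fit_crossover_model(None, df2, ("A", "B"))
        assert res1.ratio == pytest.approx(res0.ratio, rel=1e-10)
        assert res1.ci90_low == pytest.approx(res0.ci90_low, rel=1e-10)

    def test_three_way_latin_square_single_fit_contrasts(self):
        # balanced 6-sequence Williams-type design, all pairwise contrasts
        import itertools

        rng = np.random.default_rng(5)
        seqs = list(itertools.permutations("ABC"))
        rows = []
        effects = {"A": 0.0, "B": -0.1, "C": 0.05}
        for i, seq in enumerate(seqs * 2):
            subj = f"S{i:02d}"
            base = rng.normal(2.0, 0.3)
            for period, trt in enumerate(seq, start=1):
                rows.append(
                    {
                        "subject": subj,
                        "sequence": "".join(seq),
                        "period": period,
                        "treatment": trt,
                        "value": math.exp(base + effects[trt] + rng.normal(0, 0.15)),
                    }
                )
        df = pd.DataFrame(rows)
        res = {
            pair: fit_crossover_model(None, df, pair)
            for pair in [("B", "A"), ("C", "A"), ("B", "C")]
        }
        # contrasts are mutually consistent: (B/A)/(C/A) = B/C
        assert res[("B", "A")].ratio / res[("C", "A")].ratio == pytest.approx(
            res[("B", "C")].ratio, rel=1e-10
        )
        assert res[("B", "A")].df == 2 * 12 - 4

    def test_unbalanced_data_falls_back_to_reml(self):
        df = self._random_frame(seed=7, n=12)
        # drop one subject's treatment A observation -> incomplete
        drop = (df.subject == "S00") & (df.treatment == "A")
        df_unbal = df[~drop].reset_index(drop=True)
        res = fit_crossover_model(None, df_unbal, ("A", "B"))
        full = fit_crossover_model(None, df, ("A", "B"))
        assert res.df == full.df - 1
        assert res.ratio == pytest.approx(full.ratio, rel=0.15)
        assert res.ci90_low < res.ratio < res.ci90_high

    def test_missing_treatment_is_contrast_error(self):
        df = self._random_frame(seed=8)
        with pytest.raises(ValueError, match="contrast"):
            fit_crossover_model(None, df, ("A", "Z"))

    def test_nonpositive_value_is_transform_error(self):
        df = self._random_frame(seed=9)
        df.loc[0, "value"] = 0.0
        with pytest.raises(ValueError, match="> 0"):
            fit_crossover_model(None, df, ("A", "B"))
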