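"""Detection filter, two-factor ANOVA, BH-FDR, the FDR/fold-change gate and
enrichment ranks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.anova import anova_lm

from metabscape import (
    ValidationError,
    apply_gate,
    bh_fdr,
    enrichment_rank,
    filter_detected,
    fit_factor_model,
    fit_tissue_models,
)
from metabscape.simulate import EffectSpec, SyntheticDesign, generate_tissue_cohort

from conftest import make_table


# ----------------------------------------------------------------------
class TestFilterDetected:
    def _arm_table(self, counts):
        """One metabolite with the given non-zero count in each of 4 arms."""
        genotype = ["mutant"] * 8 + ["wildtype"] * 8
        diet = (["fat45"] * 4 + ["fat60"] * 4) * 2
        col = np.concatenate([
            [1.0] * c + [0.0] * (4 - c) for c in counts
        ])
        return make_table(col[:, None], genotype, diet, metabolites=["m"])

    @pytest.mark.parametrize(
        "counts, kept",
        [((3, 3, 3, 2), False), ((3, 3, 3, 3), True), ((0, 0, 0, 0), False),
         ((4, 4, 4, 4), True)],
    )
    def test_per_arm_counting(self, counts, kept):
        table = self._arm_table(counts)
        out = filter_detected(table)
        assert ("m" in out.metabolites) is kept

    def test_idempotent_and_never_grows(self):
        table = generate_tissue_cohort(
            SyntheticDesign(n_metabolites=60, detect_prob=0.6, seed=21)
        ).subset_tissue("striatum")
        once = filter_detected(table)
        twice = filter_detected(once)
        assert twice.metabolites == once.metabolites
        assert len(once.metabolites) <= len(table.metabolites)

    def test_empty_arm_named(self):
        genotype = ["mutant"] * 4 + ["wildtype"] * 4
        diet = ["fat45"] * 4 + ["fat60"] * 4  # no mutant/fat60 arm
        table = make_table(np.ones((8, 1)), genotype, diet)
        with pytest.raises(ValidationError, match="fat60"):
            filter_detected(table)

    def test_requires_single_tissue(self, null_cohort):
        with pytest.raises(ValidationError, match="single-tissue"):
            filter_detected(null_cohort)


# ----------------------------------------------------------------------
class TestFactorModel:
    def _sim(self, seed, n_per_arm=7, effect=1.0, log_sd=0.4, dropout=0.15):
        rng = np.random.default_rng(seed)
        genotype = np.array(["mutant"] * (2 * n_per_arm) + ["wildtype"] * (2 * n_per_arm))
        diet = np.tile(["fat45"] * n_per_arm + ["fat60"] * n_per_arm, 2)
        mu = np.where(genotype == "mutant", np.log(effect), 0.0)
        v = np.exp(5.0 + mu + rng.normal(0, log_sd, len(genotype)))
        v[rng.random(len(v)) < dropout] = 0.0
        return v, genotype, diet

    @pytest.mark.parametrize("ss_type, typ", [("sequential", 1), ("marginal", 2)])
    def test_matches_statsmodels_anova(self, ss_type, typ):
        """Both SS types agree with statsmodels' anova_lm on noisy data with
        non-detections."""
        for seed in range(6):
            v, g, d = self._sim(seed)
            row = fit_factor_model(v, g, d, ss_type=ss_type)
            used = v > 0
            frame = pd.DataFrame(
                {
                    "y": v[used],
                    "g": (g[used] == "mutant").astype(float),
                    "d": (d[used] == "fat60").astype(float),
                }
            )
            ref = anova_lm(smf.ols("y ~ g + d + g:d", data=frame).fit(), typ=typ)
            got = [row.F_genotype, row.F_diet, row.F_interaction]
            assert np.allclose(got, ref["F"][:3])
            assert np.allclose(
                [row.p_genotype, row.p_diet, row.p_interaction], ref["PR(>F)"][:3]
            )

    def test_scale_invariance_of_f_statistics(self):
        v, g, d = self._sim(3)
        a = fit_factor_model(v, g, d)
        b = fit_factor_model(v * 137.5, g, d)
        for key in ("F_genotype", "F_diet", "F_interaction", "p_genotype"):
            assert a[key] == pytest.approx(b[key], rel=1e-9)

    def test_constant_input_degenerate(self):
        v = np.full(16, 3.0)
        g = np.array(["mutant"] * 8 + ["wildtype"] * 8)
        d = np.tile(["fat45"] * 4 + ["fat60"] * 4, 2)
        row = fit_factor_model(v, g, d)
        assert np.isnan(row.F_genotype) and np.isnan(row.p_genotype)

    def test_zero_residual_variance_gives_inf_f(self):
        # exact cell means with no within-cell noise: F = +inf, p = 0
        g = np.array(["mutant"] * 4 + ["wildtype"] * 4)
        d = np.tile(["fat45", "fat45", "fat60", "fat60"], 2)
        v = np.array([2, 2, 2, 2, 1, 1, 1, 1], dtype=float)
        row = fit_factor_model(v, g, d)
        assert np.isinf(row.F_genotype) and row.p_genotype == 0.0

    def test_direction_consistent_with_percent_change(self):
        v, g, d = self._sim(5, effect=1.4)
        row = fit_factor_model(v, g, d)
        assert row.percent_change_genotype > 0
        assert row.genotype_direction == "increased"

    def test_planted_effect_power_and_specificity(self):
        """A 40% genotype increase at n=8/arm, log_sd 0.2 is detected by the
        genotype term and not attributed to diet, in most simulations."""
        hits_g, hits_d = 0, 0
        n_sim = 60
        for seed in range(n_sim):
            v, g, d = self._sim(seed, n_per_arm=8, effect=1.4, log_sd=0.2, dropout=0.0)
            row = fit_factor_model(v, g, d)
            hits_g += row.p_genotype < 0.05
            hits_d += row.p_diet < 0.05
        assert hits_g / n_sim > 0.9  # high power for the planted term
        assert hits_d / n_sim < 0.2  # diet stays near the nominal rate


# ----------------------------------------------------------------------
def _brute_force_bh(p, q_level):
    """Textbook step-up: largest i with p_(i) <= i*q/m is the rejection cut."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    cut = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q_level / m:
            cut = i
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:cut]] = True
    return rejected


class TestBhFdr:
    def test_all_ones(self):
        assert np.all(bh_fdr([1.0] * 5) == 1.0)

    def test_enumerated_example(self):
        # thresholds i*q/m = 0.02, 0.04, 0.06, 0.08, 0.10 at q = 0.10
        p = [0.001, 0.02, 0.03, 0.04, 0.9]
        q = bh_fdr(p)
        assert (q <= 0.10).sum() == 4
        assert np.all(q >= np.asarray(p))

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8),
        st.sampled_from([0.05, 0.10, 0.25]),
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force_step_up(self, p, level):
        q = bh_fdr(p)
        assert np.array_equal(q <= level, _brute_force_bh(p, level))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestApplyGate:
    def _frame(self, p, fc):
        return pd.DataFrame(
            {"metabolite": [f"m{i}" for i in range(len(p))], "p_genotype": p,
             "fold_change": fc}
        )

    def test_fold_change_gate_blocks_small_changes(self):
        out = apply_gate(self._frame([0.001], [1.10]))
        assert not out["passes"].iloc[0]

    def test_symmetric_decrease_passes(self):
        # 0.70 <= 1/1.3 ~= 0.769: passes as decreased
        out = apply_gate(self._frame([0.001], [0.70]))
        assert out["passes"].iloc[0]
        assert out["direction"].iloc[0] == "decreased"

    def test_boundary_arithmetic(self):
        out = apply_gate(self._frame([0.001, 0.001], [1.30, 1.0 / 1.30]))
        assert out["passes"].all()

    def test_fdr_gate(self):
        # only the tiny p survives BH at 10% despite both having large FC
        out = apply_gate(self._frame([1e-4, 0.9], [2.0, 2.0]))
        assert out["passes"].tolist() == [True, False]

    def test_null_gate_selects_nothing(self):
        rng = np.random.default_rng(0)
        out = apply_gate(self._frame(rng.uniform(size=100), np.ones(100)))
        assert out["passes"].sum() == 0


# ----------------------------------------------------------------------
class TestEnrichmentRank:
    def _two_tissue_table(self, striatum_rows, liver_rows, metabolites):
        values = np.vstack([striatum_rows, liver_rows])
        n_st = len(striatum_rows)
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(values))],
                "tissue": ["striatum"] * n_st + ["liver"] * len(liver_rows),
                "genotype": ["mutant"] * len(values),
                "diet": ["fat45"] * len(values),
            }
        )
        frame = pd.DataFrame(
            values, index=pd.Index(samples["sample_id"], name="sample_id"),
            columns=metabolites,
        )
        from metabscape.ingest import PeakTable

        return PeakTable(samples, frame)

    def test_hand_computed_ratios(self):
        mets = ["a", "b", "c", "d", "e"]
        table = self._two_tissue_table(
            np.array([[10.0, 3.0, 1.0, 0.5, 0.1]] * 2),
            np.array([[1.0, 1.0, 1.0, 1.0, 1.0]] * 2),
            mets,
        )
        out = enrichment_rank(table, "striatum", "liver")
        assert out["metabolite"].tolist() == mets
        assert out["rank"].tolist() == [1, 2, 3, 4, 5]
        assert out["ratio"].tolist() == [10.0, 3.0, 1.0, 0.5, 0.1]

    def test_absent_in_denominator_ranks_first(self):
        table = self._two_tissue_table(
            np.array([[5.0, 50.0, 2.0]] * 2),
            np.array([[1.0, 0.0, 1.0]] * 2),
            ["x", "missing_in_liver", "y"],
        )
        out = enrichment_rank(table, "striatum", "liver")
        assert out["metabolite"].iloc[0] == "missing_in_liver"
        assert not np.isfinite(out["ratio"].iloc[0])

    def test_unknown_tissue_rejected(self, null_cohort):
        with pytest.raises(ValidationError):
            enrichment_rank(null_cohort, "striatum", "cortex")


# ----------------------------------------------------------------------
def test_fold_change_parameter_recovery_across_seeds():
    """Planted multiplier 1.5 on 10 striatal metabolites: the mean estimated
    fold change over 40 seeds at n=8/arm, log_sd 0.3 is within 5% of truth."""
    targets = [f"polar_{k:03d}" for k in range(10)]
    est = []
    for seed in range(40):
        design = SyntheticDesign(
            n_mutant=16, n_wildtype=16, tissues=("striatum",),
            n_metabolites=30, fraction_lipid=0.0, detect_prob=1.0, log_sd=0.3,
            effects=(EffectSpec(targets, ("striatum",), "genotype", 1.5),),
            seed=1000 + seed,
        )
        table = generate_tissue_cohort(design)
        res = fit_tissue_models(table).set_index("metabolite")
        est.append(
            1.0 + res.loc[targets, "percent_change_genotype"].mean() / 100.0
        )
    assert np.mean(est) == pytest.approx(1.5, rel=0.05)
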