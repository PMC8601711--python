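"""Pass counting, block aggregation, information criteria and model fits."""

import json
import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from batrack.glmm import (DegenerateDataError, Gaussian, Poisson, fit_glmm)
from batrack.simulate import (CallParamSimParams, CountSimParams,
                              simulate_call_params, simulate_counts)
from batrack.stats import (ModelResult, SparseDataError, aggregate_blocks,
                           aicc, bonferroni, composition_table,
                           count_passes, fit_call_param_model,
                           fit_count_model, fit_trajectory_models, lrt,
                           model_select, percent_reduction)


class TestCountPasses:
    def test_gap_above_one_second_starts_new_pass(self):
        assert count_passes([0.0, 0.3, 0.5, 2.0]) == 2

    def test_all_gaps_within_one_second_single_pass(self):
        assert count_passes([0.0, 0.9, 1.8, 2.7]) == 1

    def test_empty_input(self):
        assert count_passes([]) == 0

    def test_exactly_one_second_gap_does_not_split(self):
        assert count_passes([0.0, 1.0, 2.0]) == 1

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            count_passes([1.0, 0.5])


def make_files(count_per_file=1, n_files=30, blocks=(1, 2)):
    rows = []
    for b in blocks:
        for f in range(1, n_files + 1):
            rows.append(("site1", "night1", b, f, "P. pygmaeus", "pass",
                         count_per_file))
    return pd.DataFrame(rows, columns=["site", "night", "block", "file",
                                       "species_group", "event_type", "count"])


class TestAggregateBlocks:
    def test_thirty_unit_files_sum_to_24(self):
        out = aggregate_blocks(make_files(1))
        assert (out["count"] == 24).all()

    def test_all_zero_files(self):
        out = aggregate_blocks(make_files(0))
        assert (out["count"] == 0).all()

    def test_events_only_in_first_minute_are_excluded(self):
        files = make_files(0, blocks=(1,))
        files.loc[files["file"] <= 6, "count"] = 5
        out = aggregate_blocks(files)
        assert (out["count"] == 0).all()

    def test_wrong_file_count_names_the_block(self):
        files = make_files(1, blocks=(1, 2))
        files = files[~((files["block"] == 2) & (files["file"] == 30))]
        with pytest.raises(ValueError, match="night1/2"):
            aggregate_blocks(files)

    def test_treatment_derived_from_alternation(self):
        out = aggregate_blocks(make_files(1, blocks=(1, 2, 3, 4)))
        sched = dict(zip(out["block"], out["treatment"]))
        assert sched == {1: "control", 2: "deterrent",
                         3: "control", 4: "deterrent"}

    def test_missing_column_is_named(self):
        with pytest.raises(ValueError, match="file"):
            aggregate_blocks(make_files(1).drop(columns=["file"]))


class TestInformationCriteria:
    def test_aicc_arithmetic(self):
        assert aicc(-50.0, 2, 10) == pytest.approx(104.0 + 12.0 / 7.0)

    def test_aicc_requires_enough_observations(self):
        with pytest.raises(ValueError):
            aicc(-50.0, 4, 5)

    def _mr(self, ll, k, n=100):
        return ModelResult("m", "gaussian", "identity", pd.DataFrame(),
                           pd.DataFrame(), ll, aicc(ll, k, n), n, k)

    def test_richer_model_needs_aicc_improvement_above_2(self):
        simple = self._mr(-50.0, 2)
        richer_small_gain = self._mr(-49.2, 3)  # dAICc < 2
        name, chosen, _ = model_select([("simple", simple),
                                        ("richer", richer_small_gain)])
        assert name == "simple"

    def test_richer_model_kept_when_clearly_better(self):
        simple = self._mr(-50.0, 2)
        richer = self._mr(-45.0, 3)
        name, chosen, _ = model_select([("simple", simple), ("richer", richer)])
        assert name == "richer"

    def test_lrt_identical_logliks(self):
        chi2, df, p = lrt(self._mr(-50.0, 3), self._mr(-50.0, 2))
        assert chi2 == 0.0 and df == 1 and p == 1.0

    def test_lrt_chi2_3_84_is_p_05(self):
        full = self._mr(-50.0, 3)
        red = self._mr(-50.0 - 3.84 / 2.0, 2)
        chi2, df, p = lrt(full, red)
        assert chi2 == pytest.approx(3.84)
        assert p == pytest.approx(0.0500, abs=5e-4)

    def test_lrt_rejects_non_nested(self):
        with pytest.raises(ValueError):
            lrt(self._mr(-50.0, 2), self._mr(-49.0, 2))
        with pytest.raises(ValueError):
            lrt(self._mr(-50.0, 3, n=100), self._mr(-51.0, 2, n=99))

    def test_bonferroni_arithmetic_and_cap(self):
        assert bonferroni(0.01, 6) == pytest.approx(0.06)
        assert bonferroni(0.5, 6) == 1.0


class TestDescriptives:
    def printed_counts(self):
        # the field composition: 5440 passes over 9 nights
        rows = []
        passes = {"P. pygmaeus": 4304, "Myotis spp.": 727,
                  "P. pipistrellus": 323, "other": 86}
        night = 0
        for sp, total in passes.items():
            base, rem = divmod(total, 9)
            for n in range(9):
                rows.append((f"site{n // 3 + 1}", f"night{n + 1}", 1,
                             "control", sp, "pass",
                             base + (1 if n < rem else 0)))
        return pd.DataFrame(rows, columns=["site", "night", "block",
                                           "treatment", "species_group",
                                           "event_type", "count"])

    def test_composition_reproduces_percentages_and_night_mean(self):
        table, summary = composition_table(self.printed_counts())
        assert summary["grand_total"] == 5440
        assert summary["per_night_mean"] == pytest.approx(604.44, abs=0.005)
        pct = dict(zip(table["species_group"], table["percent"]))
        assert pct["P. pygmaeus"] == pytest.approx(79.12, abs=0.005)
        assert float(table["percent"].sum()) == pytest.approx(100.0, abs=0.05)

    def test_single_species_is_100_percent(self):
        df = self.printed_counts()
        df = df[df["species_group"] == "P. pygmaeus"]
        table, _ = composition_table(df)
        assert table["percent"].iloc[0] == 100.0

    def test_percent_reduction_arithmetic(self):
        df = pd.DataFrame({
            "treatment": ["control", "deterrent"],
            "species_group": ["x", "x"], "event_type": ["pass", "pass"],
            "count": [100, 70],
        })
        assert percent_reduction(df)["raw_pct"] == pytest.approx(30.0)
        df["count"] = [70, 70]
        assert percent_reduction(df)["raw_pct"] == 0.0
        df["count"] = [70, 100]
        assert percent_reduction(df)["raw_pct"] == pytest.approx(-42.857, abs=0.01)


class TestCountModel:
    def test_sparse_species_refused(self):
        counts = simulate_counts(CountSimParams(seed=1))
        with pytest.raises(SparseDataError, match="majority of nights"):
            fit_count_model(counts, "Nyctalus/Eptesicus")

    def test_rate_ratio_recovered_on_one_realisation(self):
        params = CountSimParams(
            rates={("P. pygmaeus", "pass"): (46.0, 0.70)},
            sd_site=0.0, sd_night=0.0, sd_block=0.0, seed=42)
        res = fit_count_model(simulate_counts(params), "P. pygmaeus")
        ratio = float(np.exp(res.coef("treatment[deterrent]")))
        assert 0.55 < ratio < 0.85
        assert res.lrt_treatment["p"] < 0.05

    def test_variance_percentages_sum_to_100(self):
        counts = simulate_counts(CountSimParams(seed=7))
        res = fit_count_model(counts, "P. pygmaeus")
        assert res.random["pct_of_total"].sum() == pytest.approx(100.0)


class TestTrajectoryModels:
    def synth_metrics(self, seed=0, effect=0.32, n_per_block=4):
        rng = np.random.default_rng(seed)
        rows = []
        night = 0
        for s in range(3):
            for n in range(3):
                night += 1
                for b in range(1, 13):
                    treatment = "control" if b % 2 == 1 else "deterrent"
                    for _ in range(n_per_block):
                        speed = 4.54 + effect * (treatment == "deterrent") \
                            + rng.normal(0, 0.9)
                        tort = np.clip(rng.normal(0.12, 0.04), 0.101, 0.9)
                        rows.append(dict(
                            site=f"site{s+1}", night=f"night{night}", block=b,
                            treatment=treatment, mean_speed_ms=speed,
                            total_length_m=max(0.4, rng.normal(2.5, 1.5)),
                            net_displacement_m=1.0, tortuosity=tort,
                            mean_y_m=rng.uniform(6, 25),
                            distance_from_deterrent_m=rng.uniform(21, 40),
                            mean_height_m=rng.normal(0.5, 1.5),
                            n_localisations=15, n_segments=14))
        return pd.DataFrame(rows)

    def test_speed_effect_recovered(self):
        out = fit_trajectory_models(self.synth_metrics(seed=3))
        res = out["speed"]
        est = res.fixed.loc[res.fixed["term"].str.contains("treatment"),
                            "estimate"].iloc[0]
        assert est == pytest.approx(0.32, abs=0.15)
        assert res.lrt_treatment["p"] < 0.01
        assert set(out) == {"speed", "distance", "height", "length",
                            "tortuosity"}
        assert out["height"].extra["boxcox_lambda"] is not None

    def test_degenerate_tortuosity_reported_cleanly(self):
        df = self.synth_metrics(seed=1)
        df["tortuosity"] = 0.1
        with pytest.raises(DegenerateDataError, match="variance"):
            fit_trajectory_models(df)

    def test_gaussian_null_lrt_p_values_uniform(self):
        from batrack.stats import _lmm_with_treatment_lrt
        ps = []
        for seed in range(100):
            df = self.synth_metrics(seed=seed + 500, effect=0.0,
                                    n_per_block=2)
            df["block_order"] = (df["block"] - 6.5) / 5.5
            df["speed"] = df["mean_speed_ms"]
            res = _lmm_with_treatment_lrt(df, "speed", ["treatment",
                                                        "block_order"],
                                          ["block_order"],
                                          ["night", "block"], "speed")
            ps.append(res.lrt_treatment["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestCallParamModel:
    def test_bonferroni_attached_and_shift_recovered(self):
        calls = simulate_call_params(CallParamSimParams(seed=10), 150)
        res = fit_call_param_model(calls, "bandwidth")
        assert res.lrt_treatment["p_adjusted"] == pytest.approx(
            min(1.0, 6 * res.lrt_treatment["p"]))
        shift = res.coef("treatment[deterrent]")
        assert shift == pytest.approx(-5.79, abs=1.0)
        assert res.random["pct_of_total"].sum() == pytest.approx(100.0)

    def test_too_few_passes_refused(self):
        calls = simulate_call_params(CallParamSimParams(seed=0), 2)
        calls = calls[~((calls["treatment"] == "deterrent")
                        & (calls["sequence"] != calls["sequence"].iloc[-1]))]
        with pytest.raises(SparseDataError):
            fit_call_param_model(calls, "bandwidth")


class TestAgainstReferenceImplementation:
    def test_poisson_glmm_matches_lme4_laplace(self, tmp_path):
        """Same tiny dataset, same model: our Laplace fit vs glmer's."""
        counts = simulate_counts(CountSimParams(
            rates={("P. pygmaeus", "pass"): (20.0, 0.7)},
            sd_site=0.3, sd_night=0.2, sd_block=0.0, dispersion=np.inf,
            seed=8))
        sub = counts[(counts.species_group == "P. pygmaeus")]
        y = sub["count"].to_numpy(float)
        X = np.column_stack([np.ones(len(sub)),
                             (sub["treatment"] == "deterrent").astype(float)])
        groups = {"site": sub["site"].to_numpy(),
                  "night": (sub["site"] + ":" + sub["night"]).to_numpy()}
        ours = fit_glmm(y, X, groups, Poisson(), fe_names=["int", "treat"])

        csv = tmp_path / "counts.csv"
        sub.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$treat <- as.integer(d$treatment == "deterrent")
            m <- glmer(count ~ treat + (1|site) + (1|site:night),
                       data = d, family = poisson)
            cat(jsonlite::toJSON(list(beta = unname(fixef(m)),
                                      ll = as.numeric(logLik(m)))))
        """)
        script = tmp_path / "fit.R"
        script.write_text(rscript)
        out = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        assert ours.beta[0] == pytest.approx(ref["beta"][0], abs=0.02)
        assert ours.beta[1] == pytest.approx(ref["beta"][1], abs=0.02)
        assert ours.loglik == pytest.approx(ref["ll"][0], abs=0.5)
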