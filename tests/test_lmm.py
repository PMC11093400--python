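"""Crossed mixed-effects model: deviation coding, exact balanced REML,
independent oracles (lmerTest, statsmodels, paired t), interaction model,
per-ROI FDR models, and overlap statistics."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gsspipe.experiments import simulate_psc_table
from gsspipe.lmm import (deviation_code, fit_interaction_lmm, fit_network_lmm,
                         fit_roi_models, localizer_scope_effect, network_overlap)


def _balanced_table(rng, S=10, R=6, beta=0.1, noise=0.2):
    t = simulate_psc_table(rng, n_subjects=S, n_rois=R, beta=beta,
                           resid_sd=noise)
    return t


class TestDeviationCoding:
    def test_explicit_mapping(self):
        df = pd.DataFrame({"condition": ["L1_after_L1", "L1_after_L2"]})
        out = deviation_code(df, codes={"L1_after_L1": -0.5, "L1_after_L2": 0.5})
        assert list(out.condition_code) == [-0.5, 0.5]

    def test_balanced_mean_code_zero(self):
        df = pd.DataFrame({"condition": ["a", "b"] * 10})
        assert deviation_code(df).condition_code.mean() == 0.0

    def test_three_levels_rejected(self):
        df = pd.DataFrame({"condition": ["a", "b", "c"]})
        with pytest.raises(ValueError, match="2 levels"):
            deviation_code(df)


class TestBalancedFit:
    def test_noiseless_constant_difference_exact(self):
        rows = []
        for s in range(6):
            for r in range(4):
                for x in (-0.5, 0.5):
                    rows.append(("s%d" % s, r, x, 1.0 + 0.07 * x))
        t = pd.DataFrame(rows, columns=["subject", "roi", "condition_code", "psc"])
        fit = fit_network_lmm(t)
        assert fit.beta == pytest.approx(0.07, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-10) for v in fit.vc.values())

    def test_deviation_coding_identity(self, rng):
        # balanced data: the fixed effect equals the raw condition-mean
        # difference, whatever the random-effects structure estimates
        t = _balanced_table(rng)
        fit = fit_network_lmm(t)
        means = t.groupby("condition_code")["psc"].mean()
        assert fit.beta == pytest.approx(means[0.5] - means[-0.5], abs=1e-12)
        assert fit.intercept == pytest.approx(means.mean(), abs=1e-12)

    def test_simplification_trace_deterministic(self, rng):
        t = _balanced_table(rng)
        f1 = fit_network_lmm(t)
        f2 = fit_network_lmm(t)
        assert f1.trace == f2.trace
        assert f1.se == f2.se

    def test_preconditions(self, rng):
        t = _balanced_table(rng)
        with pytest.raises(ValueError, match="2 subjects"):
            fit_network_lmm(t[t.subject == "s0"])
        with pytest.raises(ValueError, match="2 ROIs"):
            fit_network_lmm(t[t.roi == "r0"])
        bad = t.copy()
        bad["condition_code"] = 1.0
        with pytest.raises(ValueError, match="deviation-coded"):
            fit_network_lmm(bad)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available")
    def test_matches_lmerTest_oracle(self, rng, tmp_path):
        t = _balanced_table(rng, S=12, R=8, beta=0.07)
        fit = fit_network_lmm(t)
        csv = tmp_path / "table.csv"
        t.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(lmerTest))
d <- read.csv("{csv}")
m <- lmer(psc ~ condition_code + (condition_code || subject)
          + (condition_code || roi), data = d, REML = TRUE)
co <- summary(m)$coefficients["condition_code", ]
cat(sprintf("%.10f %.10f %.6f %.10f\\n", co["Estimate"],
    co["Std. Error"], co["df"], co["Pr(>|t|)"]))
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.split()
        beta_r, se_r, df_r, p_r = map(float, out)
        assert fit.beta == pytest.approx(beta_r, rel=1e-6)
        assert fit.se == pytest.approx(se_r, rel=1e-3)
        assert fit.df == pytest.approx(df_r, rel=0.02)
        assert fit.p == pytest.approx(p_r, rel=0.02)

    def test_unbalanced_fallback_agrees_with_balanced_path(self, rng):
        # drop one row -> statsmodels MixedLM path; the estimate should stay
        # close to the balanced closed form on the full table
        t = _balanced_table(rng, S=10, R=4, beta=0.2, noise=0.1)
        full = fit_network_lmm(t)
        part = fit_network_lmm(t.iloc[:-1])
        assert part.method == "mixedlm_vc"
        assert full.method == "balanced_reml"
        assert part.beta == pytest.approx(full.beta, abs=3 * full.se / 10)


class TestInteraction:
    def _two_net_table(self, rng, delta_a=0.1, delta_b=0.0, S=12, Ra=4, Rb=4,
                      noise=0.05):
        rows = []
        for s in range(S):
            for net, R, d in (("netA", Ra, delta_a), ("netB", Rb, delta_b)):
                for r in range(R):
                    roi = f"{net}_r{r}"
                    base = rng.normal(1.0, 0.1)
                    for x in (-0.5, 0.5):
                        rows.append((f"s{s}", roi, net, x,
                                     base + d * x + rng.normal(0, noise)))
        return pd.DataFrame(rows, columns=["subject", "roi", "network",
                                           "condition_code", "psc"])

    def test_planted_effect_in_one_network_sign(self, rng):
        t = self._two_net_table(rng, delta_a=0.1, delta_b=0.0)
        fit = fit_interaction_lmm(t)
        # netA codes -0.5: an A-only effect makes the interaction negative
        assert fit.beta < 0
        assert fit.beta == pytest.approx(-0.1, abs=0.05)

    def test_symmetric_effects_give_null_interaction(self, rng):
        t = self._two_net_table(rng, delta_a=0.1, delta_b=0.1)
        fit = fit_interaction_lmm(t)
        assert abs(fit.beta) < 3 * fit.se

    def test_permutation_null_centred_at_zero(self, rng):
        t = self._two_net_table(rng, delta_a=0.12, delta_b=0.12, noise=0.1)
        betas = []
        rois = sorted(t.roi.unique())
        for _ in range(40):
            perm = rng.permutation(len(rois))
            net_map = {roi: ("netA" if i < len(rois) // 2 else "netB")
                       for roi, i in zip(rois, perm)}
            tp = t.copy()
            tp["network"] = tp["roi"].map(net_map)
            betas.append(fit_interaction_lmm(tp).beta)
        betas = np.asarray(betas)
        assert abs(betas.mean()) < 3 * betas.std(ddof=1) / np.sqrt(betas.size)

    def test_one_network_rejected(self, rng):
        t = self._two_net_table(rng)
        with pytest.raises(ValueError, match="two networks"):
            fit_interaction_lmm(t[t.network == "netA"])


class TestPerROIModels:
    def test_zero_difference_gives_t0_p1(self):
        rows = []
        for s in range(8):
            for x in (-0.5, 0.5):
                rows.append((f"s{s}", "r0", "net", x, 1.0))
        t = pd.DataFrame(rows, columns=["subject", "roi", "network",
                                        "condition_code", "psc"])
        out = fit_roi_models(t)
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p"] == 1.0

    def test_t_matches_paired_t_oracle(self, rng):
        t = simulate_psc_table(rng, n_subjects=15, n_rois=3, beta=0.1)
        out = fit_roi_models(t).set_index("roi")
        for roi, sub in t.groupby("roi"):
            wide = sub.pivot_table(index="subject", columns="condition_code",
                                   values="psc")
            t_exp, p_exp = stats.ttest_rel(wide[0.5], wide[-0.5])
            assert out.loc[roi, "t"] == pytest.approx(t_exp)
            assert out.loc[roi, "p"] == pytest.approx(p_exp)

    def test_planted_rois_discovered_at_fdr(self):
        # strong signal in 4 of 20 ROIs: discoveries should include all four
        # in >= 90% of simulations
        rng = np.random.default_rng(77)
        hits = 0
        n_sims = 100
        for _ in range(n_sims):
            rows = []
            for s in range(16):
                for r in range(20):
                    d = 0.5 if r < 4 else 0.0
                    for x in (-0.5, 0.5):
                        rows.append((f"s{s}", r, "net", x,
                                     d * x + rng.normal(0, 0.2)))
            t = pd.DataFrame(rows, columns=["subject", "roi", "network",
                                            "condition_code", "psc"])
            out = fit_roi_models(t, alpha=0.05)
            found = set(out[out.significant].roi)
            hits += {0, 1, 2, 3} <= found
        assert hits / n_sims >= 0.90


class TestOverlapAndScope:
    def test_identical_atlases_dice_one(self, rng):
        labels = (rng.uniform(size=(8, 8, 8)) < 0.3).astype(int)
        assert network_overlap(labels, labels)["dice"] == pytest.approx(1.0)

    def test_disjoint_atlases_dice_zero(self):
        a = np.zeros((6, 6, 6), int); a[:3] = 1
        b = np.zeros((6, 6, 6), int); b[4:] = 1
        assert network_overlap(a, b)["dice"] == 0.0

    def test_dice_matches_bruteforce(self, rng):
        a = (rng.uniform(size=(8, 8, 8)) < 0.4).astype(int)
        b = (rng.uniform(size=(8, 8, 8)) < 0.4).astype(int)
        res = network_overlap(a, b)
        inter = sum(1 for idx in np.ndindex(8, 8, 8) if a[idx] and b[idx])
        assert res["dice"] == pytest.approx(2 * inter / (a.sum() + b.sum()))
        assert res["shared_voxels"] == inter

    def test_single_roi_scope_equals_paired_difference(self, rng):
        rows = []
        for s in range(12):
            base = rng.normal(1.0, 0.3)
            rows.append((f"s{s}", 1, "net", "task", base + rng.normal(0.5, 0.1)))
            rows.append((f"s{s}", 1, "net", "control", base))
        t = pd.DataFrame(rows, columns=["subject", "roi", "network",
                                        "condition", "psc"])
        fit = localizer_scope_effect(t, codes={"control": -0.5, "task": 0.5})
        wide = t.pivot_table(index="subject", columns="condition", values="psc")
        diff = wide["task"] - wide["control"]
        assert fit.beta == pytest.approx(diff.mean(), abs=1e-10)
        t_exp, p_exp = stats.ttest_1samp(diff, 0.0)
        assert fit.t == pytest.approx(t_exp, rel=1e-6)
        assert fit.df == pytest.approx(len(diff) - 1, rel=1e-6)
        assert fit.p == pytest.approx(p_exp, rel=1e-6)
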