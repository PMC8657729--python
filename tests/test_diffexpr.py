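"""Moderated-t, BH, and probeset-collapsing behaviour.

The moderated t is checked three ways: against a hand-computed posterior
formula with a pinned prior, against its two limits (ordinary t as d0 -> 0,
common-variance z as d0 -> inf), and against the limma reference
implementation run through Rscript on the same matrix.
"""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from xsci.diffexpr import (
    EBayesPrior,
    benjamini_hochberg,
    collapse_probesets,
    estimate_prior,
    fit_moderated_t,
    trigamma_inverse,
)
from xsci.io import ExpressionStudy
from xsci.simulate import SimulationConfig, simulate_dataset, simulate_studies


def _study(matrix: np.ndarray, n1: int, n2: int, annot=None) -> ExpressionStudy:
    cols = [f"i{k}" for k in range(n1)] + [f"c{k}" for k in range(n2)]
    mat = pd.DataFrame(matrix, columns=cols,
                       index=[f"ps{r}" for r in range(matrix.shape[0])])
    groups = {c: ("injured" if c.startswith("i") else "control") for c in cols}
    return ExpressionStudy("t", "rat", mat, groups, annot or {})


def brute_force_bh(p):
    """Step-up definition evaluated literally: adj_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        out[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)), 1.0
        )
    return out


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_single_p_identity(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3] * 7), [0.3] * 7)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 51))
            p = rng.uniform(size=n)
            np.testing.assert_allclose(benjamini_hochberg(p), brute_force_bh(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        p = rng.uniform(size=40)
        np.testing.assert_allclose(
            benjamini_hochberg(p), multipletests(p, method="fdr_bh")[1]
        )

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=60)
    def test_properties(self, p):
        adj = benjamini_hochberg(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [0.01, 0.3, 1.0, 5.0, 50.0])
    def test_roundtrip(self, x):
        from scipy.special import polygamma
        y = float(polygamma(1, x))
        assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestModeratedT:
    def test_identical_arms_give_zero(self):
        mat = np.tile(np.array([[5.0, 6.0, 7.0, 5.0, 6.0, 7.0]]), (4, 1))
        mat += np.random.default_rng(1).normal(0, 0.1, mat.shape)
        mat[0, :3] = mat[0, 3:]  # probeset 0: injured == control exactly
        res, _ = fit_moderated_t(_study(mat, 3, 3))
        assert res.loc["ps0", "log2fc"] == 0.0
        assert res.loc["ps0", "t_mod"] == 0.0

    def test_pinned_prior_matches_hand_formula(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(7, 1, size=(5, 8))
        n1 = n2 = 4
        prior = EBayesPrior(d0=4.0, s0_sq=0.04)
        res, _ = fit_moderated_t(_study(mat, n1, n2), prior=prior)
        d = n1 + n2 - 2
        for r in range(5):
            x1, x2 = mat[r, :n1], mat[r, n1:]
            fc = x1.mean() - x2.mean()
            s2 = (((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()) / d
            s2_post = (prior.d0 * prior.s0_sq + d * s2) / (prior.d0 + d)
            t = fc / math.sqrt(s2_post * (1 / n1 + 1 / n2))
            assert res["t_mod"].iloc[r] == pytest.approx(t, abs=1e-10)
            p = 2 * stats.t.sf(abs(t), df=prior.d0 + d)
            assert res["p"].iloc[r] == pytest.approx(p, abs=1e-12)

    def test_null_type_one_error_within_binomial_bounds(self):
        cfg = SimulationConfig(
            seed=20, n_genes=100, frac_consistent=0.0, frac_opposite=0.0,
            effect_log2fc=0.0, noise_sd=0.5,
            species_plan=(("null_study", "rat", 4, 4),),
        )
        studies, _ = simulate_studies(cfg)
        res, _ = fit_moderated_t(studies[0])
        m = len(res)
        assert m >= 150  # 100 genes x 1-3 probesets each
        frac = float((res["p"] < 0.05).mean())
        half_width = 2.576 * math.sqrt(0.05 * 0.95 / m)
        assert abs(frac - 0.05) <= half_width

    def test_limits_of_the_shrinkage(self):
        """d0 -> 0 recovers the ordinary two-sample t; d0 -> inf the
        common-variance statistic."""
        rng = np.random.default_rng(3)
        mat = rng.normal(6, 1, size=(10, 8))
        study = _study(mat, 4, 4)
        tiny, _ = fit_moderated_t(study, prior=EBayesPrior(d0=1e-9, s0_sq=0.5))
        t_ord = stats.ttest_ind(mat[:, :4], mat[:, 4:], axis=1).statistic
        np.testing.assert_allclose(tiny["t_mod"], t_ord, rtol=1e-5)
        huge, _ = fit_moderated_t(study, prior=EBayesPrior(d0=1e12, s0_sq=0.5))
        z = (mat[:, :4].mean(1) - mat[:, 4:].mean(1)) / math.sqrt(0.5 * (0.25 + 0.25))
        np.testing.assert_allclose(huge["t_mod"], z, rtol=1e-5)

    def test_ci_brackets_fc_and_p_adj_dominates_p(self, toy_study):
        res, _ = fit_moderated_t(toy_study)
        assert (res["ci_low"] <= res["log2fc"]).all()
        assert (res["log2fc"] <= res["ci_high"]).all()
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        nz = res["log2fc"] != 0
        assert (np.sign(res.loc[nz, "t_mod"]) == np.sign(res.loc[nz, "log2fc"])).all()

    def test_all_zero_variance_is_degenerate(self):
        mat = np.tile(np.array([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]]), (3, 1))
        with pytest.raises(ValueError, match="zero variance"):
            fit_moderated_t(_study(mat, 3, 3))

    def test_matches_limma_reference(self, tmp_path):
        """The whole fit — hyperparameters, t, p — against limma via Rscript."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not found; limma cross-check cannot run")
        rng = np.random.default_rng(11)
        mat = rng.normal(7, 1, size=(60, 8))
        mat[:10, :4] += 1.5
        study = _study(mat, 4, 4)
        res, prior = fit_moderated_t(study)
        study.matrix.to_csv(tmp_path / "x.tsv", sep="\t")
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{tmp_path}/x.tsv", row.names=1))\n'
            'design <- cbind(Intercept=1, injured=c(rep(1,4), rep(0,4)))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'out <- data.frame(t=fit$t[,"injured"], p=fit$p.value[,"injured"])\n'
            f'write.table(format(out, digits=15), "{tmp_path}/r.tsv", '
            'sep="\\t", quote=FALSE)\n'
            'cat(fit$df.prior, fit$s2.prior, "\\n")\n'
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        d0_r, s0_r = map(float, proc.stdout.split())
        assert prior.d0 == pytest.approx(d0_r, rel=1e-5)
        assert prior.s0_sq == pytest.approx(s0_r, rel=1e-5)
        r = pd.read_csv(tmp_path / "r.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(res["t_mod"], r["t"], rtol=1e-9)
        np.testing.assert_allclose(res["p"], r["p"], rtol=1e-9)


class TestCollapseProbesets:
    def test_single_probeset_identity(self, toy_study):
        res, _ = fit_moderated_t(toy_study)
        collapsed = collapse_probesets(res)
        assert collapsed.loc["GeneB", "probeset_id"] == "ps2"
        pd.testing.assert_series_equal(
            collapsed.loc["GeneB", res.columns.drop("gene")],
            res.loc["ps2", res.columns.drop("gene")],
            check_names=False,
        )

    def test_highest_mean_expression_wins(self):
        res = pd.DataFrame(
            {"gene": ["G", "G"], "mean_expr": [7.1, 9.3], "p": [0.1, 0.9]},
            index=pd.Index(["psA", "psB"], name="probeset_id"),
        )
        assert collapse_probesets(res).loc["G", "probeset_id"] == "psB"

    def test_tie_broken_by_smallest_probeset_id(self):
        res = pd.DataFrame(
            {"gene": ["G", "G"], "mean_expr": [7.0, 7.0]},
            index=pd.Index(["psB", "psA"], name="probeset_id"),
        )
        assert collapse_probesets(res).loc["G", "probeset_id"] == "psA"

    def test_unmapped_probesets_dropped(self, toy_study):
        res, _ = fit_moderated_t(toy_study)
        collapsed = collapse_probesets(res)
        assert "ps5" not in collapsed["probeset_id"].values
        assert set(collapsed.index) == {"GeneA", "GeneB", "GeneC"}

    def test_planted_winner_recovered_everywhere(self, small_dataset):
        """The generator elevates one probeset per gene; collapsing must pick
        exactly that probeset for every gene in every study."""
        for study in small_dataset.studies:
            res, _ = fit_moderated_t(study)
            collapsed = collapse_probesets(res)
            planted = small_dataset.representative_probesets[study.study_id]
            src_of = study.probeset_to_gene
            for gene, ps in planted.items():
                assert collapsed.loc[src_of[ps], "probeset_id"] == ps
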