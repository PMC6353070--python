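"""Moderated t, empirical-Bayes prior, BH adjustment, consensus averaging."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats as sps

from metaproteo.stats import (
    EbPrior,
    bh_adjust,
    consensus_matrix,
    fit_eb_prior,
    moderated_t_test,
    summarize_counts,
    trigamma_inverse,
)


def two_group_labels(n1=4, n2=4):
    cols = [f"d{i}" for i in range(n1)] + [f"r{i}" for i in range(n2)]
    groups = {c: ("DS" if c.startswith("d") else "RS") for c in cols}
    return cols, groups


class TestTrigammaInverse:
    def test_against_bisection_oracle(self):
        # brute-force bisection inversion on a grid of y values
        for y in [1e-4, 0.01, 0.3, 1.0, 5.0, 50.0]:
            lo, hi = 1e-8, 1e8
            for _ in range(200):
                mid = math.sqrt(lo * hi)
                if special.polygamma(1, mid) > y:
                    lo = mid
                else:
                    hi = mid
            x = trigamma_inverse(y)
            assert x == pytest.approx(lo, rel=1e-5)

    def test_roundtrip(self):
        for y in [0.05, 0.5, 2.0]:
            assert special.polygamma(1, trigamma_inverse(y)) == pytest.approx(y, rel=1e-8)


class TestEbPrior:
    def test_equal_variances_give_infinite_d0(self):
        prior = fit_eb_prior(np.full(50, 2.5), d_g=6)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(2.5)

    def test_recovers_known_prior_from_scaled_f(self):
        # s2 ~ s0^2 * F(d_g, d0) with d0=4, s0^2=1: moment matching on
        # log s2 should recover d0 within 10% at 10^5 features
        rng = np.random.default_rng(6)
        d_g, d0, s0_sq = 6, 4.0, 1.0
        s2 = s0_sq * (rng.chisquare(d_g, 100_000) / d_g) / (rng.chisquare(d0, 100_000) / d0)
        prior = fit_eb_prior(s2, d_g)
        assert prior.d0 == pytest.approx(d0, rel=0.10)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.05)

    def test_needs_enough_features(self):
        with pytest.raises(ValueError):
            fit_eb_prior(np.ones(5), d_g=4)


class TestModeratedT:
    def test_identical_group_means_give_null_result(self):
        cols, groups = two_group_labels()
        base = pd.DataFrame(
            np.random.default_rng(0).normal(0, 1, (30, 8)), columns=cols
        )
        base.iloc[0] = [1.0, 2.0, 3.0, 4.0] * 2  # same values in both groups
        res = moderated_t_test(base, groups)
        assert res["log2fc"].iloc[0] == pytest.approx(0.0)
        assert res["t_mod"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_tiny_d0_reduces_to_ordinary_pooled_t(self):
        cols, groups = two_group_labels()
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(0, 1, (40, 8)), columns=cols)
        # d0 -> 0: posterior variance = s2_g, df = d_g (textbook two-sample t)
        res = moderated_t_test(m, groups, prior=EbPrior(d0=1e-12, s0_sq=1.0))
        t_ref, p_ref = sps.ttest_ind(
            m[cols[4:]].to_numpy(), m[cols[:4]].to_numpy(), axis=1, equal_var=True
        )
        np.testing.assert_allclose(res["t_mod"], t_ref, rtol=1e-6)
        np.testing.assert_allclose(res["p"], p_ref, rtol=1e-4)

    def test_infinite_d0_is_common_variance_z_like_test(self):
        cols, groups = two_group_labels()
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(0, 1, (30, 8)), columns=cols)
        s0_sq = 0.8
        res = moderated_t_test(m, groups, prior=EbPrior(d0=math.inf, s0_sq=s0_sq))
        fc = m[cols[4:]].mean(axis=1) - m[cols[:4]].mean(axis=1)
        z = fc / np.sqrt(s0_sq * (1 / 4 + 1 / 4))
        np.testing.assert_allclose(res["t_mod"], z, rtol=1e-12)

    def test_null_type_one_error_calibrated(self):
        cols, groups = two_group_labels(5, 5)
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(0, 1, (5000, 10)), columns=cols)
        res = moderated_t_test(m, groups)
        rate = (res["p"] < 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / 5000)
        assert rate == pytest.approx(0.05, abs=3 * se)

    def test_group_too_small_rejected(self):
        m = pd.DataFrame(np.ones((20, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match=">= 2"):
            moderated_t_test(m, {"a": "DS", "b": "RS", "c": "RS"})

    def test_matches_limma_ebayes(self, tmp_path):
        # independent oracle: limma's lmFit + eBayes on the same matrix
        cols, groups = two_group_labels()
        rng = np.random.default_rng(7)
        m = pd.DataFrame(
            rng.normal(10, 1, (150, 8)),
            index=[f"f{i}" for i in range(150)],
            columns=cols,
        )
        m.iloc[:70] += rng.normal(0, 1.4, (70, 8))  # heterogeneous variances
        mat_path = tmp_path / "mat.tsv"
        m.to_csv(mat_path, sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            textwrap.dedent(
                """
                suppressMessages(library(limma))
                args <- commandArgs(trailingOnly=TRUE)
                m <- as.matrix(read.delim(args[1], row.names=1))
                design <- cbind(Intercept=1, RS=c(0,0,0,0,1,1,1,1))
                fit <- eBayes(lmFit(m, design))
                out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior)
                write.csv(out, args[2])
                """
            )
        )
        out_path = tmp_path / "limma_out.csv"
        subprocess.run(
            ["Rscript", str(script), str(mat_path), str(out_path)],
            check=True,
            capture_output=True,
        )
        lim = pd.read_csv(out_path, index_col=0)
        res = moderated_t_test(m, groups)
        assert res.attrs["prior"].d0 == pytest.approx(lim["d0"].iloc[0], rel=1e-9)
        np.testing.assert_allclose(res["t_mod"], lim["t"], rtol=1e-9)
        np.testing.assert_allclose(res["p"], lim["p"], rtol=1e-9)


def brute_force_bh(p):
    """Step-up by explicit enumeration of all m candidate thresholds."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_adjusted_monotone_in_raw_ranks(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=40)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_equals_brute_force_enumeration(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestConsensus:
    def make(self, seed, index=None):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(0, 1, (20, 4)),
            index=index if index is not None else [f"f{i}" for i in range(20)],
            columns=list("abcd"),
        )

    def test_identical_matrices_idempotent(self):
        m = self.make(0)
        out = consensus_matrix([m, m, m]).values
        expected = (m - m.mean()) / m.std(ddof=1)
        pd.testing.assert_frame_equal(out, expected)

    def test_order_invariant(self):
        a, b, c = self.make(1), self.make(2), self.make(3)
        x = consensus_matrix([a, b, c]).values
        y = consensus_matrix([c, a, b]).values
        pd.testing.assert_frame_equal(x, y)

    def test_two_method_hand_average(self):
        a, b = self.make(4), self.make(5)
        za = (a - a.mean()) / a.std(ddof=1)
        zb = (b - b.mean()) / b.std(ddof=1)
        out = consensus_matrix([a, b]).values
        pd.testing.assert_frame_equal(out, (za + zb) / 2)

    def test_partial_features_dropped_and_recorded(self):
        a = self.make(6)
        b = self.make(7).drop(index=["f0", "f1"])
        out = consensus_matrix([a, b])
        assert "f0" not in out.values.index
        assert set(out.values.attrs["dropped_features"]) == {"f0", "f1"}

    def test_empty_intersection_rejected(self):
        a = self.make(8)
        b = self.make(9, index=[f"g{i}" for i in range(20)])
        with pytest.raises(ValueError, match="shared"):
            consensus_matrix([a, b])


class TestSummarize:
    def test_counts_nested(self, small_sim):
        from metaproteo.pipeline import differential_from_counts

        res = differential_from_counts(
            small_sim.counts, small_sim.catalog.lengths, small_sim.groups
        )
        table = summarize_counts({"nsaf": res})
        row = table.loc["nsaf"]
        assert row["quantified"] >= row["sig_05"] >= row["sig_01"]
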