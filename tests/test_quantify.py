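"""Abundance scales, in-silico digest, and downshifted-normal imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaproteo.io import TmtBlock
from metaproteo.quantify import (
    ImputePolicy,
    impute,
    log2_transform,
    nsaf,
    relative_ibaq,
    theoretical_peptide_count,
    tmt_ratio_to_pool,
    tryptic_digest,
)


class TestNsaf:
    def test_single_protein_is_one(self):
        m = nsaf(pd.DataFrame({"s1": [17]}, index=["p"]), pd.Series({"p": 120}))
        assert m.values.loc["p", "s1"] == 1.0

    def test_direct_arithmetic(self):
        # SpC/L = 0.1 and 0.05 -> NSAF 2/3 and 1/3
        counts = pd.DataFrame({"s1": [10, 20]}, index=["a", "b"])
        lengths = pd.Series({"a": 100, "b": 400})
        m = nsaf(counts, lengths)
        assert m.values["s1"].tolist() == pytest.approx([2 / 3, 1 / 3])

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 50, (50, 6)).astype(float))
        counts.iloc[0] += 1  # no all-zero column
        lengths = pd.Series(rng.integers(60, 500, 50).astype(float))
        m = nsaf(counts, lengths)
        assert np.allclose(m.values.sum(axis=0), 1.0, atol=1e-12)

    def test_composition_invariant_to_sample_rescaling(self):
        counts = pd.DataFrame({"s1": [3.0, 9.0, 1.0]}, index=list("abc"))
        lengths = pd.Series({"a": 100, "b": 200, "c": 300})
        a = nsaf(counts, lengths).values
        b = nsaf(counts * 7.0, lengths).values
        pd.testing.assert_frame_equal(a, b)

    def test_all_zero_sample_rejected_by_name(self):
        counts = pd.DataFrame({"good": [1.0], "empty": [0.0]}, index=["p"])
        with pytest.raises(ValueError, match="empty"):
            nsaf(counts, pd.Series({"p": 100}))


class TestTrypticDigest:
    def test_forced_segmentation(self):
        assert theoretical_peptide_count("AAAAAAAKCCCCCCCKDDDDDDDD") == 3

    def test_kp_suppresses_cleavage(self):
        # K followed by P does not cleave: one fragment of length 9
        assert tryptic_digest("AAAKPAAAK") == ["AAAKPAAAK"]

    def test_length_window(self):
        # fragments: AAK (3) and AAAAAAAA (8) -> only one in [7, 30]
        assert theoretical_peptide_count("AAKAAAAAAAA") == 1

    def test_empty_sequence_warns_zero(self):
        with pytest.warns(UserWarning):
            assert theoretical_peptide_count("") == 0

    def test_digest_concatenation_identity(self):
        seq = "MKAAAPRGGKLLLKPAR"
        assert "".join(tryptic_digest(seq)) == seq

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80))
    def test_matches_pyteomics_cleave(self, seq):
        # independent regex-based cleavage through pyteomics; the plain
        # [KR](?!P) rule, without the ExPASy WKP/MRP refinements, is this
        # package's documented digest contract
        from pyteomics import parser

        oracle = parser.cleave(seq, r"[KR](?!P)", missed_cleavages=0)
        assert set(tryptic_digest(seq)) == oracle


class TestRelativeIbaq:
    def test_single_feature_is_one(self):
        m = relative_ibaq(pd.DataFrame({"s1": [500.0]}, index=["p"]), pd.Series({"p": 4}))
        assert m.values.loc["p", "s1"] == 1.0

    def test_direct_arithmetic(self):
        inten = pd.DataFrame({"s1": [100.0, 300.0]}, index=["a", "b"])
        theo = pd.Series({"a": 1, "b": 3})
        m = relative_ibaq(inten, theo)
        assert m.values["s1"].tolist() == pytest.approx([0.5, 0.5])

    def test_observed_columns_sum_to_one_and_missing_stays_missing(self):
        rng = np.random.default_rng(1)
        inten = pd.DataFrame(rng.lognormal(10, 1, (30, 4)))
        inten.iloc[:10, 0] = np.nan
        theo = pd.Series(rng.integers(1, 40, 30))
        m = relative_ibaq(inten, theo)
        assert np.allclose(m.values.sum(axis=0, skipna=True), 1.0)
        assert m.values.iloc[:10, 0].isna().all()

    def test_zero_observable_peptides_rejected(self):
        inten = pd.DataFrame({"s1": [100.0]}, index=["p"])
        with pytest.raises(ValueError, match="observable"):
            relative_ibaq(inten, pd.Series({"p": 0}))


def make_block(intensities, samples, batch="b1"):
    channels = [str(126 + i) for i in range(len(samples))]
    return TmtBlock(
        batch_id=batch,
        sample_map=dict(zip(channels, samples)),
        intensities=pd.DataFrame(intensities, columns=channels),
    )


class TestTmtRatio:
    def test_sample_identical_to_pool_gives_ratio_one(self):
        block = make_block(
            {"126": [5.0, 10.0], "127": [5.0, 10.0]}, ["s07", "pool"]
        )
        m = tmt_ratio_to_pool([block])
        assert m.values["s07"].tolist() == pytest.approx([1.0, 1.0])

    def test_uniform_scaling_cancels(self):
        # channel = 2x pool before normalization: column normalization
        # equalizes sums so every ratio is exactly 1
        block = make_block({"126": [8.0, 2.0], "127": [4.0, 1.0]}, ["s07", "pool"])
        m = tmt_ratio_to_pool([block])
        assert m.values["s07"].tolist() == pytest.approx([1.0, 1.0])

    def test_two_feature_hand_computation(self):
        # sums: ch126 = 12, ch127 = 6, mean = 9 -> normalized
        # ch126 = (9, 3) * 9/12 = (6.75, 2.25); ch127 = (4, 2) * 9/6 = (6, 3)
        # ratios = (6.75/6, 2.25/3) = (1.125, 0.75)
        block = make_block({"126": [9.0, 3.0], "127": [4.0, 2.0]}, ["s07", "pool"])
        m = tmt_ratio_to_pool([block])
        assert m.values["s07"].tolist() == pytest.approx([1.125, 0.75])

    def test_features_missing_from_other_batch_are_nan(self):
        b1 = make_block({"126": [9.0, 3.0], "127": [4.0, 2.0]}, ["s07", "pool"])
        b2 = TmtBlock(
            batch_id="b2",
            sample_map={"126": "s16", "127": "pool"},
            intensities=pd.DataFrame({"126": [5.0], "127": [5.0]}, index=[5]),
        )
        m = tmt_ratio_to_pool([b1, b2])
        assert m.values.loc[5, "s07"] != m.values.loc[5, "s07"]  # NaN
        assert np.isfinite(m.values.loc[0, "s07"])


class TestLogAndImpute:
    def test_log2_zeros_become_missing(self):
        m = log2_transform(pd.DataFrame({"s1": [4.0, 0.0, np.nan]}))
        vals = m.values["s1"]
        assert vals.iloc[0] == 2.0
        assert vals.iloc[1:].isna().all()

    def test_no_missing_identity(self):
        df = pd.DataFrame(np.arange(12.0).reshape(4, 3) + 1.0)
        out = impute(np.log2(df).pipe(lambda d: d), ImputePolicy(seed=0))
        pd.testing.assert_frame_equal(out.values, np.log2(df))
        assert not out.imputed_mask.to_numpy().any()

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(20, 2, (100, 6)))
        holes = rng.uniform(size=df.shape) < 0.2
        df_missing = df.mask(holes)
        out = impute(df_missing, ImputePolicy(seed=1))
        pd.testing.assert_frame_equal(out.values.mask(holes), df_missing.mask(holes))
        assert out.imputed_mask.to_numpy().sum() == holes.sum()

    def test_same_seed_identical_draws(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(20, 2, (50, 4))).mask(
            rng.uniform(size=(50, 4)) < 0.3
        )
        a = impute(df, ImputePolicy(seed=9))
        b = impute(df, ImputePolicy(seed=9))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_downshifted_distribution_parameters(self):
        # one sample: observed ~ N(20, 2), 10^4 missing cells; imputed draws
        # must center at 20 - 2*2 = 16 with sd 0.3*2 = 0.6 (within 3 SE)
        rng = np.random.default_rng(4)
        n_obs, n_miss = 20000, 10000
        col = np.r_[rng.normal(20, 2, n_obs), np.full(n_miss, np.nan)]
        df = pd.DataFrame({"s1": col, "s2": rng.normal(20, 2, n_obs + n_miss)})
        out = impute(df, ImputePolicy(seed=5))
        draws = out.values["s1"].to_numpy()[n_obs:]
        obs = df["s1"].dropna()
        mu, sd = obs.mean(), obs.std(ddof=1)
        se_mean = 0.3 * sd / np.sqrt(n_miss)
        assert draws.mean() == pytest.approx(mu - 2 * sd, abs=3 * se_mean)
        se_sd = 0.3 * sd / np.sqrt(2 * (n_miss - 1))
        assert draws.std(ddof=1) == pytest.approx(0.3 * sd, abs=3 * se_sd)

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            ImputePolicy(width_factor=0.0)
        with pytest.raises(ValueError):
            ImputePolicy(shift_sds=-1.0)
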