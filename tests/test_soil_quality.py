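import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rhizoq.errors import (
    AlignmentError,
    ConfigError,
    DegenerateDataError,
    DomainError,
)
from rhizoq.soil_quality import (
    assign_directions,
    classify_sqi,
    compute_sqi,
    evaluate_soil_quality,
    factor_weights,
    kmo_bartlett,
    kmo_from_correlation,
    membership,
    radar_table,
    table4_fixture,
)

from .oracles import factor_weights_oracle, kmo_oracle


class TestMembership:
    def test_midpoint(self):
        assert membership(6.0, "more_better", (2.0, 10.0)) == pytest.approx(0.5)

    def test_boundary_symmetry(self):
        assert membership(2.0, "more_better", (2.0, 10.0)) == 0.0
        assert membership(2.0, "less_better", (2.0, 10.0)) == 1.0

    def test_rescaled_endpoints(self):
        kw = dict(direction="more_better", bounds=(2.0, 10.0),
                  variant="rescaled_01_to_1")
        assert membership(10.0, **kw) == pytest.approx(1.0)
        assert membership(2.0, **kw) == pytest.approx(0.1)

    def test_degenerate_bounds_raise(self):
        with pytest.raises(DegenerateDataError):
            membership(1.0, "more_better", (3.0, 3.0))

    def test_out_of_bounds_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            s = membership(11.0, "more_better", (2.0, 10.0))
        assert s == 1.0

    @given(
        y=st.floats(2.0, 10.0),
        scale=st.floats(0.1, 100.0),
        shift=st.floats(-50.0, 50.0),
    )
    def test_affine_invariance(self, y, scale, shift):
        """Rescaling value and bounds by a positive affine map leaves the
        score unchanged, for both directions and variants."""
        for direction in ("more_better", "less_better"):
            for variant in ("unit", "rescaled_01_to_1"):
                s1 = membership(y, direction, (2.0, 10.0), variant)
                s2 = membership(
                    scale * y + shift, direction,
                    (scale * 2.0 + shift, scale * 10.0 + shift), variant,
                )
                assert s1 == pytest.approx(s2, abs=1e-9)

    @given(y=st.floats(2.0, 10.0))
    def test_directions_sum_to_one_under_unit_variant(self, y):
        up = membership(y, "more_better", (2.0, 10.0))
        down = membership(y, "less_better", (2.0, 10.0))
        assert up + down == pytest.approx(1.0)


class TestDirections:
    def test_default_scheme(self):
        d = assign_directions(["pH", "EC", "SOM"])
        assert d == {
            "pH": "less_better", "EC": "less_better", "SOM": "more_better"
        }

    def test_empty(self):
        assert assign_directions([]) == {}

    def test_override_wins(self):
        d = assign_directions(["pH"], overrides={"pH": "more_better"})
        assert d["pH"] == "more_better"

    def test_unknown_indicator_warns_and_defaults(self):
        with pytest.warns(UserWarning, match="unknown"):
            d = assign_directions(["mystery"])
        assert d["mystery"] == "more_better"


class TestFactorWeights:
    def test_two_perfectly_correlated_indicators_share_equally(self):
        x = np.linspace(0, 1, 10)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        w, _ = factor_weights(df)
        assert w["a"] == pytest.approx(0.5, abs=1e-9)
        assert w["b"] == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_weights_sum_to_one_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(12, 6)))
        w, diag = factor_weights(df)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert (w >= 0).all()
        assert diag["n_retained"] >= 1

    def test_matches_eigendecomposition_oracle_on_block_structure(self):
        """A 4-indicator table with a 2-block correlation structure gives the
        same communality-share weights as a separately coded
        eigendecomposition + Jacobi varimax."""
        rng = np.random.default_rng(0)
        n = 40
        f1 = rng.normal(size=n)
        f2 = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "a": f1 + 0.1 * rng.normal(size=n),
                "b": f1 + 0.1 * rng.normal(size=n),
                "c": f2 + 0.1 * rng.normal(size=n),
                "d": f2 + 0.1 * rng.normal(size=n),
            }
        )
        w, _ = factor_weights(df)
        expected = factor_weights_oracle(df.to_numpy())
        np.testing.assert_allclose(w.to_numpy(), expected, atol=1e-6)

    def test_constant_indicator_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4]})
        with pytest.raises(DegenerateDataError, match="a"):
            factor_weights(df)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(DegenerateDataError, match="3 samples"):
            factor_weights(df)


class TestKmoBartlett:
    def test_kmo_of_printed_equicorrelated_matrix(self):
        corr = np.array([[1, 0.8, 0.8], [0.8, 1, 0.8], [0.8, 0.8, 1.0]])
        # closed form: Σr² = 6·0.64; anti-image partials all 4/9
        expected = 0.64 * 6 / (0.64 * 6 + 6 * (4.0 / 9) ** 2)
        assert kmo_from_correlation(corr) == pytest.approx(expected, abs=1e-12)
        assert kmo_from_correlation(corr) == pytest.approx(
            kmo_oracle(corr), abs=1e-12
        )

    def test_orthogonal_data_gives_zero_bartlett(self):
        # centered orthonormal columns -> exact identity correlation matrix
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 4))
        x -= x.mean(axis=0)
        q, _ = np.linalg.qr(x)
        df = pd.DataFrame(q, columns=list("abcd"))
        kmo, chi2, p = kmo_bartlett(df)
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_kmo_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(15, 5)))
        kmo, chi2, p = kmo_bartlett(df)
        assert 0.0 <= kmo <= 1.0
        assert chi2 >= 0.0
        assert 0.0 <= p <= 1.0

    def test_singular_correlation_matrix_raises(self):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(DegenerateDataError, match="singular"):
            kmo_from_correlation(corr)


class TestSqi:
    def test_table4_weighted_sums(self):
        """Weighted sums of the published membership/weight table hit the
        hand-computed SQI values."""
        m, w = table4_fixture("ryegrass")
        res = compute_sqi(m, w)
        assert res.scores["P1S5"] == pytest.approx(0.6050, abs=5e-4)
        m, w = table4_fixture("cosmos")
        res = compute_sqi(m, w)
        assert res.scores["P2S5"] == pytest.approx(0.7565, abs=5e-4)
        assert res.scores["P2S1"] == pytest.approx(0.2463, abs=5e-4)

    def test_constant_membership_is_identity(self):
        m = pd.DataFrame(0.42, index=["t1", "t2"], columns=["a", "b", "c"])
        w = pd.Series([0.5, 0.3, 0.2], index=["a", "b", "c"])
        res = compute_sqi(m, w)
        np.testing.assert_allclose(res.scores, 0.42, atol=1e-12)

    def test_indicator_mismatch_lists_difference(self):
        m = pd.DataFrame(0.5, index=["t1"], columns=["a", "b"])
        w = pd.Series([0.5, 0.5], index=["a", "c"])
        with pytest.raises(AlignmentError, match="'b'.*'c'"):
            compute_sqi(m, w)

    def test_sqi_monotone_in_memberships(self):
        m = pd.DataFrame([[0.2, 0.4]], index=["t"], columns=["a", "b"])
        w = pd.Series([0.7, 0.3], index=["a", "b"])
        base = compute_sqi(m, w).scores["t"]
        m2 = m.copy()
        m2.loc["t", "a"] += 0.3
        assert compute_sqi(m2, w).scores["t"] > base

    @pytest.mark.parametrize(
        "sqi,level",
        [(0.85, "I"), (0.9, "I"), (0.7565, "II"), (0.7, "II"), (0.6, "III"),
         (0.55, "III"), (0.499, "IV"), (0.4, "IV"), (0.2463, "V"), (0.0, "V")],
    )
    def test_grading_bounds(self, sqi, level):
        assert classify_sqi(sqi) == level

    def test_out_of_domain_sqi_raises(self):
        with pytest.raises(DomainError):
            classify_sqi(1.2)
        with pytest.raises(DomainError):
            classify_sqi(-0.1)


class TestTable4Fixture:
    def test_ryegrass_weights_row(self):
        _, w = table4_fixture("ryegrass")
        assert w.tolist() == [
            0.263, 0.149, 0.077, 0.136, 0.034, 0.125, 0.062, 0.154
        ]

    def test_both_weight_rows_sum_to_one(self):
        for species in ("ryegrass", "cosmos"):
            _, w = table4_fixture(species)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_control_ph_membership(self):
        m, _ = table4_fixture("ryegrass")
        assert m.loc["P1S1", "pH"] == 0.787

    def test_unknown_species_rejected(self):
        with pytest.raises(ConfigError):
            table4_fixture("wheat")


class TestEndToEnd:
    def test_radar_table_is_identity_reshape(self):
        m, w = table4_fixture("ryegrass")
        res = compute_sqi(m, w)
        tidy = radar_table(res)
        assert set(tidy.columns) == {"treatment", "axis", "value"}
        # every membership appears exactly once
        assert len(tidy) == m.size + len(res.scores)
        pivot = tidy[tidy["axis"] != "SQI"].pivot(
            index="treatment", columns="axis", values="value"
        )
        pd.testing.assert_frame_equal(
            pivot[m.columns].sort_index(), m.sort_index(),
            check_names=False,
        )

    def test_evaluate_soil_quality_on_synthetic_table(self, default_experiment):
        indicators, _, _, _ = default_experiment
        sub = indicators.subset(
            indicators.data["species"] == "P1"
        )
        res = evaluate_soil_quality(sub)
        assert len(res.scores) == 5
        assert res.scores.between(0, 1).all()
        assert res.weights.sum() == pytest.approx(1.0)
        # amended treatments outscore the unamended control at mid doses
        assert res.scores["dose_3"] > res.scores["dose_0"]
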