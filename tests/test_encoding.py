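"""Feature encoding: smoothed target encoding, composition columns, scaling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spraydry.datasets import GeneratorConfig, generate_dataset
from spraydry.encoding import (
    NOZZLE_COLUMN,
    SCALE_COLUMN,
    EncoderState,
    SprayFeatureEncoder,
    apply_minmax,
    build_features,
    encode_composition,
    fit_minmax,
    fit_target_encoding,
    smoothing_weight,
)


def _toy_train():
    """Nozzle A: 3 sprays at 40 um; nozzle B: 5 sprays at 24 um; global mean 30."""
    rows = [("A", 40.0)] * 3 + [("B", 24.0)] * 5
    return pd.DataFrame(
        {
            "api_id": "API-1",
            "nozzle_id": [r[0] for r in rows],
            "d50": [r[1] for r in rows],
        }
    )


class TestTargetEncoding:
    def test_hand_computed_logistic_shrinkage(self):
        # n=3, m_c=40, m_global=30, k=1, f=3: lam = 1/(1+e^(-2/3)) ~ 0.6608
        lookup, global_mean = fit_target_encoding(_toy_train(), k=1, f=3.0)
        lam = 1.0 / (1.0 + math.exp(-2.0 / 3.0))
        assert global_mean == pytest.approx(30.0)
        assert lookup["A"] == pytest.approx(lam * 40.0 + (1 - lam) * 30.0, abs=1e-12)
        assert lookup["A"] == pytest.approx(36.61, abs=5e-3)

    def test_brute_force_oracle_on_generated_nozzles(self):
        frame, _ = generate_dataset(GeneratorConfig(n_apis=10, n_nozzles=12, seed=4))
        lookup, global_mean = fit_target_encoding(frame, k=1, f=3.0)
        for nozzle, group in frame.groupby("nozzle_id"):
            n, m_c = len(group), group["d50"].mean()
            lam = 1.0 / (1.0 + math.exp(-(n - 1) / 3.0))
            assert lookup[str(nozzle)] == pytest.approx(
                lam * m_c + (1 - lam) * global_mean, abs=1e-12
            )

    def test_encoded_values_bounded_by_training_d50(self):
        frame, _ = generate_dataset(GeneratorConfig(n_apis=10, seed=4))
        lookup, _ = fit_target_encoding(frame, k=1, f=3.0)
        lo, hi = frame["d50"].min(), frame["d50"].max()
        assert all(lo <= v <= hi for v in lookup.values())

    def test_large_n_limit_approaches_category_mean(self):
        rows = pd.DataFrame({"api_id": "x", "nozzle_id": ["A"] * 500, "d50": 40.0})
        rows = pd.concat([rows, pd.DataFrame({"api_id": "x", "nozzle_id": ["B"], "d50": [10.0]})])
        lookup, _ = fit_target_encoding(rows, k=1, f=3.0)
        assert lookup["A"] == pytest.approx(40.0, abs=1e-6)

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            fit_target_encoding(_toy_train().iloc[:0])

    @given(n=st.integers(1, 1000))
    @settings(deadline=None, max_examples=30)
    def test_shrinkage_weight_in_unit_interval_and_increasing(self, n):
        w = smoothing_weight(n, 1, 3.0)
        assert 0.0 < w <= 1.0  # saturates at 1 in float for large n
        assert smoothing_weight(n + 1, 1, 3.0) >= w


class TestCompositionEncoding:
    def test_solvent_weight_percent_columns(self, small_dataset):
        frame, _ = small_dataset
        enc = SprayFeatureEncoder().fit(frame)
        matrix = encode_composition(frame, enc.state_)
        for col in enc.state_.solvent_columns:
            assert np.allclose(matrix[col], frame[col].astype(float))

    def test_polymer_none_gives_all_zero_polymer_columns(self, small_dataset):
        frame, _ = small_dataset
        enc = SprayFeatureEncoder().fit(frame)
        row = frame.iloc[[0]].copy()
        row["polymer_type"] = "None"
        matrix = encode_composition(row, enc.state_)
        assert (matrix[enc.state_.polymer_columns].to_numpy() == 0).all()

    def test_unseen_category_is_silent_zeros(self, small_dataset):
        frame, _ = small_dataset
        enc = SprayFeatureEncoder().fit(frame)
        row = frame.iloc[[0]].copy()
        row["polymer_type"] = "Brand New Polymer"
        matrix = encode_composition(row, enc.state_)
        assert (matrix[enc.state_.polymer_columns].to_numpy() == 0).all()

    def test_scale_indicator(self, small_dataset):
        frame, _ = small_dataset
        enc = SprayFeatureEncoder().fit(frame)
        matrix = encode_composition(frame, enc.state_)
        assert np.array_equal(
            matrix[SCALE_COLUMN].to_numpy(), (frame["dryer_scale"] == "PSD-2").astype(float)
        )


class TestMinMax:
    def test_basic_and_conventions(self):
        m = pd.DataFrame({"a": [10.0, 20.0, 30.0], "b": [5.0, 5.0, 5.0]})
        mm = fit_minmax(m)
        out = apply_minmax(m, mm)
        assert list(out["a"]) == [0.0, 0.5, 1.0]
        assert list(out["b"]) == [0.0, 0.0, 0.0]  # constant column convention
        test = apply_minmax(pd.DataFrame({"a": [40.0], "b": [7.0]}), mm)
        assert test["a"].iloc[0] == pytest.approx(1.5)  # no clipping

    def test_training_rows_scale_into_unit_interval(self, small_dataset):
        frame, _ = small_dataset
        enc = SprayFeatureEncoder().fit(frame)
        X = enc.transform(frame)
        assert (X.to_numpy() >= -1e-12).all() and (X.to_numpy() <= 1 + 1e-12).all()


class TestBuildFeatures:
    def test_flags_control_nozzle_columns(self, small_dataset):
        frame, _ = small_dataset
        orifices = {nz: 1.0 for nz in frame["nozzle_id"].unique()}
        for te, od in [(True, False), (False, True), (True, True), (False, False)]:
            enc = SprayFeatureEncoder(
                use_target_encoding=te,
                include_orifice_diameter=od,
                orifice_diameters=orifices,
            ).fit(frame)
            X = enc.transform(frame)
            assert (NOZZLE_COLUMN in X.columns) == te
            assert ("orifice_diameter" in X.columns) == od

    def test_missing_orifice_diameter_errors(self, small_dataset):
        frame, _ = small_dataset
        with pytest.raises(ValueError, match="orifice"):
            SprayFeatureEncoder(include_orifice_diameter=True, orifice_diameters={}).fit(frame)

    def test_deterministic_and_reproduces_training_matrix(self, small_dataset):
        frame, _ = small_dataset
        enc = SprayFeatureEncoder().fit(frame)
        a, b = enc.transform(frame), enc.transform(frame)
        pd.testing.assert_frame_equal(a, b)

    def test_unseen_nozzle_maps_to_global_mean(self, small_dataset):
        frame, _ = small_dataset
        enc = SprayFeatureEncoder(scale=False).fit(frame)
        row = frame.iloc[[0]].copy()
        row["nozzle_id"] = "NOZZLE-NEVER-SEEN"
        X = enc.transform(row)
        assert X[NOZZLE_COLUMN].iloc[0] == pytest.approx(enc.state_.global_mean_d50)


def test_leakage_guard_holdout_d50_never_touches_features(small_dataset):
    """Permuting held-out D50 values leaves held-out encoded features
    bit-identical: the encoder is a function of training rows only."""
    frame, _ = small_dataset
    apis = sorted(frame["api_id"].unique())
    hold = frame[frame["api_id"] == apis[0]]
    fit_rows = frame[frame["api_id"] != apis[0]]
    enc = SprayFeatureEncoder().fit(fit_rows)
    X1 = enc.transform(hold)
    corrupted = hold.copy()
    corrupted["d50"] = np.random.default_rng(0).permutation(corrupted["d50"].to_numpy()) * 3.7
    enc2 = SprayFeatureEncoder().fit(fit_rows)
    X2 = enc2.transform(corrupted)
    assert np.array_equal(X1.to_numpy(), X2.to_numpy())


def test_encoder_state_serialization_round_trip(tmp_path, small_dataset):
    frame, _ = small_dataset
    enc = SprayFeatureEncoder().fit(frame)
    path = tmp_path / "state.txt"
    enc.state_.save(path)
    back = EncoderState.load(path)
    assert back.feature_columns == enc.state_.feature_columns
    assert back.nozzle_lookup == pytest.approx(enc.state_.nozzle_lookup)
    assert back.minmax == enc.state_.minmax
    X1 = build_features(frame, enc.state_)
    X2 = build_features(frame, back)
    assert np.array_equal(X1.to_numpy(), X2.to_numpy())
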