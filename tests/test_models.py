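import numpy as np
import pandas as pd
import pytest

import slrmig as sm
from slrmig.models import (
    BAU_PRODUCTION,
    CLIMATE_PRODUCTION,
    MigrationMatrix,
    ProductionFunction,
    cpc,
    extended_radiation_weights,
    radiation_weights,
    validate_flow_table,
)


def line_toy_features():
    # origin A (pop 100), destinations B and C (pop 50 each) at 100/200 km
    return pd.DataFrame(
        {
            "origin": ["A", "A"],
            "dest": ["B", "C"],
            "m_i": [100.0, 100.0],
            "m_j": [50.0, 50.0],
            "d_km": [100.0, 200.0],
            "s": [0.0, 50.0],
        }
    )


class TestRadiation:
    def test_toy_weights(self):
        w = radiation_weights([100, 100], [50, 50], [0, 50])
        np.testing.assert_allclose(w, [1 / 3, 1 / 6], rtol=1e-14)

    def test_toy_normalized_row(self):
        p = sm.RadiationModel().predict_proba(line_toy_features())
        np.testing.assert_allclose(p.to_numpy(), [2 / 3, 1 / 3], rtol=1e-14)

    def test_single_destination_row(self):
        feats = line_toy_features().iloc[:1]
        p = sm.RadiationModel().predict_proba(feats)
        assert p.iloc[0] == 1.0

    def test_all_zero_destinations_uniform_with_warning(self):
        feats = line_toy_features().assign(m_j=0.0)
        with pytest.warns(UserWarning, match="uniform"):
            p = sm.RadiationModel().predict_proba(feats)
        np.testing.assert_allclose(p.to_numpy(), [0.5, 0.5])

    def test_matches_brute_force_on_random_instance(self, small_region):
        """Vectorized closed form equals pair-by-pair evaluation on a 40-zone instance."""
        zones, _ = small_region
        pops = zones["population"].astype(float)
        feats = sm.build_feature_table(pops, pops, zones[["lat", "lon"]], exclude_self=True)
        w_vec = radiation_weights(feats["m_i"], feats["m_j"], feats["s"])
        w_loop = np.array(
            [
                (mi * mj) / ((mi + s) * (mi + mj + s))
                for mi, mj, s in zip(feats["m_i"], feats["m_j"], feats["s"])
            ]
        )
        assert np.max(np.abs(w_vec - w_loop)) < 1e-12


class TestExtendedRadiation:
    def test_closed_form_values(self):
        # (m_i=100, m_j=50, s=0, alpha=1): ((150-100)(100+1))/((100+1)(150+1))
        w0 = extended_radiation_weights(100.0, 50.0, 0.0, 1.0)
        assert w0 == pytest.approx(50 * 101 / (101 * 151), rel=1e-12)
        # (m_i=100, m_j=50, s=50, alpha=1): ((200-150)(101))/((151)(201))
        w1 = extended_radiation_weights(100.0, 50.0, 50.0, 1.0)
        assert w1 == pytest.approx(50 * 101 / (151 * 201), rel=1e-12)

    def test_zero_destination_gives_zero_weight(self):
        assert extended_radiation_weights(100.0, 0.0, 10.0, 0.7) == 0.0

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            extended_radiation_weights(1.0, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            sm.ExtendedRadiationModel(alpha=-1.0)

    def test_large_population_limit_approaches_radiation(self):
        """At alpha=1, s=0 and populations ~1e6 the '+1' correction vanishes."""
        m = 1.0e6
        w_ext = extended_radiation_weights(m, m, 0.0, 1.0)
        w_rad = radiation_weights(m, m, 0.0)
        assert abs(w_ext - w_rad) / w_rad < 1e-4


class TestProduction:
    def test_climate_identity(self):
        assert CLIMATE_PRODUCTION(350.0) == 350.0

    def test_bau_three_percent(self):
        assert BAU_PRODUCTION(1000.0) == pytest.approx(30.0)

    def test_zero(self):
        assert ProductionFunction(0.5)(0.0) == 0.0

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            CLIMATE_PRODUCTION(-1.0)

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ProductionFunction(1.5)


class TestProbabilityContract:
    def test_rows_are_distributions(self):
        """All model rows over 1e4 random feature rows sum to 1 with nonnegative entries."""
        rng = np.random.default_rng(42)
        n = 10_000
        origins = np.repeat([f"o{k}" for k in range(500)], 20)
        feats = pd.DataFrame(
            {
                "origin": origins,
                "dest": [f"d{k}" for k in range(n)],
                "m_i": rng.lognormal(9, 1, n),
                "m_j": rng.lognormal(9, 1, n),
                "d_km": rng.uniform(1, 2000, n),
                "s": rng.lognormal(8, 2, n),
            }
        )
        neural = sm.NeuralMigrationModel(epochs=5, seed=1)
        tiny_flows = pd.DataFrame(
            {"origin": origins[:40], "dest": feats["dest"][:40], "migrants": rng.integers(1, 50, 40)}
        )
        neural.fit(feats.iloc[:40], tiny_flows)
        models = [
            sm.RadiationModel(),
            sm.ExtendedRadiationModel(alpha=0.5),
            sm.DistanceTiltedModel(sm.ExtendedRadiationModel(alpha=0.5), scale_km=200.0),
            neural,
        ]
        for model in models:
            p = model.predict_proba(feats)
            assert (p.to_numpy() >= 0).all()
            sums = p.groupby(feats["origin"]).sum()
            assert np.max(np.abs(sums.to_numpy() - 1.0)) < 1e-9


class TestNeural:
    def test_refit_is_bitwise_identical(self, region200, region200_features):
        zones, _ = region200
        gen = sm.ExtendedRadiationModel(alpha=0.5)
        feats = region200_features
        flows = sm.generate_flows(zones, gen, 0.03, 2004, 9, feats=feats)
        m1 = sm.NeuralMigrationModel(epochs=30, seed=3).fit(feats, flows)
        m2 = sm.NeuralMigrationModel(epochs=30, seed=3).fit(feats, flows)
        np.testing.assert_array_equal(
            m1.predict_proba(feats).to_numpy(), m2.predict_proba(feats).to_numpy()
        )

    def test_permutation_equivariance(self, fitted_neural, region200_features):
        model, _, _ = fitted_neural
        feats = region200_features
        sub = feats[feats["origin"] == feats["origin"].iloc[0]].reset_index(drop=True)
        perm = sub.sample(frac=1.0, random_state=1).reset_index(drop=True)
        p = model.predict_proba(sub).to_numpy()
        pp = model.predict_proba(perm).to_numpy()
        lookup = dict(zip(sub["dest"], p))
        # equality up to summation order in the row normalisation
        np.testing.assert_allclose(
            pp, np.array([lookup[d] for d in perm["dest"]]), rtol=1e-12
        )

    def test_single_destination_origin_row_is_one(self, fitted_neural):
        model, _, _ = fitted_neural
        feats = pd.DataFrame(
            {"origin": ["o"], "dest": ["d"], "m_i": [5e3], "m_j": [2e3], "d_km": [120.0], "s": [1e4]}
        )
        assert model.predict_proba(feats).iloc[0] == 1.0

    def test_unfitted_predict_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            sm.NeuralMigrationModel().predict_proba(line_toy_features())

    def test_degenerate_training_rejected(self, region200_features):
        flows = pd.DataFrame({"origin": ["a"], "dest": ["b"], "migrants": [0.0]})
        with pytest.raises(ValueError, match="degenerate"):
            sm.NeuralMigrationModel().fit(region200_features, flows)

    def test_json_round_trip_preserves_predictions(self, fitted_neural, region200_features, tmp_path):
        model, _, _ = fitted_neural
        clone = sm.NeuralMigrationModel.from_json(model.to_json())
        np.testing.assert_array_equal(
            model.predict_proba(region200_features).to_numpy(),
            clone.predict_proba(region200_features).to_numpy(),
        )

    def test_recovers_generating_radiation_rows(self, region200, region200_features):
        """Fit on multinomial flows from the radiation model; held-out CPC >= 0.9."""
        zones, _ = region200
        gen = sm.RadiationModel()
        feats = region200_features
        flows = sm.generate_flows(zones, gen, 0.03, 2004, 77, feats=feats)
        model = sm.NeuralMigrationModel(epochs=800, seed=2).fit(feats, flows)
        held = feats[feats["origin"].isin(model.val_origins_)]
        idx = pd.MultiIndex.from_frame(held[["origin", "dest"]])
        score = cpc(
            pd.Series(gen.predict_proba(held).to_numpy(), index=idx),
            pd.Series(model.predict_proba(held).to_numpy(), index=idx),
        )
        assert score >= 0.9


class TestCPC:
    def _mat(self, entries):
        df = pd.DataFrame(entries, columns=["origin", "dest", "migrants"])
        return MigrationMatrix.from_frame(df)

    def test_identity(self):
        a = self._mat([("A", "B", 10.0), ("A", "C", 5.0)])
        assert cpc(a, a) == 1.0

    def test_half_overlap(self):
        a = self._mat([("A", "B", 10.0), ("A", "C", 0.0)])
        b = self._mat([("A", "B", 5.0), ("A", "C", 5.0)])
        assert cpc(a, b) == pytest.approx(0.5)

    def test_disjoint_support(self):
        a = self._mat([("A", "B", 10.0)])
        b = self._mat([("C", "D", 10.0)])
        assert cpc(a, b) == 0.0

    def test_both_zero_rejected(self):
        a = MigrationMatrix.empty()
        with pytest.raises(ValueError):
            cpc(a, a)


class TestFlowTable:
    def test_duplicate_key_rejected(self):
        df = pd.DataFrame(
            {"origin": ["A", "A"], "dest": ["B", "B"], "migrants": [1.0, 2.0], "year": [2004, 2004]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            validate_flow_table(df)

    def test_negative_flow_rejected_with_row(self):
        df = pd.DataFrame({"origin": ["A"], "dest": ["B"], "migrants": [-1.0]})
        with pytest.raises(ValueError, match=r"rows \[0\]"):
            validate_flow_table(df)

    def test_irs_style_column_names_accepted(self):
        df = pd.DataFrame({"origin_id": ["A"], "dest_id": ["B"], "migrants": [3.0]})
        out = validate_flow_table(df)
        assert list(out["origin"]) == ["A"]
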