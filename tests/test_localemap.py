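"""Locale aggregation, exact Jenks classification, layer export."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ermimap as em
from ermimap.errors import ConfigError, InputError
from ermimap.localemap import BreaksClassification, classify, read_layer


def jenks_oracle_cost(values, n_classes):
    """Minimum within-class SSD over all boundary placements (exhaustive)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def ssd(chunk):
        return ((chunk - chunk.mean()) ** 2).sum()

    best = np.inf
    for bounds in combinations(range(1, n), n_classes - 1):
        edges = [0, *bounds, n]
        cost = sum(ssd(v[a:b]) for a, b in zip(edges[:-1], edges[1:]))
        best = min(best, cost)
    return best


def classification_cost(values, cls):
    values = np.asarray(values, dtype=float)
    return sum(
        ((values[cls.classes == c] - values[cls.classes == c].mean()) ** 2).sum()
        for c in np.unique(cls.classes)
    )


class TestAssignLocales:
    def test_planted_grid_centroids_recovered(self, rng):
        """Homes around well-separated centroids map back to them."""
        metrics = pytest.importorskip("sklearn.metrics")
        lat_c, lon_c = np.meshgrid(np.linspace(25, 49, 6), np.linspace(-124, -67, 8))
        lat_c, lon_c = lat_c.ravel(), lon_c.ravel()  # 48 well-separated locales
        truth = rng.integers(0, 48, 600)
        lat = lat_c[truth] + rng.normal(0, 0.15, 600)
        lon = lon_c[truth] + rng.normal(0, 0.15, 600)
        labels = em.assign_locales(lat, lon, n_locales=48, seed=0)
        assert metrics.adjusted_rand_score(truth, labels) > 0.95

    def test_saturated_case(self):
        lat = np.linspace(25, 45, 10)
        lon = np.linspace(-120, -70, 10)
        labels = em.assign_locales(lat, lon, n_locales=10, seed=0)
        assert len(np.unique(labels)) == 10

    def test_survey_scale_plotting_positions(self):
        hm = em.generate(em.SynthConfig(seed=0))
        labels = em.assign_locales(hm.latitude, hm.longitude, n_locales=82, seed=1)
        assert len(labels) == 1083
        assert len(np.unique(labels)) == 82

    def test_k_too_large(self):
        with pytest.raises(ConfigError):
            em.assign_locales([30.0, 31.0], [-100.0, -99.0], n_locales=5)


class TestAggregate:
    def test_single_home_locale_identity(self):
        df = pd.DataFrame({"latitude": [30.0], "longitude": [-90.0], "ermi": [4.2]})
        out = em.aggregate(df, [0])
        assert out.loc[0, "mean_lat"] == 30.0
        assert out.loc[0, "ermi"] == 4.2
        assert out.loc[0, "n_homes"] == 1

    def test_two_home_midpoint(self):
        df = pd.DataFrame(
            {"latitude": [30.0, 32.0], "longitude": [-90.0, -92.0],
             "ermi": [2.0, 4.0]}
        )
        out = em.aggregate(df, [0, 0])
        assert out.loc[0, "ermi"] == pytest.approx(3.0)

    def test_weighted_grand_mean_identity(self, rng):
        n = 200
        df = pd.DataFrame(
            {"latitude": rng.uniform(25, 49, n),
             "longitude": rng.uniform(-124, -67, n),
             "ermi": rng.standard_normal(n)}
        )
        labels = rng.integers(0, 13, n)
        out = em.aggregate(df, labels)
        grand = (out["ermi"] * out["n_homes"]).sum() / out["n_homes"].sum()
        assert grand == pytest.approx(df["ermi"].mean(), abs=1e-10)

    def test_empty_locale_rejected(self):
        df = pd.DataFrame({"latitude": [30.0, 31.0], "longitude": [-90.0, -91.0]})
        with pytest.raises(InputError):
            em.aggregate(df, [0, 2], n_locales=3)


class TestJenks:
    def test_forced_singleton_classes(self):
        cls = em.jenks_breaks([1.0, 2.0, 3.0, 4.0, 5.0], n_classes=5)
        assert cls.classes.tolist() == [1, 2, 3, 4, 5]

    def test_obvious_gaps(self):
        cls = em.jenks_breaks([1.0, 2.0, 10.0, 11.0, 100.0, 101.0], n_classes=3)
        assert cls.classes.tolist() == [1, 1, 2, 2, 3, 3]
        assert cls.breaks == (2.0, 11.0)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            vals = rng.normal(0, 10, 12)
            cls = em.jenks_breaks(vals, n_classes=5)
            assert classification_cost(vals, cls) == pytest.approx(
                jenks_oracle_cost(vals, 5), abs=1e-9
            )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        vals=st.lists(
            st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
            min_size=5, max_size=14,
        ),
        k=st.integers(min_value=2, max_value=5),
    )
    def test_optimality_property(self, vals, k):
        """DP cost equals exhaustive enumeration for all n <= 14, k <= 5."""
        if len(np.unique(vals)) < k:
            return
        cls = em.jenks_breaks(np.array(vals), n_classes=k)
        assert classification_cost(vals, cls) <= jenks_oracle_cost(vals, k) + 1e-6

    def test_monotone_classes(self, rng):
        vals = rng.standard_normal(40)
        cls = em.jenks_breaks(vals, n_classes=5)
        order = np.argsort(vals)
        assert (np.diff(cls.classes[order]) >= 0).all()

    def test_degrades_below_distinct_count(self):
        with pytest.warns(RuntimeWarning, match="distinct"):
            cls = em.jenks_breaks([1.0, 1.0, 2.0, 2.0], n_classes=5)
        assert cls.n_classes == 2

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            em.jenks_breaks([], n_classes=5)

    def test_classify_tie_to_lower_class(self):
        assert classify([1.0, 2.0, 2.5], (2.0,)).tolist() == [1, 1, 2]


class TestExportLayer:
    @pytest.fixture()
    def layer_inputs(self, rng):
        n = 82
        summaries = pd.DataFrame(
            {
                "locale_id": np.arange(n),
                "n_homes": rng.integers(1, 30, n),
                "mean_lat": rng.uniform(25, 49, n),
                "mean_lon": rng.uniform(-124, -67, n),
                "ermi": rng.normal(5, 4, n),
            }
        )
        cls = em.jenks_breaks(summaries["ermi"].to_numpy(), 5, variable="ermi")
        return summaries, cls

    def test_geojson_round_trip(self, tmp_path, layer_inputs):
        summaries, cls = layer_inputs
        path = tmp_path / "layer.geojson"
        em.export_layer(summaries, cls, path)
        back = read_layer(path)
        assert len(back) == 82
        np.testing.assert_allclose(back["value"], summaries["ermi"], atol=1e-9)
        np.testing.assert_allclose(back["mean_lon"], summaries["mean_lon"],
                                   atol=1e-9)
        assert set(back["class"]) <= {1, 2, 3, 4, 5}
        # grey/size ranks mirror the class (1 = lightest/smallest)
        assert (back["grey_rank"] == back["class"]).all()

    def test_geojson_is_lon_lat(self, tmp_path, layer_inputs):
        import json

        summaries, cls = layer_inputs
        path = tmp_path / "layer.geojson"
        em.export_layer(summaries, cls, path)
        geo = json.loads(path.read_text())
        assert geo["type"] == "FeatureCollection"
        first = geo["features"][0]["geometry"]["coordinates"]
        assert first[0] == pytest.approx(summaries["mean_lon"].iloc[0])
        assert first[1] == pytest.approx(summaries["mean_lat"].iloc[0])

    def test_csv_mirror(self, tmp_path, layer_inputs):
        summaries, cls = layer_inputs
        path = tmp_path / "layer.csv"
        em.export_layer(summaries, cls, path, format="csv")
        back = read_layer(path)
        np.testing.assert_allclose(back["value"], summaries["ermi"], atol=1e-9)

    def test_empty_rejected(self, tmp_path, layer_inputs):
        _, cls = layer_inputs
        empty = pd.DataFrame(columns=["locale_id", "n_homes", "mean_lat",
                                      "mean_lon", "ermi"])
        target = tmp_path / "nothing.geojson"
        with pytest.raises(InputError):
            em.export_layer(empty, cls, target)
        assert not target.exists()


def test_aggregation_invariant_to_home_order(rng):
    n = 120
    df = pd.DataFrame(
        {"latitude": rng.uniform(25, 49, n), "longitude": rng.uniform(-124, -67, n),
         "ermi": rng.standard_normal(n)}
    )
    labels = rng.integers(0, 7, n)
    out1 = em.aggregate(df, labels)
    perm = rng.permutation(n)
    out2 = em.aggregate(df.iloc[perm].reset_index(drop=True), labels[perm])
    merged = out1.merge(out2, on="locale_id", suffixes=("_a", "_b"))
    np.testing.assert_allclose(merged["ermi_a"], merged["ermi_b"], atol=1e-12)
    cls1 = em.jenks_breaks(out1["ermi"].to_numpy(), 5)
    cls2 = em.jenks_breaks(out2.sort_values("locale_id")["ermi"].to_numpy(), 5)
    assert cls1.breaks == cls2.breaks
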