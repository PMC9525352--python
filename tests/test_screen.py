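"""Screen ingestion, percent-of-control normalization, significance flags."""

import numpy as np
import pandas as pd
import pytest

from dntbattery import (
    build_series,
    flag_significant,
    percent_of_control,
    read_screen_table,
)
from dntbattery.errors import (
    AnalysisError,
    ConfigurationError,
    NormalizationError,
    SchemaError,
)


def make_table(rows):
    return pd.DataFrame(
        rows, columns=["compound", "endpoint", "concentration_uM", "replicate", "value", "role"]
    )


@pytest.fixture
def tiny_table(tmp_path):
    df = make_table(
        [
            ("A", "NPC2a", 1.0, 1, 55.0, "dnt"),
            ("A", "NPC2a", 1.0, 2, 60.0, "dnt"),
            ("A", "NPC2a", 0.0, 1, 100.0, "dnt"),
        ]
    )
    path = tmp_path / "screen.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadScreenTable:
    def test_identity_parse(self, tiny_table):
        wells, pairing = read_screen_table(tiny_table, {"NPC2a": ["LDH_72h", "LDH_120h"]})
        assert len(wells) == 3
        assert pairing["NPC2a"] == ["LDH_72h", "LDH_120h"]

    def test_missing_concentration_column_is_schema_error(self, tmp_path):
        df = make_table([("A", "NPC2a", 1.0, 1, 55.0, "dnt")]).drop(columns="concentration_uM")
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="concentration_uM"):
            read_screen_table(path, {"NPC2a": ["LDH"]})

    def test_unpaired_dnt_endpoint_is_configuration_error(self, tiny_table):
        with pytest.raises(ConfigurationError, match="NPC2a"):
            read_screen_table(tiny_table, {"NPC5": ["LDH"]})


class TestPercentOfControl:
    def test_divides_by_matched_control_mean(self):
        df = make_table(
            [
                ("A", "E", 0.0, 1, 90.0, "dnt"),
                ("A", "E", 0.0, 2, 110.0, "dnt"),
                ("A", "E", 1.0, 1, 80.0, "dnt"),
            ]
        )
        out = percent_of_control(df)
        assert out.loc[out["concentration_uM"] == 1.0, "value_pct_control"].iloc[0] == 80.0
        # the control wells themselves average exactly 100
        assert out.loc[out["concentration_uM"] == 0.0, "value_pct_control"].mean() == 100.0

    def test_value_equal_to_control_mean_maps_to_100(self):
        df = make_table(
            [
                ("A", "E", 0.0, 1, 42.0, "dnt"),
                ("A", "E", 0.0, 2, 42.0, "dnt"),
                ("A", "E", 1.0, 1, 42.0, "dnt"),
            ]
        )
        out = percent_of_control(df)
        assert out.loc[out["concentration_uM"] == 1.0, "value_pct_control"].iloc[0] == 100.0

    def test_zero_controls_raise(self):
        df = make_table(
            [
                ("A", "E", 0.0, 1, 0.0, "dnt"),
                ("A", "E", 0.0, 2, 0.0, "dnt"),
                ("A", "E", 1.0, 1, 50.0, "dnt"),
            ]
        )
        with pytest.raises(NormalizationError):
            percent_of_control(df)

    def test_idempotent_on_normalized_data(self):
        rng = np.random.default_rng(0)
        rows = [("A", "E", 0.0, r, 100.0, "dnt") for r in range(1, 4)]
        rows += [("A", "E", c, r, float(rng.uniform(20, 120)), "dnt")
                 for c in (0.1, 1.0) for r in range(1, 4)]
        df = make_table(rows)
        once = percent_of_control(df)
        again = percent_of_control(once.assign(value=once["value_pct_control"]))
        np.testing.assert_allclose(
            once["value_pct_control"], again["value_pct_control"], rtol=1e-12
        )

    def test_plate_matched_controls(self):
        rows = [
            ("A", "E", 0.0, 1, 50.0, "dnt", "p1"),
            ("A", "E", 0.0, 2, 50.0, "dnt", "p1"),
            ("A", "E", 1.0, 1, 25.0, "dnt", "p1"),
            ("A", "E", 0.0, 1, 200.0, "dnt", "p2"),
            ("A", "E", 0.0, 2, 200.0, "dnt", "p2"),
            ("A", "E", 1.0, 1, 100.0, "dnt", "p2"),
        ]
        df = pd.DataFrame(
            rows,
            columns=["compound", "endpoint", "concentration_uM", "replicate", "value", "role", "plate_id"],
        )
        out = percent_of_control(df)
        treated = out[out["concentration_uM"] == 1.0]
        np.testing.assert_allclose(treated["value_pct_control"], [50.0, 50.0])


def anova_table(shift, n=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for c, mu in [(0.0, 100.0), (1.0, 100.0), (10.0, 100.0 + shift)]:
        for r in range(1, n + 1):
            rows.append(("A", "E", c, r, mu + rng.normal(0, 1.0), "dnt"))
    return make_table(rows)


class TestFlagSignificant:
    def test_identical_constant_groups_yield_no_flags(self):
        df = make_table(
            [("A", "E", c, r, 100.0, "dnt") for c in (0.0, 1.0, 10.0) for r in (1, 2, 3)]
        )
        flags = flag_significant(df)
        assert not flags["significant"].any()

    def test_group_shifted_ten_sd_is_flagged(self):
        flags = flag_significant(anova_table(shift=10.0, seed=1))
        flagged = flags.set_index("concentration_uM")["significant"]
        assert flagged[10.0]
        assert not flagged[1.0]

    def test_flags_invariant_under_affine_rescaling(self):
        df = anova_table(shift=10.0, seed=2)
        scaled = df.assign(value=df["value"] * 3.7)
        pd.testing.assert_series_equal(
            flag_significant(df)["significant"], flag_significant(scaled)["significant"]
        )

    def test_boundary_p_equal_alpha_is_inclusive(self):
        flags = flag_significant(anova_table(shift=10.0, seed=3))
        p = float(flags.set_index("concentration_uM")["p_adjusted"][10.0])
        refl = flag_significant(anova_table(shift=10.0, seed=3), alpha=p)
        assert refl.set_index("concentration_uM")["significant"][10.0]

    def test_insufficient_replication_raises(self):
        df = make_table(
            [("A", "E", 0.0, 1, 100.0, "dnt"), ("A", "E", 1.0, 1, 50.0, "dnt")]
        )
        with pytest.raises(AnalysisError):
            flag_significant(df)


class TestBuildSeries:
    def test_series_sorted_and_controls_captured(self):
        df = make_table(
            [
                ("A", "E", 10.0, 1, 40.0, "dnt"),
                ("A", "E", 10.0, 2, 42.0, "dnt"),
                ("A", "E", 1.0, 1, 80.0, "dnt"),
                ("A", "E", 1.0, 2, 78.0, "dnt"),
                ("A", "E", 0.0, 1, 99.0, "dnt"),
                ("A", "E", 0.0, 2, 101.0, "dnt"),
            ]
        )
        series = build_series(percent_of_control(df), {"E": "decrease"}, {"E": ["LDH"]})
        ser = series[("A", "E")]
        np.testing.assert_allclose(ser.concentrations, [1.0, 10.0])
        assert ser.reference_endpoints == ["LDH"]
        assert len(ser.control_values) == 2
        assert ser.ns.tolist() == [2, 2]
        assert np.isfinite(ser.sems).all()
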