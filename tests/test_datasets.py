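"""Case generation, splitting, scenarios, and the CSV dialect."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmikit import (
    CaseDataset,
    GeneratorConfig,
    generate_dataset,
    generate_scenario,
    read_csv,
    rectal_temperature,
    split_dataset,
    write_csv,
)


@pytest.fixture(scope="module")
def default_11k():
    return generate_dataset(GeneratorConfig(count=11000, seed=42))


class TestGenerator:
    def test_rejection_rate_matches_truncated_normal_mass(self, default_11k):
        # P(49.75 <= N(70,10) < 100.25) ~ 0.9773 after rounding to 0.5 kg
        p = stats.norm.cdf(100.25, 70, 10) - stats.norm.cdf(49.75, 70, 10)
        n = len(default_11k)
        sigma = np.sqrt(11000 * p * (1 - p))
        assert abs(n - 11000 * p) < 5 * sigma

    def test_weights_rounded_and_bounded(self, default_11k):
        m = default_11k.frame["m"]
        assert ((m >= 50) & (m <= 100)).all()
        assert np.allclose(m * 2, np.round(m * 2))

    def test_cases_respect_physical_restrictions(self, default_11k):
        f = default_11k.frame
        assert (f["Tr"] > f["Ta"]).all()
        assert (f["Tr"] <= 37.2).all()

    def test_empty_request_yields_empty_dataset(self):
        data = generate_dataset(GeneratorConfig(count=0, seed=0))
        assert len(data) == 0 and data.X.shape == (0, 4)

    def test_deterministic_given_seed(self):
        a = generate_dataset(GeneratorConfig(count=500, seed=9))
        b = generate_dataset(GeneratorConfig(count=500, seed=9))
        assert a.frame.equals(b.frame)
        c = generate_dataset(GeneratorConfig(count=500, seed=10))
        assert not a.frame.equals(c.frame)

    def test_grid_marginals_are_uniform(self, default_11k):
        f = default_11k.frame.iloc[:10000]
        for col, grid in (
            ("t", np.arange(1.0, 18.01, 0.5)),
            ("Ta", np.arange(-10.0, 35.01, 0.5)),
            ("cf", np.array([0.7, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4])),
        ):
            counts = f[col].value_counts().reindex(np.round(grid, 6), fill_value=0)
            assert stats.chisquare(counts).pvalue > 0.01

    def test_weight_mean_matches_truncated_normal(self, default_11k):
        # oracle: expectation of the rounded-then-truncated normal
        grid = np.arange(50.0, 100.5, 0.5)
        mass = stats.norm.cdf(grid + 0.25, 70, 10) - stats.norm.cdf(grid - 0.25, 70, 10)
        expected = np.sum(grid * mass) / np.sum(mass)
        assert abs(default_11k.frame["m"].mean() - expected) < 0.5

    def test_rectal_temperature_regenerates_bit_identically(self, default_11k):
        f = default_11k.frame.head(200)
        regenerated = [
            rectal_temperature(r.t, r.m, r.cf, r.Ta) for r in f.itertuples()
        ]
        assert (np.array(regenerated) == f["Tr"].to_numpy()).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(weight_sigma=-1)
        with pytest.raises(ValueError):
            GeneratorConfig(weight_bounds=(100, 50))


class TestSplit:
    def test_split_sizes_follow_rounding_rule(self, default_11k):
        train, test = split_dataset(default_11k, 0.25, seed=0)
        n = len(default_11k)
        assert len(test) == int(np.rint(0.25 * n))
        assert len(train) == n - len(test)

    def test_smallest_split(self):
        data = CaseDataset(
            pd.DataFrame(
                {"m": [70.0] * 4, "cf": 1.0, "Tr": [30, 31, 32, 33], "Ta": 20.0, "t": [1, 2, 3, 4]}
            )
        )
        train, test = split_dataset(data, 0.25, seed=1)
        assert (len(train), len(test)) == (3, 1)

    def test_partition_is_disjoint_and_exhaustive(self, default_11k):
        train, test = split_dataset(default_11k, 0.25, seed=3)
        merged = (
            pd.concat([train.frame, test.frame])
            .sort_values(list(train.frame.columns))
            .reset_index(drop=True)
        )
        original = (
            default_11k.frame.sort_values(list(train.frame.columns)).reset_index(drop=True)
        )
        assert merged.equals(original)

    def test_deterministic_partition(self, default_11k):
        a = split_dataset(default_11k, 0.25, seed=5)
        b = split_dataset(default_11k, 0.25, seed=5)
        assert a[0].frame.equals(b[0].frame) and a[1].frame.equals(b[1].frame)

    def test_rejects_degenerate_inputs(self, default_11k):
        with pytest.raises(ValueError):
            split_dataset(default_11k, 0.0, seed=0)
        one = CaseDataset(default_11k.frame.head(1))
        with pytest.raises(ValueError):
            split_dataset(one, 0.5, seed=0)


class TestScenarios:
    @pytest.mark.parametrize(
        "sid, n, t_hi, sizes", [(1, 275, 18.0, (165, 55, 55)), (2, 184, 7.0, (110, 37, 37))]
    )
    def test_scenario_composition(self, sid, n, t_hi, sizes):
        split = generate_scenario(sid, seed=21)
        f = split.dataset.frame
        assert len(split.dataset) == n
        assert ((f["Ta"] >= 4.5) & (f["Ta"] <= 18.0)).all()
        assert ((f["t"] >= 1 / 3) & (f["t"] <= t_hi)).all()
        assert ((f["m"] >= 50) & (f["m"] <= 100)).all()
        assert (len(split.train), len(split.validation), len(split.test)) == sizes
        parts = pd.concat([split.train.frame, split.validation.frame, split.test.frame])
        assert len(parts) == n

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            generate_scenario(3, seed=0)

    def test_scenario_deterministic(self):
        a = generate_scenario(1, seed=4)
        b = generate_scenario(1, seed=4)
        assert a.dataset.frame.equals(b.dataset.frame)
        assert a.test.frame.equals(b.test.frame)


class TestCsvDialect:
    def test_lossless_round_trip(self, tmp_path, default_11k):
        path = tmp_path / "cases.csv"
        data = CaseDataset(default_11k.frame.head(100))
        write_csv(data, path)
        back = read_csv(path, require_labels=True)
        assert back.frame.equals(data.frame)
        regenerated = [
            rectal_temperature(r.t, r.m, r.cf, r.Ta) for r in back.frame.itertuples()
        ]
        assert np.allclose(regenerated, back.frame["Tr"], atol=1e-6)

    def test_header_layout(self, tmp_path, default_11k):
        path = tmp_path / "cases.csv"
        write_csv(CaseDataset(default_11k.frame.head(3)), path)
        assert path.read_text().splitlines()[0] == "m,cf,Tr,Ta,t"

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("m,cf,Tr,Ta,t\n70,1.0,30.0,20.0,5.0\n70,1.0,oops,20.0,5.0\n")
        with pytest.raises(ValueError, match="line 3"):
            read_csv(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("m,cf\n70,1.0\n")
        with pytest.raises(ValueError, match="expected columns"):
            read_csv(path)

    def test_unlabelled_input_allowed_unless_labels_required(self, tmp_path):
        path = tmp_path / "cases.csv"
        path.write_text("m,cf,Tr,Ta\n70,1.0,30.0,20.0\n")
        data = read_csv(path)
        assert np.isnan(data.y).all()
        with pytest.raises(ValueError):
            read_csv(path, require_labels=True)


class TestCoolingCase:
    def test_round_trip_through_record_view(self, default_11k):
        from pmikit import CoolingCase

        subset = CaseDataset(default_11k.frame.head(5))
        cases = list(subset.cases())
        assert all(isinstance(c, CoolingCase) for c in cases)
        rebuilt = CaseDataset.from_cases(cases)
        assert rebuilt.frame.equals(subset.frame)

    def test_physical_invariants_enforced(self):
        from pmikit import CoolingCase

        with pytest.raises(ValueError):
            CoolingCase(m=70, cf=1.0, Tr=19.0, Ta=20.0, t=5.0)
        with pytest.raises(ValueError):
            CoolingCase(m=70, cf=1.0, Tr=38.0, Ta=20.0, t=0.0)
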