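"""Generators: survey structure, practice sizes, registry series, fixture."""

import numpy as np
import pandas as pd
import pytest

from dogpop import (
    MixtureParams,
    RegistrationSeries,
    apply_quota,
    generate_breed_county_tables,
    generate_practice_sizes,
    generate_registry,
    generate_survey,
    paper_survey_fixture,
)
from dogpop.synthetic_data import (
    FIXTURE_MEMBERSHIP_COUNTS,
    TABLE3_AREAS,
    BreedCountyConfig,
    ConfigurationError,
    SurveyConfig,
    joint_from_marginals,
)


class TestGenerateSurvey:
    def test_no_owners_means_no_dogs(self):
        ds = generate_survey(SurveyConfig(p_own=0.0, seed=1))
        assert ds.dogs == []
        assert all(c.n_dogs == 0 for c in ds.calls)

    def test_quota_fills_to_510_when_valid_calls_abound(self):
        config = SurveyConfig(
            n_areas=17, calls_per_area=120, quota=30, p_valid=0.8, seed=2
        )
        ds = apply_quota(generate_survey(config), 30)
        assert sum(c.valid for c in ds.calls) == 17 * 30 == 510

    def test_membership_marginal_matches_joint(self):
        """Pooled empirical insured share stays within 3 binomial SEs of the
        marginal implied by the joint flag table."""
        flagged = total = 0
        for seed in range(4):
            config = SurveyConfig(
                n_areas=20,
                calls_per_area=400,
                p_valid=0.9,
                p_own=0.6,
                extra_dog_rate=0.5,
                area_effect_sd=0.0,
                membership_joint=joint_from_marginals(0.7, 0.4, 0.3, 0.05),
                seed=seed,
            )
            ds = generate_survey(config)
            flagged += sum(d.insured for d in ds.dogs)
            total += len(ds.dogs)
        assert total > 5000
        se = np.sqrt(0.4 * 0.6 / total)
        assert abs(flagged / total - 0.4) < 3 * se

    def test_dog_counts_conserved_per_area(self):
        ds = generate_survey(SurveyConfig(seed=4))
        by_area = ds.dogs_by_area()
        for area in ds.areas:
            declared = sum(
                c.n_dogs for c in ds.calls if c.area_id == area and c.valid
            )
            assert declared == len(by_area[area])

    def test_seed_determinism_is_byte_identical(self, tmp_path):
        frames = []
        for run in range(2):
            ds = generate_survey(SurveyConfig(seed=99))
            path = tmp_path / f"calls{run}.csv"
            ds.calls_frame().to_csv(path, index=False)
            frames.append(path.read_bytes())
        assert frames[0] == frames[1]

    @pytest.mark.parametrize("field,value", [("p_valid", 1.5), ("p_own", -0.1)])
    def test_invalid_probability_names_the_field(self, field, value):
        config = SurveyConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=field):
            generate_survey(config)

    def test_joint_table_must_normalise(self):
        joint = joint_from_marginals(0.5, 0.5, 0.5, 0.5)
        joint[(0, 0, 0, 0)] += 0.1
        with pytest.raises(ConfigurationError, match="membership_joint"):
            generate_survey(SurveyConfig(membership_joint=joint))


class TestGeneratePracticeSizes:
    def test_degenerate_component_returns_constant(self):
        m = MixtureParams([1.0], [3000.0], [1e-9])
        assert (generate_practice_sizes(m, 50, seed=1) == 3000).all()

    def test_zero_n_is_empty(self):
        m = MixtureParams([1.0], [3000.0], [10.0])
        assert generate_practice_sizes(m, 0, seed=1).size == 0

    def test_negative_n_rejected(self):
        m = MixtureParams([1.0], [3000.0], [10.0])
        with pytest.raises(ValueError):
            generate_practice_sizes(m, -1)

    def test_sample_mean_matches_mixture_mean(self):
        m = MixtureParams([0.5, 0.3, 0.2], [1000, 5000, 15000], [200, 800, 2000])
        x = generate_practice_sizes(m, 5000, seed=2)
        assert (x >= 1).all()
        # mixture variance = sum z(b^2 + a^2) - mean^2
        var = float(m.weights @ (m.sds**2 + m.means**2) - m.mean() ** 2)
        se = np.sqrt(var / 5000)
        assert abs(x.mean() - m.mean()) < 3 * se


class TestGenerateRegistry:
    def test_constant_model(self):
        series = generate_registry(1999, 2008, lambda y: 1000)
        assert isinstance(series, RegistrationSeries)
        assert (series.counts == 1000).all()
        assert list(series.years) == list(range(1999, 2009))

    def test_linear_trend_exact(self):
        series = generate_registry(2000, 2004, lambda y: 100 + 10 * (y - 2000))
        assert list(series.counts) == [100, 110, 120, 130, 140]

    def test_poisson_noise_centres_on_model(self):
        means = np.array(
            [
                generate_registry(
                    2000, 2001, lambda y: 500, seed=s, noise="poisson"
                ).counts
                for s in range(1000)
            ]
        ).mean(axis=0)
        se = np.sqrt(500 / 1000)
        assert np.abs(means - 500).max() < 3 * se

    def test_year_order_enforced(self):
        with pytest.raises(ValueError):
            generate_registry(2005, 2000, lambda y: 1)


class TestBreedCountyTables:
    def _config(self, **kw):
        base = dict(
            breed_shares={"A": 0.5, "B": 0.5},
            county_rows=[("X", 0.6, 100.0, 1e6), ("Y", 0.4, 300.0, 2e6)],
            n_breed_total=10_000,
        )
        base.update(kw)
        return BreedCountyConfig(**base)

    def test_single_breed_takes_all(self):
        breeds, _ = generate_breed_county_tables(
            self._config(breed_shares={"Only": 1.0}), seed=1
        )
        assert breeds["count"].sum() == breeds.loc[0, "count"] == 10_000

    def test_equal_shares_split_evenly(self):
        breeds, _ = generate_breed_county_tables(self._config(), seed=2)
        se = np.sqrt(10_000 * 0.25)
        assert abs(breeds["count"].iloc[0] - 5000) < 3 * se

    def test_zero_share_county_retained(self):
        cfg = self._config(
            county_rows=[("X", 1.0, 100.0, 1e6), ("Z", 0.0, 50.0, 1e5)]
        )
        _, counties = generate_breed_county_tables(cfg, seed=3)
        assert set(counties["county"]) == {"X", "Z"}
        assert counties.set_index("county").loc["Z", "count"] == 0

    def test_unnormalised_shares_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_breed_county_tables(
                self._config(breed_shares={"A": 0.5, "B": 0.6}), seed=4
            )


class TestPaperFixture:
    def test_published_totals(self, raw_fixture):
        assert len(raw_fixture.calls) == 1656
        assert sum(c.valid for c in raw_fixture.calls) == 614
        assert len(raw_fixture.dogs) == 181

    def test_per_area_columns(self, raw_fixture):
        by_area = raw_fixture.dogs_by_area()
        for area, _, owning, dogs in TABLE3_AREAS:
            households = {d.household_id for d in by_area[area]}
            assert len(households) == owning
            assert len(by_area[area]) == dogs

    def test_membership_counts_reproduce_printed_percentages(self, raw_fixture):
        counts = raw_fixture.flag_counts()
        assert counts == FIXTURE_MEMBERSHIP_COUNTS
        printed = {"vet": 71.82, "insured": 40.33, "kc": 30.39, "pets": 2.76}
        for name, pct in printed.items():
            assert round(100 * counts[name] / 181, 2) == pct
            # uniqueness: no other integer count rounds to the same value
            matches = [
                k for k in range(182) if round(100 * k / 181, 2) == pct
            ]
            assert matches == [counts[name]]

    def test_overlap_cells_sum_to_total(self, raw_fixture):
        from dogpop import venn_overlap

        table = venn_overlap(raw_fixture)
        assert sum(table.cells.values()) == 181

    def test_fixture_is_deterministic(self):
        a = paper_survey_fixture().dogs_frame()
        b = paper_survey_fixture().dogs_frame()
        pd.testing.assert_frame_equal(a, b)
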