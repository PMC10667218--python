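"""Synthetic campaign generator: counts, determinism, censoring,
correlation and range recovery."""

import numpy as np
import pytest

from hydrometal.datagen import (
    DEFAULT_DETECTION_LIMIT,
    GeneratorConfig,
    apply_censoring,
    generate_samples,
    nearest_psd,
    reference_survey,
)
from hydrometal.records import METALS, to_frame

from conftest import make_record


def big_single_season(n=1000, seed=7, **kw):
    return GeneratorConfig(
        stations={f"S{i}": "r1" for i in range(n)},
        seasons=("spring",),
        replicates=1,
        censor_stations={},
        replicate_cv=1e-9,
        seed=seed,
        **kw,
    )


class TestGenerate:
    def test_count_is_stations_x_seasons_x_replicates(self, small_config):
        recs = generate_samples(small_config)
        assert len(recs) == 10 * 2 * 3

    def test_seeded_determinism_byte_identical(self, small_config):
        a = to_frame(generate_samples(GeneratorConfig(seed=42)))
        b = to_frame(generate_samples(GeneratorConfig(seed=42)))
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = to_frame(generate_samples(GeneratorConfig(seed=43)))
        assert a.to_csv(index=False) != c.to_csv(index=False)

    def test_uncensored_marginals_respect_ranges(self, small_config):
        recs = generate_samples(small_config)
        for rec in recs:
            for m in METALS:
                if not rec.below_detection[m]:
                    lo, hi = small_config.ranges[m]
                    assert lo <= rec.conc[m] <= hi

    def test_censored_cells_flagged(self, small_config):
        recs = generate_samples(small_config)
        for sid in ("S1", "S2", "S10"):
            cell = [r for r in recs
                    if r.sample_id == sid and r.season == "spring"]
            assert cell and all(
                r.below_detection[m] for r in cell for m in METALS
            )

    def test_correlation_recovery_at_n_1000(self):
        """Empirical Pearson r within 0.05 of each target (0.01 at
        r >= 0.99) for the near-singular spring structure."""
        cfg = big_single_season()
        df = to_frame(generate_samples(cfg))
        cols = [df[f"{m}_mg_l"].to_numpy() for m in METALS]
        emp = np.corrcoef(cols)
        target = cfg.correlations["spring"]
        for i in range(5):
            for j in range(i + 1, 5):
                tol = 0.01 if target[i, j] >= 0.99 else 0.05
                assert abs(emp[i, j] - target[i, j]) <= tol, (
                    METALS[i], METALS[j], emp[i, j], target[i, j]
                )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(stations={})
        with pytest.raises(ValueError):
            GeneratorConfig(seasons=())
        with pytest.raises(ValueError):
            GeneratorConfig(replicates=0)
        with pytest.raises(ValueError):
            GeneratorConfig(ranges={**dict(GeneratorConfig().ranges),
                                    "cd": (0.01, 0.005)})


class TestPSDRepair:
    def test_valid_matrix_unchanged(self):
        c = np.eye(5)
        assert np.allclose(nearest_psd(c), c)

    def test_mild_indefiniteness_repaired(self):
        c = np.full((5, 5), 0.99)
        np.fill_diagonal(c, 1.0)
        c[0, 1] = c[1, 0] = -0.2  # inconsistent with the near-1 block
        fixed = nearest_psd(c, tol=2.0)
        w = np.linalg.eigvalsh(fixed)
        assert w.min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)

    def test_gross_indefiniteness_rejected(self):
        c = np.full((5, 5), 0.99)
        np.fill_diagonal(c, 1.0)
        c[0, 1] = c[1, 0] = -0.9
        with pytest.raises(ValueError):
            nearest_psd(c, tol=0.1)

    def test_asymmetry_rejected(self):
        c = np.eye(5)
        c[0, 1] = 0.5
        with pytest.raises(ValueError):
            nearest_psd(c)


class TestCensoring:
    def test_half_lod_substitution(self):
        rec = make_record({**{m: 0.01 for m in METALS}, "cd": 0.001})
        out = apply_censoring([rec], {"cd": 0.004}, "half_lod")
        assert out[0].conc["cd"] == pytest.approx(0.002)
        assert out[0].below_detection["cd"]
        assert not out[0].below_detection["cu"]

    def test_above_limit_untouched(self):
        rec = make_record({m: 0.01 for m in METALS})
        out = apply_censoring([rec], {"cd": 0.004}, "half_lod")
        assert out[0].conc["cd"] == 0.01
        assert not out[0].below_detection["cd"]

    def test_zero_policy(self):
        rec = make_record({**{m: 0.01 for m in METALS}, "pb": 0.001})
        out = apply_censoring([rec], DEFAULT_DETECTION_LIMIT, "zero")
        assert out[0].conc["pb"] == 0.0

    def test_drop_policy_removes_records(self):
        recs = [make_record({m: 0.01 for m in METALS}) for _ in range(59)]
        recs.append(make_record({**{m: 0.01 for m in METALS}, "zn": 0.001}))
        out = apply_censoring(recs, DEFAULT_DETECTION_LIMIT, "drop")
        assert len(out) == 59

    def test_unknown_policy(self):
        with pytest.raises(ValueError):
            apply_censoring([], {}, "interpolate")


class TestReferenceSurvey:
    def test_el_maleh_winter_urban_vector(self, survey):
        rec = next(r for r in survey if r.river == "el_maleh"
                   and r.season == "winter" and r.sample_id == "S4")
        assert rec.conc == {"cd": 0.01, "cu": 0.01, "fe": 0.009,
                            "pb": 0.01, "zn": 0.009}

    def test_hassar_spring_uniform_vector(self, spring_vector):
        assert all(v == 0.009 for v in spring_vector.conc.values())

    def test_lagoon_winter_peaks(self, survey):
        rec = next(r for r in survey if r.river == "lagoon"
                   and r.season == "winter")
        assert rec.conc["pb"] == 0.22
        assert rec.conc["zn"] == 0.17

    def test_ambiguous_sentence_kept_as_two_variants(self):
        both = reference_survey("both")
        literal = reference_survey("literal")
        swapped = reference_survey("range_consistent")
        assert len(both) == len(literal) + 2 == len(swapped) + 2
        lit_s2 = next(r for r in literal if r.sample_id == "S2"
                      and r.season == "winter")
        swp_s2 = next(r for r in swapped if r.sample_id == "S2"
                      and r.season == "winter")
        assert lit_s2.conc["cu"] == swp_s2.conc["fe"] == 0.34

    def test_spring_censoring_flags(self, survey):
        bdl = [r for r in survey if r.season == "spring"
               and r.sample_id in ("S1", "S2", "S10")]
        assert len(bdl) == 3
        for r in bdl:
            assert all(r.below_detection[m] for m in METALS)
            assert all(v == 0.002 for v in r.conc.values())  # LOD/2


def test_generator_config_yaml_round_trip(tmp_path):
    cfg = GeneratorConfig(seed=5)
    path = tmp_path / "gen.yaml"
    cfg.to_yaml(path)
    back = GeneratorConfig.from_yaml(path)
    assert back.stations == cfg.stations
    assert back.seasons == cfg.seasons
    assert back.ranges == cfg.ranges
    for season in cfg.correlations:
        assert np.allclose(back.correlations[season],
                           cfg.correlations[season])
    assert to_frame(generate_samples(back)).equals(
        to_frame(generate_samples(cfg))
    )


def test_standards_yaml_round_trip(tmp_path, standards_csf):
    path = tmp_path / "std.yaml"
    standards_csf.to_yaml(path)
    from hydrometal.standards import StandardsTable

    back = StandardsTable.from_yaml(path)
    assert back.limits == standards_csf.limits
    assert back.rfd == standards_csf.rfd
    assert back.csf == standards_csf.csf
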