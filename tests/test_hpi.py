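"""Pollution-index chain: weights, sub-indices, totals, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrometal.hpi import (
    classify_hpi,
    contamination_status,
    hpi_table,
    hpi_total,
    parameter_weights,
    relative_weight,
)
from hydrometal.records import METALS
from hydrometal.standards import StandardsTable

from conftest import make_record


def brute_force_hpi(conc: dict[str, float], limits: dict[str, float],
                    exclude=()) -> float:
    """Independent oracle: sum over metals of normalised limit-reciprocal
    weight times concentration/limit ratio."""
    total_rw = sum(1.0 / v for v in limits.values())
    return sum(
        (1.0 / limits[m] / total_rw) * (conc[m] / limits[m])
        for m in conc
        if m not in exclude
    )


class TestWeights:
    def test_relative_weight_is_reciprocal(self):
        assert relative_weight(0.003) == pytest.approx(333.3333333, rel=1e-9)
        assert relative_weight(1.0) == 1.0

    def test_relative_weight_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            relative_weight(0.0)

    def test_who_parameter_weights(self, standards):
        # sum Rw = 1/0.003 + 1/2 + 1/0.3 + 1/0.01 + 1/3 = 437.5
        wp = parameter_weights(standards)
        assert wp["cd"] == pytest.approx(333.3333333 / 437.5, rel=1e-9)
        assert wp["pb"] == pytest.approx(100.0 / 437.5, rel=1e-9)
        assert sum(wp.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_metal_weight_is_one(self):
        wp = parameter_weights(StandardsTable(limits={"cd": 0.003}))
        assert wp == {"cd": 1.0}

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            parameter_weights(StandardsTable(limits={}))

    @given(
        limits=st.lists(
            st.floats(1e-4, 1e3, allow_nan=False), min_size=1, max_size=5
        )
    )
    @settings(deadline=None)
    def test_weights_always_normalised(self, limits):
        table = StandardsTable(
            limits={f"m{i}": v for i, v in enumerate(limits)}
        )
        assert sum(parameter_weights(table).values()) == pytest.approx(
            1.0, abs=1e-9
        )


class TestContaminationStatus:
    @pytest.mark.parametrize(
        "conc, limit, expected",
        [(0.009, 0.003, 3.0), (0.5, 0.5, 1.0), (0.0, 0.1, 0.0)],
    )
    def test_ratio(self, conc, limit, expected):
        assert contamination_status(conc, limit) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            contamination_status(0.1, 0.0)
        with pytest.raises(ValueError):
            contamination_status(-0.1, 0.1)


class TestTotal:
    def test_spring_vector_matches_hand_oracle(self, standards, spring_vector):
        res = hpi_total(spring_vector, standards)
        expected = brute_force_hpi(spring_vector.conc, standards.limits)
        assert res.hpi_total == pytest.approx(expected, abs=1e-12)
        assert res.hpi_total == pytest.approx(2.4916645714, abs=1e-9)
        assert res.band == "high/unfit"

    def test_concentrations_at_limits_score_one(self, standards):
        rec = make_record({m: standards.limits[m] for m in METALS})
        assert hpi_total(rec, standards).hpi_total == pytest.approx(
            1.0, abs=1e-12
        )

    def test_exclusion_drops_subindex_without_reweighting(
        self, standards, spring_vector
    ):
        full = hpi_total(spring_vector, standards)
        no_cd = hpi_total(spring_vector, standards, exclude={"cd"})
        assert no_cd.hpi_total == pytest.approx(
            full.hpi_total - full.subindex["cd"], abs=1e-12
        )
        assert no_cd.hpi_total == pytest.approx(0.2059502857, abs=1e-9)
        # weights are NOT renormalised on exclusion
        assert sum(no_cd.wp.values()) == pytest.approx(1.0, abs=1e-12)

    def test_missing_standard_errors(self, spring_vector):
        partial = StandardsTable(limits={"cd": 0.003})
        with pytest.raises(KeyError):
            hpi_total(spring_vector, partial)

    @given(
        conc=st.lists(st.floats(0, 10, allow_nan=False), min_size=5,
                      max_size=5),
        scale=st.floats(0.1, 10, allow_nan=False),
    )
    @settings(deadline=None, max_examples=50)
    def test_homogeneity_and_oracle_equivalence(self, conc, scale):
        standards = StandardsTable.default()
        c = dict(zip(METALS, conc))
        base = hpi_total(make_record(c), standards).hpi_total
        assert base == pytest.approx(
            brute_force_hpi(c, standards.limits), abs=1e-12
        )
        scaled = hpi_total(
            make_record({m: v * scale for m, v in c.items()}), standards
        ).hpi_total
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-12)

    @given(
        conc=st.lists(st.floats(0, 1, allow_nan=False), min_size=5,
                      max_size=5),
        metal=st.sampled_from(METALS),
        bump=st.floats(1e-6, 1.0, allow_nan=False),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotonicity(self, conc, metal, bump):
        standards = StandardsTable.default()
        c = dict(zip(METALS, conc))
        before = hpi_total(make_record(c), standards).hpi_total
        c[metal] += bump
        after = hpi_total(make_record(dict(c)), standards).hpi_total
        assert after >= before


class TestClassification:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0.0, "negligible/excellent"),
            (0.2, "negligible/excellent"),
            (0.25, "negligible/excellent"),  # edge belongs to lower band
            (0.3, "very_low/good"),
            (0.5, "very_low/good"),
            (0.6, "low/poor"),
            (0.9, "moderate/very_poor"),
            (1.0, "moderate/very_poor"),
            (1.001, "high/unfit"),
            (2.49, "high/unfit"),
        ],
    )
    def test_bands(self, value, band):
        assert classify_hpi(value) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_hpi(-0.1)


def test_hpi_table_means_replicates(standards):
    recs = [
        make_record({m: 0.01 for m in METALS}, replicate=1),
        make_record({m: 0.02 for m in METALS}, replicate=2),
    ]
    df = hpi_table(recs, standards)
    assert len(df) == 1
    expected = brute_force_hpi({m: 0.015 for m in METALS}, standards.limits)
    assert df["hpi_total"].iloc[0] == pytest.approx(expected, abs=1e-12)
    each = hpi_table(recs, standards, replicate_mode="each")
    assert len(each) == 2
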