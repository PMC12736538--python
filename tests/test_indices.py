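"""Index formulas: worked examples from the reference tables plus the
algebraic invariants (additivity, antisymmetry, reciprocity, scaling)."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from intercrop import (
    GasExchangeReading,
    IndexInputs,
    aggressivity,
    competitive_ratio,
    compute_all,
    compute_index_set,
    cumulative_yield,
    lec,
    ler,
    partial_ler,
    percent_of_control,
    photosynthetic_rate,
    relative_crowding,
    spi,
)
from intercrop.errors import DomainError, MissingCellError, ValidationError
from intercrop.trial_data import PlotObservation, TrialDataset

# MA(2:2) and MA(3:1)/MA(3:2)/MA(3:3) yield quadruples from the reference
# tables, 2023: maize grain (intercrop, mono) and alfalfa forage.
MA22_2023 = IndexInputs(7800.9, 8366.1, 9470.3, 11779.3, 0.5, 0.5)
MA33_2023 = IndexInputs(6771.4, 6867.4, 9470.3, 11779.3, 0.5, 0.5)
MA31_2023 = IndexInputs(8534.0, 5245.1, 9470.3, 11779.3, 0.75, 0.25)
MA32_2023 = IndexInputs(8245.8, 5655.1, 9470.3, 11779.3, 0.6, 0.4)


def proportional(y_mm=9000.0, y_am=12000.0, z_m=0.5):
    """Intercrop yields exactly proportional to sowing shares (neutral case)."""
    return IndexInputs(z_m * y_mm, (1 - z_m) * y_am, y_mm, y_am, z_m, 1 - z_m)


yields = st.floats(100.0, 20000.0, allow_nan=False)
fractions = st.floats(0.05, 0.99)
shares = st.floats(0.1, 0.9)


@st.composite
def valid_inputs(draw):
    y_mm = draw(yields)
    y_am = draw(yields)
    z_m = draw(shares)
    return IndexInputs(
        draw(fractions) * y_mm, draw(fractions) * y_am, y_mm, y_am, z_m, 1 - z_m
    )


class TestPartialLer:
    def test_reference_value(self):
        assert partial_ler(7800.9, 9470.3) == pytest.approx(0.8237, abs=5e-5)

    def test_identity_and_zero(self):
        assert partial_ler(123.4, 123.4) == pytest.approx(1.0)
        assert partial_ler(0.0, 500.0) == 0.0

    def test_nonpositive_mono_rejected(self):
        with pytest.raises(DomainError):
            partial_ler(100.0, 0.0)


class TestLerLec:
    def test_reference_values(self):
        assert ler(MA22_2023) == pytest.approx(1.534, abs=5e-4)
        assert round(ler(MA22_2023), 1) == 1.5
        assert ler(MA33_2023) == pytest.approx(1.298, abs=5e-4)
        assert lec(MA22_2023) == pytest.approx(0.585, abs=5e-4)
        assert round(lec(MA22_2023), 1) == 0.6

    def test_proportional_partition_gives_unit_ler(self):
        assert ler(proportional()) == pytest.approx(1.0)

    def test_lec_symmetric_product(self):
        inp = IndexInputs(750.0, 750.0, 1000.0, 1000.0)
        assert lec(inp) == pytest.approx(0.5625)
        assert lec(IndexInputs(0.0, 750.0, 1000.0, 1000.0)) == 0.0

    @given(valid_inputs())
    def test_ler_additivity_lec_multiplicativity(self, inp):
        p_m = partial_ler(inp.y_im, inp.y_mm)
        p_a = partial_ler(inp.y_ia, inp.y_am)
        assert ler(inp) == pytest.approx(p_m + p_a)
        assert lec(inp) == pytest.approx(p_m * p_a)

    @given(valid_inputs())
    def test_ler_monotone_in_intercrop_yields(self, inp):
        up = IndexInputs(
            inp.y_im * 1.01, inp.y_ia, inp.y_mm, inp.y_am, inp.z_maize, inp.z_alfalfa
        )
        assert ler(up) > ler(inp)
        worse_mono = IndexInputs(
            inp.y_im, inp.y_ia, inp.y_mm * 1.01, inp.y_am, inp.z_maize, inp.z_alfalfa
        )
        assert ler(worse_mono) < ler(inp)


class TestSpi:
    def test_reference_value(self):
        assert spi(MA22_2023) == pytest.approx(14527.0, abs=0.5)

    def test_single_crop_limit(self):
        assert spi(IndexInputs(5000.0, 0.0, 9000.0, 12000.0)) == pytest.approx(5000.0)

    def test_algebraic_identity_at_mono_yields(self):
        assert spi(IndexInputs(9000.0, 12000.0, 9000.0, 12000.0)) == pytest.approx(18000.0)


class TestRelativeCrowding:
    def test_reference_values(self):
        k = relative_crowding(MA22_2023)
        assert k.k_maize == pytest.approx(4.673, abs=5e-4)
        assert k.k_alfalfa == pytest.approx(2.451, abs=5e-4)
        assert k.k_system == pytest.approx(11.45, abs=5e-3)
        assert k.flags == ()

    def test_neutral_partition_gives_unit_coefficients(self):
        k = relative_crowding(proportional())
        assert k.k_maize == pytest.approx(1.0)
        assert k.k_alfalfa == pytest.approx(1.0)
        assert k.k_system == pytest.approx(1.0)

    def test_degenerate_yield_flagged_infinite_not_negative(self):
        k = relative_crowding(IndexInputs(9000.0, 6000.0, 9000.0, 12000.0))
        assert math.isinf(k.k_maize) and k.k_maize > 0
        assert math.isinf(k.k_system)
        assert "k_maize:infinite" in k.flags
        above = relative_crowding(IndexInputs(9500.0, 6000.0, 9000.0, 12000.0))
        assert math.isinf(above.k_maize)


class TestAggressivity:
    def test_reference_value_sign_from_formula(self):
        a_m, a_a = aggressivity(MA31_2023)
        assert a_m == pytest.approx(-0.580, abs=5e-4)
        assert a_a == pytest.approx(0.580, abs=5e-4)

    def test_proportional_partition_is_neutral(self):
        a_m, a_a = aggressivity(proportional(z_m=0.7))
        assert a_m == pytest.approx(0.0, abs=1e-12)

    @given(valid_inputs())
    def test_antisymmetry(self, inp):
        a_m, a_a = aggressivity(inp)
        assert a_a == -a_m


class TestCompetitiveRatio:
    def test_reference_value(self):
        cr_m, cr_a, flags = competitive_ratio(MA32_2023)
        assert cr_m == pytest.approx(1.209, abs=5e-4)
        assert flags == ()

    def test_proportional_partition_is_unity(self):
        cr_m, cr_a, _ = competitive_ratio(proportional(z_m=0.6))
        assert cr_m == pytest.approx(1.0)
        assert cr_a == pytest.approx(1.0)

    def test_zero_partial_ler_flagged(self):
        cr_m, cr_a, flags = competitive_ratio(IndexInputs(5000.0, 0.0, 9000.0, 12000.0))
        assert math.isinf(cr_m) and cr_a == 0.0
        assert "cr_maize:infinite" in flags

    @given(valid_inputs())
    def test_reciprocal_product(self, inp):
        cr_m, cr_a, _ = competitive_ratio(inp)
        assert cr_m * cr_a == pytest.approx(1.0)


class TestCumulativeAndPercent:
    def test_reference_sums(self):
        assert cumulative_yield(8211.4, 7213.1) == pytest.approx(15424.5)
        assert cumulative_yield(7800.9, 6868.3) == pytest.approx(14669.2)
        assert cumulative_yield(42.0, 0.0) == 42.0

    def test_percent_of_control_conventions(self):
        p = percent_of_control(199.97, 205.7)
        assert p.truncated == 97 and p.rounded == 97
        assert percent_of_control(5.0, 5.0).exact == pytest.approx(100.0)
        assert percent_of_control(8534.0, 9470.3).exact == pytest.approx(90.1, abs=0.05)
        # the two integer renderings straddle a .5 boundary differently
        p2 = percent_of_control(935.0, 1000.0)
        assert (p2.truncated, p2.rounded) == (93, 94)

    def test_percent_requires_positive_control(self):
        with pytest.raises(DomainError):
            percent_of_control(10.0, 0.0)


class TestPhotosyntheticRate:
    @pytest.mark.parametrize("delta, expected", [(0.0, 0.0), (21.6, 1.0), (43.2, 2.0)])
    def test_chamber_constant_linearity(self, delta, expected):
        reading = GasExchangeReading(n1=400.0, n2=400.0 + delta)
        assert photosynthetic_rate(reading) == pytest.approx(expected)

    def test_negative_rate_allowed_but_flagged(self):
        with pytest.warns(UserWarning, match="CO2 release"):
            rate = photosynthetic_rate(GasExchangeReading(n1=400.0, n2=390.0))
        assert rate < 0


@given(valid_inputs(), st.floats(0.1, 10.0))
def test_scale_invariance_of_ratio_indices(inp, c):
    scaled = IndexInputs(
        c * inp.y_im, c * inp.y_ia, c * inp.y_mm, c * inp.y_am, inp.z_maize, inp.z_alfalfa
    )
    assert ler(scaled) == pytest.approx(ler(inp))
    assert lec(scaled) == pytest.approx(lec(inp))
    assert aggressivity(scaled)[0] == pytest.approx(aggressivity(inp)[0])
    assert competitive_ratio(scaled)[0] == pytest.approx(competitive_ratio(inp)[0])
    k0, k1 = relative_crowding(inp), relative_crowding(scaled)
    assert k1.k_system == pytest.approx(k0.k_system)
    assert spi(scaled) == pytest.approx(c * spi(inp), rel=1e-9)


def test_neutral_partition_full_fixed_point():
    inp = proportional(z_m=0.75)
    s = compute_index_set(inp)
    assert s.ler == pytest.approx(1.0)
    assert s.lec == pytest.approx(0.75 * 0.25)
    assert s.aggressivity_maize == pytest.approx(0.0, abs=1e-12)
    assert s.cr_maize == pytest.approx(1.0)
    assert s.k_maize == pytest.approx(1.0)
    assert s.k_alfalfa == pytest.approx(1.0)


class TestComputeAll:
    def test_reference_composition(self, reference_ds):
        s = compute_all(reference_ds, 2023, "MA(2:2)", "forage", "ratio_of_means")
        assert s.ler == pytest.approx(1.534, abs=5e-4)
        assert s.lec == pytest.approx(0.585, abs=5e-4)
        assert s.cumulative_yield == pytest.approx(14669.2, abs=0.5)

    def test_modes_coincide_without_variance(self):
        obs = []
        cells = [
            ("MM", "maize", "grain_yield", 9000.0),
            ("AM", "alfalfa", "forage_yield", 12000.0),
            ("AM", "alfalfa", "biomass_dm", 9000.0),
            ("MA(1:1)", "maize", "grain_yield", 7000.0),
            ("MA(1:1)", "alfalfa", "forage_yield", 8000.0),
            ("MA(1:1)", "alfalfa", "biomass_dm", 6000.0),
        ]
        for cfg, crop, trait, v in cells:
            for rep in (1, 2, 3):
                obs.append(PlotObservation(2023, cfg, rep, crop, trait, v, "kg ha-1"))
        ds = TrialDataset.from_observations(obs, allow_unbalanced=True)
        a = compute_all(ds, 2023, "MA(1:1)", mode="ratio_of_means")
        b = compute_all(ds, 2023, "MA(1:1)", mode="per_replicate_mean")
        for name in ("ler", "lec", "spi", "k_system", "aggressivity_maize", "cr_maize"):
            assert getattr(a, name) == pytest.approx(getattr(b, name))

    def test_missing_mono_control_raises(self):
        obs = [
            PlotObservation(2023, "MA(1:1)", rep, crop, trait, 100.0, "kg ha-1")
            for rep in (1, 2, 3)
            for crop, trait in [
                ("maize", "grain_yield"),
                ("alfalfa", "forage_yield"),
                ("alfalfa", "biomass_dm"),
            ]
        ]
        ds = TrialDataset.from_observations(obs)
        with pytest.raises(MissingCellError, match="MM"):
            compute_all(ds, 2023, "MA(1:1)")

    def test_mono_pattern_rejected(self, reference_ds):
        with pytest.raises(ValidationError):
            compute_all(reference_ds, 2023, "MM")
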