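"""Isotope arithmetic: δ notation, B value, %Ndfa and the N budget."""

import math
import warnings

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from ndfa import isotopes as iso

DELTAS = st.floats(min_value=-50, max_value=50)
POSITIVE = st.floats(min_value=1e-3, max_value=1e3)


# ---------------------------------------------------------------------------
# delta notation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "factor, expected",
    [(1.0, 0.0), (1.001, 1.0), (1.00395, 3.95)],
)
def test_delta15n_from_ratio(factor, expected):
    ratio = iso.IsotopeRatio(r_sample=factor * iso.ATM_15N_14N_RATIO)
    assert iso.delta15n(ratio) == pytest.approx(expected, abs=1e-9)


def test_nonpositive_ratio_rejected():
    with pytest.raises(iso.InvalidInputError):
        iso.IsotopeRatio(r_sample=0.0)
    with pytest.raises(iso.InvalidInputError):
        iso.IsotopeRatio(r_sample=0.003, r_atm=-1.0)


@settings(derandomize=True)
@given(delta=DELTAS)
def test_delta_notation_round_trip(delta):
    """Reconstructing the sample ratio from δ recovers the input ratio."""
    r = iso.ratio_from_delta15n(delta)
    assert iso.delta15n(iso.IsotopeRatio(r_sample=r)) == pytest.approx(delta, abs=1e-9)


# ---------------------------------------------------------------------------
# whole-plant delta and B value
# ---------------------------------------------------------------------------


def _organ(organ, delta, n):
    return iso.OrganMeasurement(organ=organ, delta15n=delta, n_content=n)


def test_whole_plant_equal_organs_is_identity():
    assert iso.whole_plant_delta15n(
        _organ("shoot", -3.0, 17.0), _organ("root", -3.0, 5.0)
    ) == pytest.approx(-3.0)


def test_whole_plant_weighted_mean():
    value = iso.whole_plant_delta15n(_organ("shoot", -4.0, 100.0), _organ("root", -2.0, 50.0))
    assert value == pytest.approx(-10.0 / 3.0)


def test_whole_plant_zero_n_is_degenerate():
    with pytest.raises(iso.DegenerateInputError):
        iso.whole_plant_delta15n(_organ("shoot", -4.0, 0.0), _organ("root", -2.0, 0.0))


@settings(derandomize=True)
@given(ds=DELTAS, dr=DELTAS, ns=POSITIVE, nr=POSITIVE)
def test_whole_plant_bounded_by_organs(ds, dr, ns, nr):
    value = iso.whole_plant_delta15n(_organ("shoot", ds, ns), _organ("root", dr, nr))
    lo, hi = min(ds, dr), max(ds, dr)
    assert lo - 1e-9 <= value <= hi + 1e-9


@pytest.mark.parametrize(
    "shoot_deltas, expected",
    [([-3.68], -3.68), ([-3.68, -3.99], -3.835), ([-4.0, -4.0], -4.0)],
)
def test_b_value_is_mean_of_shoot_deltas(shoot_deltas, expected):
    landraces = tuple(
        (f"lr{i}", _organ("shoot", d, 100.0), _organ("root", d + 1.0, 30.0))
        for i, d in enumerate(shoot_deltas)
    )
    assert iso.b_value(iso.BValueExperiment(landraces)) == pytest.approx(expected)


def test_b_value_ignores_roots_and_whole_plant():
    """Roots shift whole-plant δ¹⁵N but must never shift the B value."""
    shoot = _organ("shoot", -3.68, 100.0)
    for root_delta in (-2.6, 5.0):
        exp = iso.BValueExperiment((("x", shoot, _organ("root", root_delta, 50.0)),))
        assert iso.b_value(exp) == -3.68


def test_empty_b_experiment_rejected():
    with pytest.raises(iso.InvalidInputError):
        iso.BValueExperiment(())


# ---------------------------------------------------------------------------
# %Ndfa
# ---------------------------------------------------------------------------


def test_ndfa_matches_published_cell():
    assert iso.ndfa_percent(3.95, 1.03, -3.835) == pytest.approx(37.46, abs=0.5)


@pytest.mark.parametrize("leg, expected", [(3.95, 0.0), (-3.835, 100.0)])
def test_ndfa_dilution_extremes(leg, expected):
    assert iso.ndfa_percent(3.95, leg, -3.835) == pytest.approx(expected)


def test_ndfa_degenerate_denominator():
    with pytest.raises(iso.DegenerateInputError, match="denominator"):
        iso.ndfa_percent(3.95, 1.0, 3.95)


def test_ndfa_out_of_range_warns_and_returns_raw():
    with pytest.warns(iso.NdfaRangeWarning):
        value = iso.ndfa_percent(3.95, 5.0, -3.835)
    assert value < 0


def test_ndfa_clamp_mode():
    assert iso.ndfa_percent(3.95, 5.0, -3.835, clamp=True) == 0.0
    assert iso.ndfa_percent(3.95, -5.0, -3.835, clamp=True) == 100.0


@settings(derandomize=True)
@given(
    ref=st.floats(min_value=1.0, max_value=10.0),
    b=st.floats(min_value=-10.0, max_value=0.0),
    leg1=DELTAS,
    leg2=DELTAS,
)
def test_ndfa_strictly_decreasing_in_legume_delta(ref, b, leg1, leg2):
    lo, hi = sorted((leg1, leg2))
    assume(hi - lo > 1e-6)  # below float resolution the dilution ties
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", iso.NdfaRangeWarning)
        v_lo = iso.ndfa_percent(ref, lo, b)
        v_hi = iso.ndfa_percent(ref, hi, b)
    assert v_lo > v_hi


@settings(derandomize=True)
@given(
    ref=st.floats(min_value=0.5, max_value=10.0),
    b=st.floats(min_value=-10.0, max_value=0.0),
    t=st.floats(min_value=0.0, max_value=1.0),
)
def test_ndfa_bounded_when_legume_between_b_and_ref(ref, b, t):
    leg = b + t * (ref - b)
    with warnings.catch_warnings():
        # float rounding may push the endpoint cases past the bound by ~1 ulp
        warnings.simplefilter("ignore", iso.NdfaRangeWarning)
        assert -1e-9 <= iso.ndfa_percent(ref, leg, b) <= 100.0 + 1e-9


# ---------------------------------------------------------------------------
# N budget and upscaling
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "dm, n_pct, expected", [(0.0, 3.0, 0.0), (10.0, 3.0, 300.0), (20.40, 2.77, 565.08)]
)
def test_shoot_n_content(dm, n_pct, expected):
    assert iso.shoot_n_content(dm, n_pct) == pytest.approx(expected, rel=1e-6)


def test_shoot_n_content_rejects_negative():
    with pytest.raises(iso.InvalidInputError):
        iso.shoot_n_content(-1.0, 2.0)


@pytest.mark.parametrize(
    "within, between, per_hole, expected",
    [(1.0, 1.0, 1, 10_000.0), (0.20, 0.60, 2, 166_666.6667), (0.5, 0.4, 1, 50_000.0)],
)
def test_plant_density(within, between, per_hole, expected):
    design = iso.TrialDesign(within, between, per_hole)
    assert iso.plant_density(design) == pytest.approx(expected, rel=1e-4)


def test_plant_density_rejects_zero_spacing():
    with pytest.raises(iso.InvalidInputError):
        iso.TrialDesign(0.0, 0.6, 2)


@pytest.mark.parametrize(
    "ndfa, content, density, expected",
    [(0.0, 600.0, 166_666.7, 0.0), (50.0, 600.0, 166_666.6667, 50.0), (37.46, 567.09, 166_666.6667, 35.4)],
)
def test_n_fixed(ndfa, content, density, expected):
    assert iso.n_fixed(ndfa, content, density) == pytest.approx(expected, abs=0.11)


@settings(derandomize=True)
@given(
    ndfa=st.floats(min_value=0, max_value=100),
    content=st.floats(min_value=0, max_value=2000),
    k=st.floats(min_value=0.1, max_value=10),
)
def test_n_fixed_linear_in_each_argument(ndfa, content, k):
    density = 166_666.6667
    base = iso.n_fixed(ndfa, content, density)
    assert iso.n_fixed(k * ndfa, content, density) == pytest.approx(k * base, rel=1e-9, abs=1e-12)
    assert iso.n_fixed(ndfa, k * content, density) == pytest.approx(k * base, rel=1e-9, abs=1e-12)
    assert iso.n_fixed(ndfa, content, k * density) == pytest.approx(k * base, rel=1e-9, abs=1e-12)


def test_soil_n_uptake_is_difference():
    assert iso.soil_n_uptake(100.0, 40.0) == 60.0
    assert iso.soil_n_uptake(94.5, 35.5) == pytest.approx(59.0)


def test_cn_ratio():
    assert iso.cn_ratio(30.0, 3.0) == pytest.approx(10.0)
    assert iso.cn_ratio(2.5, 2.5) == 1.0
    with pytest.raises(iso.DegenerateInputError):
        iso.cn_ratio(40.0, 0.0)


@pytest.mark.parametrize(
    "mass, n, density, expected",
    [(0.0, 10, 166_666.7, 0.0), (89.0, 10, 166_666.6667, 1483.3), (10.0, 1, 10_000.0, 100.0)],
)
def test_grain_yield_per_ha(mass, n, density, expected):
    assert iso.grain_yield_per_ha(mass, n, density) == pytest.approx(expected, abs=0.05)


def test_grain_yield_rejects_zero_plants():
    with pytest.raises(iso.InvalidInputError):
        iso.grain_yield_per_ha(10.0, 0, 1000.0)


# ---------------------------------------------------------------------------
# budget closure
# ---------------------------------------------------------------------------


@settings(derandomize=True)
@given(
    leg=st.floats(min_value=-3.0, max_value=3.9),
    dm=st.floats(min_value=0.1, max_value=40.0),
    n_pct=st.floats(min_value=0.5, max_value=5.0),
)
def test_symbiosis_budget_closes_exactly(leg, dm, n_pct):
    result = iso.symbiosis_result(
        delta_ref=3.95, delta_leg=leg, b=-3.835, shoot_dm=dm, n_pct=n_pct,
        c_pct=40.0, density=166_666.6667,
    )
    assert result.n_fixed + result.soil_n_uptake == pytest.approx(result.total_n, abs=1e-12)
    if 0 <= result.ndfa_pct <= 100:
        assert 0 <= result.n_fixed <= result.total_n + 1e-12
    assert math.isfinite(result.cn_ratio)
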