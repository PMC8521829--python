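"""Feature formulas against naive-loop oracles, invariances, known values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgtb.features import (
    FEATURE_METHODS,
    SIGNAL_VARIANTS,
    base_feature_columns,
    energy_entropy,
    feature_table,
    kurtosis,
    relative_power,
    skewness,
    snr,
    zero_crossing_rate,
)

SETTINGS = settings(deadline=None, max_examples=60, derandomize=True)

finite_arrays = st.lists(
    st.floats(min_value=-100.0, max_value=100.0, allow_nan=False), min_size=4, max_size=200
).map(np.asarray)


# --- naive-loop oracles (explicit sums, population 1/N moments) -------------

def _oracle_moment(x, p):
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    sd = math.sqrt(var)
    if sd == 0:
        return float("nan")
    return sum(((v - mu) / sd) ** p for v in x) / n


def _oracle_entropy(x):
    total = 0.0
    for v in x:
        s = v * v
        if s > 0:
            total += s * math.log(s)
    return -total


def _oracle_zcr_literal(x):
    return sum(1 for v in x if v < 0) / len(x)


def _oracle_snr(x):
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    if var == 0:
        return float("nan")
    a = [abs(v) for v in x]
    mua = sum(a) / n
    vara = sum((v - mua) ** 2 for v in a) / n
    return vara / var


@SETTINGS
@given(finite_arrays)
def test_skewness_matches_oracle(x):
    got, want = skewness(x), _oracle_moment(x, 3)
    if math.isnan(want):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(want, abs=1e-10, rel=1e-10)


@SETTINGS
@given(finite_arrays)
def test_kurtosis_matches_oracle(x):
    got, want = kurtosis(x), _oracle_moment(x, 4)
    if math.isnan(want):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(want, abs=1e-10, rel=1e-10)


@SETTINGS
@given(finite_arrays)
def test_entropy_matches_oracle(x):
    assert energy_entropy(x) == pytest.approx(_oracle_entropy(x), abs=1e-7, rel=1e-10)


@SETTINGS
@given(finite_arrays)
def test_zcr_matches_oracle(x):
    assert zero_crossing_rate(x) == pytest.approx(_oracle_zcr_literal(x), abs=1e-12)


@SETTINGS
@given(finite_arrays)
def test_snr_matches_oracle(x):
    got, want = snr(x), _oracle_snr(x)
    if math.isnan(want):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(want, abs=1e-10, rel=1e-10)


# --- known values -----------------------------------------------------------

def test_known_values():
    assert skewness([0.0, 0.0, 0.0, 1.0]) == pytest.approx(2.0 / math.sqrt(3.0))
    assert kurtosis([1.0, -1.0, 1.0, -1.0]) == pytest.approx(1.0)
    assert energy_entropy([0.5, 0.5]) == pytest.approx(math.log(2.0) / 2.0 * 2.0)
    assert zero_crossing_rate([-1.0, 2.0, -3.0, 4.0]) == pytest.approx(0.5)
    assert zero_crossing_rate([0.0, 1.0]) == 0.0  # strictly negative only
    assert zero_crossing_rate([-1.0, 1.0, -1.0], mode="sign_change") == pytest.approx(1.0)
    # |x| of a symmetric two-point signal is constant -> SNR 0
    assert snr([1.0, -1.0, 1.0, -1.0]) == pytest.approx(0.0)


def test_kurtosis_of_gaussian_near_three(rng):
    x = rng.normal(size=200_000)
    assert kurtosis(x) == pytest.approx(3.0, abs=0.1)


def test_relative_power_in_band_sine():
    fs = 360.0
    t = np.arange(4096) / fs
    x = np.sin(2 * np.pi * 10.0 * t)  # inside the 5-15 Hz band
    assert relative_power(x, fs) == pytest.approx(1.0, abs=1e-3)


def test_relative_power_out_of_band_sine():
    fs = 360.0
    t = np.arange(4096) / fs
    x = np.sin(2 * np.pi * 30.0 * t)  # inside ref band, outside 5-15 Hz
    assert relative_power(x, fs) < 0.05


def test_relative_power_bounds_and_validation():
    x = np.random.default_rng(0).normal(size=2000)
    rp = relative_power(x, 360.0)
    assert 0.0 <= rp <= 1.0
    with pytest.raises(ValueError):
        relative_power(x, fs=60.0)  # fs below twice ref upper edge


# --- invariances ------------------------------------------------------------

def test_moment_invariances(rng):
    x = rng.normal(size=500)
    for f in (skewness, kurtosis):
        assert f(3.0 * x + 7.0) == pytest.approx(f(x), rel=1e-9)
    assert skewness(-x) == pytest.approx(-skewness(x), rel=1e-9)
    assert snr(5.0 * x) == pytest.approx(snr(x), rel=1e-9)  # scale-invariant


def test_degenerate_inputs():
    assert math.isnan(skewness([2.0, 2.0, 2.0]))
    assert math.isnan(kurtosis([2.0, 2.0, 2.0]))
    assert math.isnan(snr([2.0, 2.0, 2.0]))
    assert energy_entropy([0.0, 0.0]) == 0.0
    with pytest.raises(ValueError):
        skewness([1.0])
    with pytest.raises(ValueError):
        zero_crossing_rate([1.0], mode="bogus")


# --- feature table ----------------------------------------------------------

def test_feature_table_structure(small_segments, small_table):
    assert list(small_table.columns) == ["record", "start_sample", "label"] + base_feature_columns()
    assert len(small_table) == len(small_segments)
    assert len(base_feature_columns()) == len(FEATURE_METHODS) * len(SIGNAL_VARIANTS) == 12


def test_feature_table_filtered_differs(small_table):
    # filtering changes the signal, so paired columns must differ
    for m in FEATURE_METHODS:
        assert not np.allclose(
            small_table[f"{m}_unfiltered"], small_table[f"{m}_filtered"], equal_nan=True
        )


def test_feature_table_rejects_filtered_input(small_segments):
    from ecgtb.preprocess import bandpass

    with pytest.raises(ValueError):
        feature_table([bandpass(small_segments[0])])
    with pytest.raises(ValueError):
        feature_table([])
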