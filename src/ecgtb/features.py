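"""The six scalar feature-engineering methods computed per ECG segment.

All statistics use population (1/N) moments, matching the study's printed
formulas.  Two of the definitions are deliberately literal rather than
conventional:

* ``zero_crossing_rate`` in ``literal`` mode is the fraction of strictly
  negative samples (the indicator-sum definition as printed); the familiar
  adjacent-sign-change estimator is available as ``mode="sign_change"`` and
  is never silently substituted.
* ``snr`` is the variance of ``|x|`` over the variance of ``x`` — the roles
  of "signal" and "noise" follow the printed definition, unusual as it is.

Features that are undefined on a segment (zero variance, zero reference
power) are returned as NaN and recorded as missing, never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import FilterSpec, bandpass
from .segments import EcgSegment

__all__ = [
    "FEATURE_METHODS",
    "SIGNAL_VARIANTS",
    "skewness",
    "kurtosis",
    "energy_entropy",
    "zero_crossing_rate",
    "snr",
    "relative_power",
    "feature_table",
    "base_feature_columns",
]

#: Canonical method order: skewness, kurtosis, entropy, zero-crossing rate,
#: signal-to-noise ratio, relative power.
FEATURE_METHODS = ("fS", "fK", "fE", "fZ", "fN", "fR")
SIGNAL_VARIANTS = ("unfiltered", "filtered")

#: Welch estimator settings for the relative-power feature (fixed for
#: bit-reproducibility): Hamming window, 512-sample segments, 50% overlap.
WELCH_NPERSEG = 512
WELCH_NOVERLAP = 256
WELCH_NFFT = 512


def _as_array(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample sequence")
    return x


def skewness(x) -> float:
    """Third standardized population moment; NaN for constant input."""
    x = _as_array(x)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean()
    sigma = x.std()  # population (1/N)
    if sigma == 0:
        return float("nan")
    return float(np.mean(((x - mu) / sigma) ** 3))


def kurtosis(x) -> float:
    """Fourth standardized population moment (non-excess); NaN for constant input."""
    x = _as_array(x)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        return float("nan")
    return float(np.mean(((x - mu) / sigma) ** 4))


def energy_entropy(x) -> float:
    """-sum(x^2 ln x^2) with the convention 0 ln 0 = 0."""
    x = _as_array(x)
    sq = x**2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(sq > 0, sq * np.log(sq), 0.0)
    return float(-terms.sum())


def zero_crossing_rate(x, mode: str = "literal") -> float:
    """Fraction of strictly negative samples (``literal``, the default) or
    adjacent sign changes / (N-1) (``sign_change``)."""
    x = _as_array(x)
    if len(x) < 1:
        raise ValueError("need at least 1 sample")
    if mode == "literal":
        return float(np.mean(x < 0))
    if mode == "sign_change":
        if len(x) < 2:
            return 0.0
        s = np.sign(x)
        return float(np.sum(s[1:] * s[:-1] < 0) / (len(x) - 1))
    raise ValueError(f"unknown mode {mode!r}")


def snr(x) -> float:
    """Variance of |x| divided by variance of x (population); NaN if x constant."""
    x = _as_array(x)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    denom = x.std() ** 2
    if denom == 0:
        return float("nan")
    return float(np.abs(x).std() ** 2 / denom)


def relative_power(
    x,
    fs: float,
    band: tuple[float, float] = (5.0, 15.0),
    ref: tuple[float, float] = (1.0, 40.0),
) -> float:
    """Welch band power in ``band`` relative to the ``ref`` band, in [0, 1].

    Band edges are inclusive on both ends.  NaN when the reference band
    carries no power (all-zero signal).
    """
    x = _as_array(x)
    if fs <= 2 * ref[1]:
        raise ValueError("sampling rate must exceed twice the reference upper edge")
    nperseg = min(WELCH_NPERSEG, len(x))
    noverlap = nperseg // 2 if nperseg < WELCH_NPERSEG else WELCH_NOVERLAP
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=max(WELCH_NFFT, nperseg),
    )
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    in_ref = (freqs >= ref[0]) & (freqs <= ref[1])
    denom = psd[in_ref].sum()
    if denom == 0:
        return float("nan")
    return float(psd[in_band].sum() / denom)


_DISPATCH = {
    "fS": lambda x, fs: skewness(x),
    "fK": lambda x, fs: kurtosis(x),
    "fE": lambda x, fs: energy_entropy(x),
    "fZ": lambda x, fs: zero_crossing_rate(x),
    "fN": lambda x, fs: snr(x),
    "fR": lambda x, fs: relative_power(x, fs),
}


def base_feature_columns() -> list[str]:
    """The 12 base feature column names in deterministic order."""
    return [f"{m}_{v}" for m in FEATURE_METHODS for v in SIGNAL_VARIANTS]


def feature_table(
    segments: list[EcgSegment], filter_spec: FilterSpec = FilterSpec()
) -> pd.DataFrame:
    """One row per segment: provenance, label, and the 12 base features
    (6 methods x unfiltered/filtered)."""
    if not segments:
        raise ValueError("no segments supplied")
    rows = []
    for seg in segments:
        if seg.filtered:
            raise ValueError("feature_table expects unfiltered segments")
        filt = bandpass(seg, filter_spec)
        row: dict[str, object] = {
            "record": seg.record_id,
            "start_sample": seg.start_sample,
            "label": seg.label,
        }
        for method in FEATURE_METHODS:
            fn = _DISPATCH[method]
            row[f"{method}_unfiltered"] = fn(seg.samples, seg.fs)
            row[f"{method}_filtered"] = fn(filt.samples, filt.fs)
        rows.append(row)
    cols = ["record", "start_sample", "label"] + base_feature_columns()
    return pd.DataFrame(rows, columns=cols)
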