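"""The seven-fold transformation map applied to every base feature.

phi(f) = [f, ln f, 1/f, sqrt f, f^2, f^3, asin f]

The source formulas are silent on out-of-domain inputs (ln or sqrt of a
negative, 1/0, asin outside [-1, 1]); the policy here is explicit and
conservative: literal math, undefined values become missing.  The one
exception is arcsine, which defaults to clipping its argument into [-1, 1]
(with a recorded clip count) — without it the asin column of any feature
exceeding 1 in magnitude (e.g. kurtosis, which is >= 1 by construction)
would be entirely void.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import base_feature_columns

__all__ = [
    "TRANSFORM_KINDS",
    "DomainPolicy",
    "transform_value",
    "transform_array",
    "expand_transforms",
]

#: Canonical transform order.
TRANSFORM_KINDS = ("identity", "log", "reciprocal", "sqrt", "square", "cube", "arcsine")


@dataclass(frozen=True)
class DomainPolicy:
    """How out-of-domain inputs are handled."""

    log_sqrt_negative: str = "missing"  # or "abs_with_flag"
    reciprocal_zero_eps: float = 0.0  # 0 -> exact zero becomes missing
    arcsine_out_of_range: str = "clip"  # or "missing"

    def __post_init__(self) -> None:
        if self.reciprocal_zero_eps < 0:
            raise ValueError("reciprocal_zero_eps must be >= 0")
        if self.log_sqrt_negative not in ("missing", "abs_with_flag"):
            raise ValueError("log_sqrt_negative must be 'missing' or 'abs_with_flag'")
        if self.arcsine_out_of_range not in ("clip", "missing"):
            raise ValueError("arcsine_out_of_range must be 'clip' or 'missing'")


DEFAULT_POLICY = DomainPolicy()


def transform_array(
    values: np.ndarray, kind: str, policy: DomainPolicy = DEFAULT_POLICY
) -> tuple[np.ndarray, int]:
    """Vectorized transform; returns (result, number of arcsine clips).

    Missing inputs (NaN) propagate; out-of-domain results become NaN (or are
    clipped, for arcsine under the default policy).
    """
    v = np.asarray(values, dtype=float)
    n_clipped = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "identity":
            out = v.copy()
        elif kind == "log":
            src = np.abs(v) if policy.log_sqrt_negative == "abs_with_flag" else v
            out = np.where(src > 0, np.log(np.where(src > 0, src, 1.0)), np.nan)
        elif kind == "reciprocal":
            zero = np.abs(v) <= policy.reciprocal_zero_eps
            out = np.where(zero, np.nan, 1.0 / np.where(zero, 1.0, v))
        elif kind == "sqrt":
            src = np.abs(v) if policy.log_sqrt_negative == "abs_with_flag" else v
            out = np.where(src >= 0, np.sqrt(np.where(src >= 0, src, 0.0)), np.nan)
        elif kind == "square":
            out = v**2
        elif kind == "cube":
            out = v**3
        elif kind == "arcsine":
            finite = np.isfinite(v)
            oob = finite & (np.abs(v) > 1)
            n_clipped = int(oob.sum())
            if policy.arcsine_out_of_range == "clip":
                out = np.arcsin(np.clip(v, -1.0, 1.0))
            else:
                out = np.where(oob, np.nan, np.arcsin(np.clip(v, -1.0, 1.0)))
            out = np.where(finite, out, np.nan)
        else:
            raise ValueError(f"unknown transform kind {kind!r}")
    out = np.where(np.isfinite(v), out, np.nan)
    return out, n_clipped


def transform_value(
    f: float, kind: str, policy: DomainPolicy = DEFAULT_POLICY
) -> float:
    """Scalar convenience wrapper around :func:`transform_array`."""
    out, _ = transform_array(np.asarray([f], dtype=float), kind, policy)
    return float(out[0])


def expand_transforms(
    table: pd.DataFrame, policy: DomainPolicy = DEFAULT_POLICY
) -> pd.DataFrame:
    """Expand the 12 base feature columns into 12 x 7 = 84 transformed columns.

    Column naming is ``<method>_<variant>__<kind>``; the identity column is a
    bitwise copy of its base column.  Per-column missing and clip counts are
    recorded in ``result.attrs["missing_counts"]`` / ``attrs["clip_counts"]``.
    """
    base_cols = base_feature_columns()
    missing = [c for c in base_cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks base columns: {missing}")
    meta_cols = [c for c in table.columns if c not in base_cols]
    out = table[meta_cols].copy()
    missing_counts: dict[str, int] = {}
    clip_counts: dict[str, int] = {}
    new_cols = {}
    for base in base_cols:
        values = table[base].to_numpy(dtype=float)
        for kind in TRANSFORM_KINDS:
            name = f"{base}__{kind}"
            transformed, n_clipped = transform_array(values, kind, policy)
            new_cols[name] = transformed
            missing_counts[name] = int(np.isnan(transformed).sum())
            if n_clipped:
                clip_counts[name] = n_clipped
    out = pd.concat([out, pd.DataFrame(new_cols, index=table.index)], axis=1)
    out.attrs["missing_counts"] = missing_counts
    out.attrs["clip_counts"] = clip_counts
    return out


def feature_transform_columns() -> list[str]:
    """All 84 expanded column names in deterministic order."""
    return [f"{b}__{k}" for b in base_feature_columns() for k in TRANSFORM_KINDS]
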