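"""Class-imbalance handling: random under-sampling (RUS) and SMOTE.

Both operate on the scalar evaluated feature column (the study classifies
one transformed feature at a time), balancing each binary trial:

* RUS subsamples the majority class uniformly without replacement down to the
  minority count (e.g. 283 Norm vs 66 APB -> 66 vs 66);
* SMOTE raises the minority class to the majority count by convex
  interpolation between a random minority sample and one of its k nearest
  minority neighbours (e.g. 66 APB -> 283 vs 283 Norm).

Balancing is applied to the whole dataset before the 70/30 split by default,
mirroring the study's ordering; a leakage-safe split-first mode (balance the
training fold only) is available in the study driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrialSpec",
    "BalanceResult",
    "random_undersample",
    "smote",
    "balance_dataset",
    "BALANCE_KINDS",
]

BALANCE_KINDS = ("unbalanced", "RUS", "SMOTE")


@dataclass(frozen=True)
class TrialSpec:
    """One binary classification trial of the study."""

    positive_class: str  # AF, PVC or APB
    balance: str = "unbalanced"
    seed: int = 0
    negative_class: str = "Norm"

    def __post_init__(self) -> None:
        if self.positive_class == self.negative_class:
            raise ValueError("positive and negative class must differ")
        if self.balance not in BALANCE_KINDS:
            raise ValueError(f"balance must be one of {BALANCE_KINDS}")


@dataclass
class BalanceResult:
    """A balanced (or passthrough) feature/label set.

    ``indices`` maps each retained original row back to its input position;
    SMOTE-generated rows carry index -1 and ``synthetic_mask`` True.
    """

    values: np.ndarray
    labels: np.ndarray
    synthetic_mask: np.ndarray
    indices: np.ndarray
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.values) == len(self.synthetic_mask) == len(self.indices) == n):
            raise ValueError("value/label/mask/index lengths must agree")


def _counts(labels: np.ndarray) -> dict[str, int]:
    uniq, cnt = np.unique(labels, return_counts=True)
    return {str(u): int(c) for u, c in zip(uniq, cnt)}


def _check_two_classes(labels: np.ndarray):
    """Return (minority_label, majority_label, counts) keeping label dtype."""
    uniq, cnt = np.unique(labels, return_counts=True)
    if len(uniq) != 2 or cnt.min() == 0:
        raise ValueError(
            f"need exactly two non-empty classes, got counts {_counts(labels)}"
        )
    order = np.argsort(cnt, kind="stable")  # ties: first-listed label is minority
    minority, majority = uniq[order[0]], uniq[order[1]]
    return minority, majority, {str(minority): int(cnt[order[0]]), str(majority): int(cnt[order[1]])}


def random_undersample(values, labels, seed: int = 0) -> BalanceResult:
    """Subsample the majority class uniformly without replacement."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    minority, majority, counts = _check_two_classes(labels)
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(labels), dtype=bool)
    keep[labels == minority] = True
    maj_idx = np.flatnonzero(labels == majority)
    chosen = rng.choice(maj_idx, size=int(np.sum(labels == minority)), replace=False)
    keep[chosen] = True
    idx = np.flatnonzero(keep)
    return BalanceResult(
        values=values[idx],
        labels=labels[idx],
        synthetic_mask=np.zeros(len(idx), dtype=bool),
        indices=idx,
        class_counts=_counts(labels[idx]),
    )


def smote(values, labels, k: int = 5, seed: int = 0) -> BalanceResult:
    """Raise the minority class to the majority count by 1-D SMOTE.

    Each synthetic value is x + u (x_nn - x) for a random minority sample x,
    one of its k nearest minority neighbours x_nn (absolute-difference
    metric), and u ~ Uniform(0, 1).  k is reduced when fewer neighbours
    exist; a singleton minority cannot be oversampled and raises.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    minority, majority, counts = _check_two_classes(labels)
    n_needed = int(np.sum(labels == majority)) - int(np.sum(labels == minority))
    rng = np.random.default_rng(seed)
    if n_needed == 0:
        return BalanceResult(
            values=values.copy(),
            labels=labels.copy(),
            synthetic_mask=np.zeros(len(labels), dtype=bool),
            indices=np.arange(len(labels)),
            class_counts=dict(counts),
        )
    min_vals = values[labels == minority]
    if len(min_vals) < 2:
        raise ValueError(
            "SMOTE needs at least two minority samples to interpolate; "
            f"got {len(min_vals)}"
        )
    k_eff = min(k, len(min_vals) - 1)
    # k nearest minority neighbours of each minority sample, |difference| metric
    diffs = np.abs(min_vals[:, None] - min_vals[None, :])
    np.fill_diagonal(diffs, np.inf)
    neighbour_idx = np.argsort(diffs, axis=1, kind="stable")[:, :k_eff]

    synth = np.empty(n_needed)
    for j in range(n_needed):
        i = int(rng.integers(len(min_vals)))
        nn = neighbour_idx[i, int(rng.integers(k_eff))]
        u = rng.random()
        synth[j] = min_vals[i] + u * (min_vals[nn] - min_vals[i])

    out_values = np.concatenate([values, synth])
    out_labels = np.concatenate([labels, np.full(n_needed, minority, dtype=labels.dtype)])
    mask = np.concatenate([np.zeros(len(values), bool), np.ones(n_needed, bool)])
    idx = np.concatenate([np.arange(len(values)), np.full(n_needed, -1)])
    return BalanceResult(
        values=out_values,
        labels=out_labels,
        synthetic_mask=mask,
        indices=idx,
        class_counts=_counts(out_labels),
    )


def balance_dataset(values, labels, kind: str, seed: int = 0, k: int = 5) -> BalanceResult:
    """Dispatch on the balance regime; ``unbalanced`` is a passthrough."""
    if kind == "unbalanced":
        values = np.asarray(values, dtype=float)
        labels = np.asarray(labels)
        _check_two_classes(labels)
        return BalanceResult(
            values=values.copy(),
            labels=labels.copy(),
            synthetic_mask=np.zeros(len(labels), bool),
            indices=np.arange(len(labels)),
            class_counts=_counts(labels),
        )
    if kind == "RUS":
        return random_undersample(values, labels, seed=seed)
    if kind == "SMOTE":
        return smote(values, labels, k=k, seed=seed)
    raise ValueError(f"unknown balance kind {kind!r}")
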