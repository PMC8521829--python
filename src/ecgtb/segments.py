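"""Core container for labeled 10-second ECG segments.

All downstream stages (filtering, feature extraction, balancing,
classification) operate on :class:`EcgSegment` objects, whether the samples
came from a WFDB record or from the in-package synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: The four rhythm classes of the study, in canonical order.
CLASS_LABELS = ("Norm", "AF", "PVC", "APB")


@dataclass
class EcgSegment:
    """One labeled ECG trace.

    Parameters
    ----------
    samples
        Signal samples in millivolts.
    fs
        Sampling rate in Hz (> 60).
    label
        Rhythm class, one of ``Norm``, ``AF``, ``PVC``, ``APB``.
    source
        ``"synthetic"`` or ``"wfdb"``.
    record_id
        Identifier of the originating record.
    start_sample
        0-based offset of the segment within its record.
    filtered
        Whether the bandpass filter has been applied.
    meta
        Free-form provenance (e.g. generated beat times and ectopy flags
        for synthetic segments).
    """

    samples: np.ndarray
    fs: float
    label: str
    source: str = "synthetic"
    record_id: str = ""
    start_sample: int = 0
    filtered: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 60:
            raise ValueError(f"sampling rate must exceed 60 Hz, got {self.fs}")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment samples must be finite")

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return len(self.samples) / self.fs
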