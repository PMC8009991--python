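"""Turn per-subject series and metadata into labeled, augmented samples.

Augmentation crops each 230-timepoint scan into five overlapping windows of
length T = 90 (stride 35, overlap 55), multiplying the sample count by five.
Response labeling applies the operational 20% seizure-reduction rule and
group assignment splits active subjects into responders / non-responders,
with sham subjects kept as their own group.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from tdcsgraph.synthetic_data import SubjectRecord

__all__ = [
    "SampleTimeSeries",
    "GROUPS",
    "label_response",
    "window_timeseries",
    "assign_groups",
    "make_samples",
]

# The three analysis groups.
GROUPS = ("active_responder", "active_nonresponder", "sham")


@dataclass
class SampleTimeSeries:
    """One augmented analysis window of a subject's scan."""

    subject_id: str
    condition: str  # "pre" | "post"
    window_index: int
    data: np.ndarray  # regions x T

    def __post_init__(self) -> None:
        if self.condition not in ("pre", "post"):
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def sample_id(self) -> str:
        return f"{self.subject_id}_{self.condition}_w{self.window_index}"

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]


def label_response(baseline: int, followup: int, threshold: float = 0.2) -> bool:
    """Apply the seizure-reduction response rule.

    A subject responds when the follow-up count is at least ``threshold``
    (default 20%) below baseline:  (baseline - followup)/baseline >= threshold.
    Computed with exact rational arithmetic so boundary cases like
    (5, 4) -> exactly 20% -> response are decided without float error.
    """
    if baseline <= 0:
        raise ValueError(
            "baseline seizure count must be positive (inclusion requires at "
            "least one seizure during the 4-week baseline)"
        )
    if followup < 0:
        raise ValueError("followup seizure count must be non-negative")
    reduction = Fraction(baseline - followup, baseline)
    return reduction >= Fraction(str(threshold))


def window_timeseries(
    ts: np.ndarray,
    subject_id: str = "",
    condition: str = "pre",
    T: int = 90,
    stride: int = 35,
) -> list[SampleTimeSeries]:
    """Crop a regions x n series into overlapping windows of length T.

    Windows start at 0, stride, 2*stride, ... while start + T <= n, giving
    floor((n - T)/stride) + 1 contiguous column slices; with the defaults
    (n = 230, T = 90, stride = 35) that is five windows overlapping by 55
    timepoints.
    """
    ts = np.asarray(ts)
    n = ts.shape[1]
    if n < T:
        raise ValueError(f"series has {n} timepoints, need at least T={T}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    windows = []
    for w, start in enumerate(range(0, n - T + 1, stride)):
        windows.append(
            SampleTimeSeries(
                subject_id=subject_id,
                condition=condition,
                window_index=w,
                data=ts[:, start : start + T].copy(),
            )
        )
    return windows


def assign_groups(
    subjects: Sequence[SubjectRecord], threshold: float = 0.2
) -> dict[str, str]:
    """Map subject_id -> group label.

    Active subjects split by :func:`label_response` on their seizure counts;
    sham subjects never carry a response label.
    """
    groups: dict[str, str] = {}
    for s in subjects:
        if s.arm == "sham":
            groups[s.subject_id] = "sham"
        else:
            responded = label_response(
                s.baseline_seizures, s.followup_seizures, threshold
            )
            groups[s.subject_id] = (
                "active_responder" if responded else "active_nonresponder"
            )
    return groups


def make_samples(
    series: Mapping[str, Mapping[str, np.ndarray]],
    T: int = 90,
    stride: int = 35,
) -> list[SampleTimeSeries]:
    """Window every subject's pre and post series into analysis samples.

    Pre and post windows of a subject are paired downstream by window_index;
    output order is (subject, condition in pre/post, window).
    """
    samples: list[SampleTimeSeries] = []
    for subject_id in series:
        for condition in ("pre", "post"):
            samples.extend(
                window_timeseries(
                    series[subject_id][condition],
                    subject_id=subject_id,
                    condition=condition,
                    T=T,
                    stride=stride,
                )
            )
    return samples
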