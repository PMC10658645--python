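"""Test-retest reproducibility metrics.

The coefficient of reproducibility (CoR) is 1.96 times the sample SD of
the per-subject signed difference between the two scans; the
coefficient of variation (CoV) is the pooled SD of all datapoints of a
technique (both repeats) divided by their pooled mean.  Subjects with
an excluded scan are removed from both scans of the paired statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RepeatedMeasures",
    "coefficient_of_reproducibility",
    "coefficient_of_variation",
]


@dataclass(frozen=True)
class RepeatedMeasures:
    """Paired test-retest measurements of one technique."""

    subject_ids: tuple
    technique: str
    ratio_scan1: np.ndarray
    ratio_scan2: np.ndarray
    exclusions: tuple[tuple[object, int, str], ...] = field(default_factory=tuple)
    # exclusions: (subject_id, scan number 1|2, reason)

    def __post_init__(self) -> None:
        s1 = np.asarray(self.ratio_scan1, dtype=float)
        s2 = np.asarray(self.ratio_scan2, dtype=float)
        ids = tuple(self.subject_ids)
        if not (len(ids) == s1.size == s2.size):
            raise ValueError("subject_ids, ratio_scan1 and ratio_scan2 must share length")
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "ratio_scan1", s1)
        object.__setattr__(self, "ratio_scan2", s2)
        object.__setattr__(self, "exclusions", tuple(self.exclusions))

    def _included(self) -> np.ndarray:
        excluded_subjects = {e[0] for e in self.exclusions}
        return np.array([sid not in excluded_subjects for sid in self.subject_ids])

    def paired(self) -> tuple[np.ndarray, np.ndarray]:
        """Scan-1/scan-2 arrays of subjects with neither scan excluded."""
        keep = self._included()
        return self.ratio_scan1[keep], self.ratio_scan2[keep]

    def pooled(self) -> np.ndarray:
        """All included datapoints of the technique (both repeats)."""
        s1, s2 = self.paired()
        return np.concatenate([s1, s2])


def coefficient_of_reproducibility(data: RepeatedMeasures) -> float:
    """CoR = 1.96 x SD of the per-subject signed scan1-scan2 difference."""
    s1, s2 = data.paired()
    if s1.size < 2:
        raise ValueError("CoR needs at least 2 paired subjects after exclusions")
    return float(1.96 * np.std(s1 - s2, ddof=1))


def coefficient_of_variation(data: RepeatedMeasures) -> float:
    """CoV = pooled both-scan SD over pooled mean."""
    pooled = data.pooled()
    if pooled.size < 2:
        raise ValueError("CoV needs at least 2 datapoints after exclusions")
    mean = pooled.mean()
    if mean <= 0:
        raise ValueError("CoV undefined for non-positive mean ratio")
    return float(np.std(pooled, ddof=1) / mean)
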