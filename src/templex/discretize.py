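"""Three-state discretization of ROI time series.

Continuous per-ROI signals are z-scored (population SD) and reduced to a
point-process-like sequence of activation events: state ``1`` where the
normalized signal exceeds ``+theta``, ``-1`` below ``-theta`` and ``0`` in
between.  ``theta`` is expressed as a fraction of the standard deviation;
the customary sweep is 0.25, 0.5, 0.75 and 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StateSeries", "zscore", "discretize"]

#: thresholds conventionally swept in the analysis
STANDARD_THRESHOLDS = (0.25, 0.5, 0.75, 1.0)


@dataclass
class StateSeries:
    """Per-ROI discrete state sequences in {-1, 0, 1}.

    Attributes
    ----------
    states : ndarray of shape (n_roi, n_time), values in {-1, 0, 1}
    threshold : float
        The fraction of SD used as the event threshold.
    roi_labels : list of str
    """

    states: np.ndarray
    threshold: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not np.isin(self.states, (-1, 0, 1)).all():
            raise ValueError("states must contain only values in {-1, 0, 1}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{i}" for i in range(self.states.shape[0])]
        if len(self.roi_labels) != self.states.shape[0]:
            raise ValueError("roi_labels length does not match state matrix")

    @property
    def n_roi(self) -> int:
        return self.states.shape[0]

    @property
    def n_time(self) -> int:
        return self.states.shape[1]


def zscore(series: np.ndarray, roi_labels: list[str] | None = None) -> np.ndarray:
    """Z-score each ROI row to mean 0, SD 1 (population SD, ``ddof=0``).

    Raises
    ------
    ValueError
        If a row has zero variance; the offending ROI is named.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D ROI x timepoint matrix")
    sd = x.std(axis=1, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        labels = roi_labels or [f"ROI{i}" for i in range(x.shape[0])]
        raise ValueError(
            f"zero-variance time series for {labels[bad[0]]!r}: cannot z-score"
        )
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def discretize(
    z: np.ndarray,
    threshold: float = 1.0,
    roi_labels: list[str] | None = None,
) -> StateSeries:
    """Threshold a normalized matrix into {-1, 0, 1} states.

    ``state = 1`` where ``z > +threshold``, ``-1`` where ``z < -threshold``,
    ``0`` otherwise.  Values exactly at the threshold map to 0 ("between
    thresholds" is read inclusively).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(z, dtype=float)
    states = np.zeros(z.shape, dtype=np.int8)
    states[z > threshold] = 1
    states[z < -threshold] = -1
    return StateSeries(states=states, threshold=float(threshold),
                       roi_labels=list(roi_labels) if roi_labels else [])
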