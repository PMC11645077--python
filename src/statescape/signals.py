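"""ROI time-series handling: extraction, filtering, binarization, state encoding.

The joint activity of ``N`` regions at one time point is summarised as an
*activation state*: each ROI is either active (spin ``+1``) or inactive
(spin ``-1``) relative to its own temporal threshold.  A state is encoded as
an integer in ``[0, 2**N)`` where ROI ``0`` occupies the least significant
bit and an active ROI contributes a ``1`` bit.  With ``N`` ROIs there are
``2**N`` possible states (256 for the canonical eight-ROI analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "StateSequence",
    "StateDistribution",
    "StateBinarizer",
    "extract_roi_timeseries",
    "select_rois",
    "bandpass",
    "binarize",
    "empirical_distribution",
    "encode_states",
    "decode_state",
    "state_to_activation_map",
    "state_label",
]

MAX_ROIS = 20  # 2**20 states is the largest enumerable landscape


def _as_frame(ts) -> pd.DataFrame:
    """Coerce a time-series input (DataFrame or T x N array) to a DataFrame."""
    if isinstance(ts, pd.DataFrame):
        df = ts
    else:
        arr = np.asarray(ts, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"time series must be 2-D (T x N), got shape {arr.shape}")
        df = pd.DataFrame(arr, columns=[f"roi{i + 1}" for i in range(arr.shape[1])])
    if df.isna().any().any():
        raise ValueError("time series contains missing values")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least 2 time points and 2 ROIs")
    return df


# ---------------------------------------------------------------------------
# state encoding


def encode_states(spins: np.ndarray) -> np.ndarray:
    """Encode a T x N spin matrix (entries in {-1, +1}) as state indices.

    ROI ``j`` (column ``j``) maps to bit ``j``; spin ``+1`` sets the bit.
    """
    spins = np.asarray(spins)
    if spins.ndim != 2:
        raise ValueError("spins must be 2-D (T x N)")
    n = spins.shape[1]
    if n > MAX_ROIS:
        raise ValueError(f"N={n} exceeds the enumerable limit of {MAX_ROIS} ROIs")
    if not np.isin(spins, (-1, 1)).all():
        raise ValueError("spins must contain only -1 and +1")
    bits = (spins > 0).astype(np.int64)
    weights = 1 << np.arange(n, dtype=np.int64)
    return bits @ weights


def decode_state(k: int, n_rois: int) -> np.ndarray:
    """Boolean activation vector of state ``k`` (index 0 = ROI 1 = LSB)."""
    k = int(k)
    if not 0 <= k < (1 << n_rois):
        raise ValueError(f"state index {k} out of range for N={n_rois}")
    return ((k >> np.arange(n_rois)) & 1).astype(bool)


def state_to_activation_map(k: int, n_rois: int) -> np.ndarray:
    """Alias of :func:`decode_state`: which ROIs are active in state ``k``."""
    return decode_state(k, n_rois)


def state_label(k: int, n_rois: int) -> str:
    """Concatenated 1-based positions of the active ROIs, e.g. state 6 -> "23".

    The all-inactive state is labelled "-".  Mirrors the convention of
    naming a state by the set of co-active regions.
    """
    active = np.flatnonzero(decode_state(k, n_rois)) + 1
    return "".join(str(i) for i in active) if active.size else "-"


@dataclass
class StateSequence:
    """A binarized multi-ROI recording: T x N spins plus the encoded states."""

    spins: np.ndarray
    roi_names: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self):
        self.spins = np.asarray(self.spins, dtype=np.int8)
        if not self.roi_names:
            self.roi_names = [f"roi{i + 1}" for i in range(self.spins.shape[1])]
        if len(self.roi_names) != self.spins.shape[1]:
            raise ValueError("roi_names length does not match spin columns")
        # validates values and N <= MAX_ROIS
        self.state_index = encode_states(self.spins)

    @property
    def n_rois(self) -> int:
        return self.spins.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.spins.shape[0]


@dataclass
class StateDistribution:
    """Probability vector over all ``2**N`` activation states.

    ``n_observations`` is the sample count behind an empirical distribution
    and 0 for a model distribution.
    """

    probs: np.ndarray
    n_observations: int = 0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or self.probs.size & (self.probs.size - 1):
            raise ValueError("probs length must be a power of two")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probs must be nonnegative and sum to 1 within 1e-12")

    @property
    def n_rois(self) -> int:
        return int(self.probs.size).bit_length() - 1

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "StateDistribution":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("empty count vector")
        probs = counts / total
        probs /= probs.sum()  # forces exact renormalisation
        return cls(probs, n_observations=int(round(total)))


# ---------------------------------------------------------------------------
# operations


def extract_roi_timeseries(image4d, labels, roi_labels=None) -> pd.DataFrame:
    """Mean time series per labelled region of a 4-D volume.

    Parameters
    ----------
    image4d : nibabel image or ndarray, shape (X, Y, Z, T)
    labels : nibabel image or integer ndarray, shape (X, Y, Z)
        Label 0 is background.  ROI order in the output is ascending label.
    roi_labels : sequence of int, optional
        Restrict/refuse: every requested label must occur in the volume.
    """
    data = np.asanyarray(image4d.dataobj) if hasattr(image4d, "dataobj") else np.asarray(image4d)
    lab = np.asanyarray(labels.dataobj) if hasattr(labels, "dataobj") else np.asarray(labels)
    lab = np.rint(lab).astype(np.int64)
    if data.ndim != 4:
        raise ValueError("image must be 4-D (X, Y, Z, T)")
    if lab.shape != data.shape[:3]:
        raise ValueError(f"label grid {lab.shape} does not match image grid {data.shape[:3]}")
    present = np.unique(lab[lab > 0])
    if present.size == 0:
        raise ValueError("label volume contains no nonzero labels")
    if roi_labels is None:
        roi_labels = present
    else:
        roi_labels = np.asarray(sorted(roi_labels))
        missing = np.setdiff1d(roi_labels, present)
        if missing.size:
            raise ValueError(f"labels absent from volume: {missing.tolist()}")
    flat = data.reshape(-1, data.shape[3])
    lab_flat = lab.ravel()
    cols = {f"roi{r}": flat[lab_flat == r].mean(axis=0) for r in roi_labels}
    return pd.DataFrame(cols)


def select_rois(ts, roi_names) -> pd.DataFrame:
    """Restrict and reorder the ROI columns of a time-series table."""
    df = _as_frame(ts)
    names = list(roi_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate ROI names in selection")
    unknown = [n for n in names if n not in df.columns]
    if unknown:
        raise KeyError(f"unknown ROI name(s): {unknown}")
    return df.loc[:, names]


def bandpass(ts, low_hz: float, high_hz: float, tr_seconds: float, order: int = 4) -> pd.DataFrame:
    """Zero-phase Butterworth band-pass of each ROI column.

    The canonical resting-state band is 0.01-0.1 Hz.  ``low_hz = 0`` degrades
    to a pure low-pass.
    """
    df = _as_frame(ts)
    nyq = 0.5 / tr_seconds
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(f"band [{low_hz}, {high_hz}] Hz outside (0, Nyquist={nyq:.4g}) Hz")
    if low_hz > 0:
        sos = _sig.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos")
    else:
        sos = _sig.butter(order, high_hz, btype="lowpass", fs=1.0 / tr_seconds, output="sos")
    out = _sig.sosfiltfilt(sos, df.to_numpy(), axis=0)
    return pd.DataFrame(out, columns=df.columns, index=df.index)


class StateBinarizer(TransformerMixin, BaseEstimator):
    """Threshold each ROI series at its own mean (or median) into spins.

    A transformer in the scikit-learn sense: ``fit`` learns per-ROI
    thresholds, ``transform`` maps a T x N series to a T x N spin matrix with
    entries in {-1, +1} (active above threshold).  Thresholding at the
    temporal mean is the standard choice in the energy-landscape literature;
    the threshold is invariant under per-ROI affine rescaling with positive
    slope, so arbitrary signal units are acceptable.

    Parameters
    ----------
    rule : {"mean", "median"}, default "mean"
    """

    def __init__(self, rule: str = "mean"):
        self.rule = rule

    def fit(self, X, y=None):
        df = _as_frame(X)
        if self.rule not in ("mean", "median"):
            raise ValueError(f"unknown rule {self.rule!r}; use 'mean' or 'median'")
        values = df.to_numpy(dtype=float)
        zero_var = np.flatnonzero(values.std(axis=0) == 0)
        if zero_var.size:
            bad = [df.columns[i] for i in zero_var]
            raise ValueError(f"zero-variance ROI column(s): {bad}")
        agg = np.mean if self.rule == "mean" else np.median
        self.thresholds_ = agg(values, axis=0)
        self.roi_names_ = list(df.columns)
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("StateBinarizer is not fitted")
        values = _as_frame(X).to_numpy(dtype=float)
        if values.shape[1] != self.n_features_in_:
            raise ValueError("column count changed between fit and transform")
        return np.where(values > self.thresholds_, 1, -1).astype(np.int8)


def binarize(ts, rule: str = "mean", subject_id: str = "") -> StateSequence:
    """One-shot binarization of a time-series table into a :class:`StateSequence`."""
    df = _as_frame(ts)
    spins = StateBinarizer(rule=rule).fit(df).transform(df)
    return StateSequence(spins, roi_names=list(df.columns), subject_id=subject_id)


def empirical_distribution(bps: StateSequence) -> StateDistribution:
    """Normalized visit frequency of every activation state in a recording."""
    counts = np.bincount(bps.state_index, minlength=1 << bps.n_rois)
    return StateDistribution.from_counts(counts)
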