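"""Evoked-response preprocessing: trial rejection, averaging, binning, feature matrices.

The decoder and the RSA both consume downsampled evoked responses: the
signal in a 0-800 ms epoch is averaged into 20-ms bins (40 bins with the
defaults), concatenated channel-by-bin into one feature vector per word,
and column z-scored. Binning uses half-open bins [start, start + width);
z-scoring uses the population (1/n) standard deviation and maps constant
columns to zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinnedEpochs",
    "FeatureMatrix",
    "reject_trials",
    "average_repetitions",
    "bin_timecourses",
    "window_features",
    "zscore_columns",
]


@dataclass
class BinnedEpochs:
    """Binned evoked responses: (items, channels, bins) with bin metadata."""

    data: np.ndarray
    bin_width: float  # ms
    window: tuple[float, float]  # ms
    bin_centers: np.ndarray  # ms

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("binned data must be (items, channels, bins)")
        n_bins = int(np.floor((self.window[1] - self.window[0]) / self.bin_width))
        if self.data.shape[2] != n_bins:
            raise ValueError(
                f"expected {n_bins} bins for window {self.window} at "
                f"{self.bin_width} ms, got {self.data.shape[2]}"
            )
        diffs = np.diff(self.bin_centers)
        if np.any(diffs <= 0) or not np.allclose(diffs, self.bin_width):
            raise ValueError("bin_centers must increase in steps of bin_width")

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]


@dataclass
class FeatureMatrix:
    """Items x features matrix with (channel, bin) provenance per column."""

    values: np.ndarray
    feature_index: list[tuple[int, int]]  # (channel, bin) per column
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (items x features)")
        if len(self.feature_index) != self.values.shape[1]:
            raise ValueError("feature_index must have one entry per column")
        if self.standardized:
            n = self.values.shape[0]
            mu = self.values.mean(axis=0)
            sd = self.values.std(axis=0)
            nonconst = sd > 1e-12
            # population-sd scaling gives sd 1; sample-sd (ddof=1) gives sqrt((n-1)/n)
            ok = (np.abs(sd[nonconst] - 1) < 1e-8) | (
                np.abs(sd[nonconst] - np.sqrt((n - 1) / n)) < 1e-8
            )
            if np.any(np.abs(mu) > 1e-8) or not np.all(ok):
                raise ValueError("standardized matrix fails mean-0 / sd-1 check")


def reject_trials(
    trials: np.ndarray, threshold: float
) -> tuple[np.ndarray, int]:
    """Drop trials in which any sample on any channel exceeds ``threshold``.

    ``trials`` is (repetitions, channels, samples); the amplitude criterion
    is on absolute value (the default in the emulated pipeline corresponds
    to 3,000 fT/cm on planar gradiometers). Returns the retained trials and
    the number removed; raises if nothing survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    trials = np.asarray(trials)
    if trials.ndim != 3:
        raise ValueError("trials must be (repetitions, channels, samples)")
    keep = np.abs(trials).max(axis=(1, 2)) <= threshold
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError(f"all {trials.shape[0]} trials exceeded the rejection threshold")
    return trials[keep], n_removed


def average_repetitions(trials: np.ndarray) -> np.ndarray:
    """Pointwise mean over the repetitions of one item."""
    trials = np.asarray(trials)
    if trials.shape[0] < 1:
        raise ValueError("no trials to average")
    return trials.mean(axis=0)


def bin_timecourses(
    evoked: np.ndarray,
    sfreq: float,
    window: tuple[float, float] = (0.0, 800.0),
    bin_width: float = 20.0,
    epoch_start: float = 0.0,
) -> BinnedEpochs:
    """Average samples into fixed-width time bins.

    ``evoked`` is (items, channels, samples) starting at ``epoch_start`` ms
    and sampled at ``sfreq`` Hz. Each bin is the mean of the samples whose
    time falls in the half-open interval [bin_start, bin_start + bin_width);
    with the defaults (0-800 ms, 20-ms bins at 1 kHz) this yields 40 bins
    of 20 samples each.
    """
    evoked = np.asarray(evoked)
    if evoked.ndim != 3:
        raise ValueError("evoked must be (items, channels, samples)")
    start, end = window
    n_samples = evoked.shape[2]
    times = epoch_start + 1000.0 * np.arange(n_samples) / sfreq
    if start < times[0] - 1e-9 or end > times[-1] + 1000.0 / sfreq + 1e-9:
        raise ValueError(
            f"window {window} outside recorded epoch "
            f"[{times[0]:g}, {times[-1] + 1000.0 / sfreq:g}) ms"
        )
    n_bins = int(np.floor((end - start) / bin_width))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    binned = np.empty(evoked.shape[:2] + (n_bins,))
    for b in range(n_bins):
        lo, hi = start + b * bin_width, start + (b + 1) * bin_width
        mask = (times >= lo - 1e-9) & (times < hi - 1e-9)
        if not mask.any():
            raise ValueError(f"bin [{lo:g}, {hi:g}) ms contains no samples")
        binned[:, :, b] = evoked[:, :, mask].mean(axis=2)
    centers = start + bin_width * (np.arange(n_bins) + 0.5)
    return BinnedEpochs(
        data=binned, bin_width=bin_width, window=window, bin_centers=centers
    )


def window_features(
    binned: BinnedEpochs, window_size: int = 5, start_bin: int = 0
) -> FeatureMatrix:
    """Concatenate channels x ``window_size`` consecutive bins into one row per item.

    With 204 channels and a 5-bin window this yields 1,020 features.
    """
    n_items, n_channels, n_bins = binned.data.shape
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if start_bin < 0 or start_bin + window_size > n_bins:
        raise ValueError(
            f"window [{start_bin}, {start_bin + window_size}) overruns {n_bins} bins"
        )
    chunk = binned.data[:, :, start_bin : start_bin + window_size]
    values = chunk.reshape(n_items, n_channels * window_size)
    index = [
        (c, start_bin + b) for c in range(n_channels) for b in range(window_size)
    ]
    return FeatureMatrix(values=values, feature_index=index, standardized=False)


def zscore_columns(
    matrix: FeatureMatrix | np.ndarray, ddof: int = 0
) -> FeatureMatrix:
    """Standardize each column to mean 0, s.d. 1 (population s.d. by default).

    Constant columns become all-zero columns rather than raising: this keeps
    the feature geometry intact without dropping columns. Note the scaling
    statistics come from all items; a fold-safe variant recomputes them
    within training folds (see ``neurosem.zeroshot``).
    """
    if isinstance(matrix, FeatureMatrix):
        values, index = matrix.values, matrix.feature_index
    else:
        values = np.asarray(matrix, dtype=float)
        index = [(0, j) for j in range(values.shape[1])]
    if values.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 rows")
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    out = np.zeros_like(values, dtype=float)
    nonconst = sd > 0
    out[:, nonconst] = (values[:, nonconst] - mu[nonconst]) / sd[nonconst]
    return FeatureMatrix(values=out, feature_index=list(index), standardized=True)
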