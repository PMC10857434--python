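"""Valley-of-the-log-histogram thresholding shared by ploidy and marker gates."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks


class UnimodalError(ValueError):
    """No usable valley between two modes; caller should supply a threshold."""


def log_valley_threshold(
    values: np.ndarray,
    n_hist_bins: int = 64,
    smooth_sigma: float = 1.5,
    min_mode_separation: float = 0.2,
) -> float:
    """Threshold at the histogram valley between the two largest log modes.

    Builds a histogram of ``log(values)``, smooths it with a Gaussian kernel
    (sd ``smooth_sigma`` bins), locates the two tallest local maxima, and
    returns ``exp`` of the minimum between them. The valley must sit at least
    ``min_mode_separation`` log-units from both modes; otherwise the
    distribution is treated as effectively unimodal and
    :class:`UnimodalError` is raised, advising a manual threshold.
    """
    values = np.asarray(values, float)
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("values must be finite and strictly positive")
    logv = np.log(values)
    lo, hi = logv.min(), logv.max()
    if hi - lo < 2 * min_mode_separation:
        raise UnimodalError(
            "value range too narrow for two separated modes; "
            "supply a manual threshold"
        )
    counts, edges = np.histogram(logv, bins=n_hist_bins, range=(lo, hi))
    smooth = gaussian_filter1d(counts.astype(float), smooth_sigma)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks, props = find_peaks(smooth, height=0.0)
    if len(peaks) < 2:
        raise UnimodalError(
            "fewer than two modes found; supply a manual threshold"
        )
    order = np.argsort(props["peak_heights"])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    valley = p1 + int(np.argmin(smooth[p1 : p2 + 1]))
    if (centers[valley] - centers[p1] < min_mode_separation
            or centers[p2] - centers[valley] < min_mode_separation):
        raise UnimodalError(
            "modes are closer than the minimum separation "
            f"({min_mode_separation} log-units); supply a manual threshold"
        )
    return float(np.exp(centers[valley]))
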