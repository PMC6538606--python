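"""Time-frequency decomposition and across-epoch coherence.

The connectivity metric is magnitude coherence estimated across epochs
at every time-frequency point from Morlet-wavelet coefficients:

    Coh(f, t) = |sum_e X_e(f,t) conj(Y_e(f,t))|
                / sqrt(sum_e |X_e|^2 * sum_e |Y_e|^2)

which lies in [0, 1] by Cauchy-Schwarz.  The wavelet front-end is
pluggable: any callable mapping an :class:`~pescar.simulate.EpochSet` to
complex coefficients with the same layout can replace
:func:`wavelet_transform`.

Samples within a configurable number of wavelet standard deviations of
the epoch edges (at the lowest analysis frequency) are flagged invalid
and excluded from downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .simulate import EpochSet

__all__ = [
    "TFDecomposition",
    "CoherenceMap",
    "wavelet_transform",
    "coherence",
    "all_pair_coherence",
    "averaged_roi_coherence",
]


@dataclass
class TFDecomposition:
    """Complex wavelet coefficients for one EpochSet.

    ``coeffs`` has shape (n_subrois, n_epochs, n_freqs, n_times);
    ``valid_times`` flags samples free of epoch-edge contamination.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid_times: np.ndarray
    subject_id: int | None = None
    condition_id: str | None = None


@dataclass
class CoherenceMap:
    """Coherence for every cross-ROI sub-ROI pair, one subject/condition.

    ``coh`` has shape (n_pairs, n_freqs, n_times); ``pair_index[k]`` is
    the (sub-ROI in ROI1, sub-ROI in ROI2) local-index pair of row k.
    """

    subject_id: int
    condition_id: str
    coh: np.ndarray
    pair_index: list[tuple[int, int]]
    freqs: np.ndarray
    times: np.ndarray
    n_degenerate: int = 0


def wavelet_transform(
    epochs: EpochSet, freqs, n_cycles=7.0, decim=1, edge_sigmas=2.0
) -> TFDecomposition:
    """Morlet-wavelet decomposition of every sub-ROI series.

    ``freqs`` must lie below Nyquist; ``n_cycles`` below 3 gives wavelets
    too short for a stable coherence estimate and is rejected.  Time is
    decimated by ``decim`` after the transform.  ``edge_sigmas`` sets the
    edge-exclusion margin in units of the wavelet temporal standard
    deviation sigma_t = n_cycles / (2*pi*f) at the lowest frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    nyquist = epochs.sampling_rate / 2.0
    if np.any(freqs >= nyquist):
        raise ValueError(f"frequencies must be below Nyquist ({nyquist:g} Hz)")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    if n_cycles < 3:
        raise ValueError("n_cycles must be >= 3")
    decim = int(decim)
    # mne expects (n_epochs, n_channels, n_times)
    data = np.transpose(epochs.data, (1, 0, 2))
    n_times = data.shape[-1]
    # the longest wavelet spans ~10 sigma_t at the lowest frequency; pad
    # short epochs with zeros (multiple of decim keeps the grid aligned)
    wav_len = (
        int(np.ceil(10.0 * n_cycles / (2.0 * np.pi * freqs.min()) * epochs.sampling_rate))
        + 1
    )
    pad = 0
    if wav_len > n_times:
        pad = int(np.ceil((wav_len - n_times) / 2 / decim)) * decim
        data = np.pad(data, ((0, 0), (0, 0), (pad, pad)))
    coeffs = tfr_array_morlet(
        data,
        sfreq=epochs.sampling_rate,
        freqs=freqs,
        n_cycles=n_cycles,
        output="complex",
        decim=decim,
        zero_mean=True,
        verbose="error",
    )
    # -> (n_epochs, n_channels, n_freqs, n_times_dec); reorder channel-first
    coeffs = np.transpose(coeffs, (1, 0, 2, 3))
    times = epochs.times[::decim]
    if pad:
        start = pad // decim
        coeffs = coeffs[..., start : start + times.size]
    edge = edge_sigmas * n_cycles / (2.0 * np.pi * freqs.min())
    valid = (times >= epochs.times[0] + edge) & (times <= epochs.times[-1] - edge)
    return TFDecomposition(
        coeffs=coeffs,
        freqs=freqs,
        times=times,
        valid_times=valid,
        subject_id=epochs.subject_id,
        condition_id=epochs.condition_id,
    )


def coherence(x, y, return_n_degenerate=False):
    """Magnitude coherence across epochs at every (f, t).

    ``x`` and ``y`` are complex coefficient arrays (n_epochs, n_freqs,
    n_times).  Points where either auto-spectrum is zero are defined as
    coherence 0 and counted as degenerate.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("coefficient arrays must share shape")
    sxy = np.abs(np.sum(x * np.conj(y), axis=0))
    den = np.sum(np.abs(x) ** 2, axis=0) * np.sum(np.abs(y) ** 2, axis=0)
    degenerate = den <= 0.0
    n_degenerate = int(np.count_nonzero(degenerate))
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(degenerate, 0.0, sxy / np.sqrt(np.where(degenerate, 1.0, den)))
    coh = np.clip(coh, 0.0, 1.0)
    if return_n_degenerate:
        return coh, n_degenerate
    return coh


def _check_consistent(dataset):
    sets = list(dataset)
    ref = sets[0]
    for es in sets[1:]:
        if es.data.shape != ref.data.shape or not np.allclose(es.times, ref.times):
            raise ValueError("all EpochSets must share shapes and time axes")
        if not np.array_equal(es.roi_membership, ref.roi_membership):
            raise ValueError("all EpochSets must share ROI membership")
    return sets


def _pair_coherence_from_tfd(tfd: TFDecomposition, roi1_idx, roi2_idx):
    c = tfd.coeffs[:, :, :, tfd.valid_times]
    c1 = c[roi1_idx]
    c2 = c[roi2_idx]
    # cross- and auto-spectra summed over epochs, all pairs at once
    sxy = np.abs(np.einsum("aeft,beft->abft", c1, np.conj(c2)))
    auto = np.sum(np.abs(c) ** 2, axis=1)
    den = auto[roi1_idx][:, np.newaxis] * auto[roi2_idx][np.newaxis]
    degenerate = den <= 0.0
    n_degenerate = int(np.count_nonzero(degenerate))
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(degenerate, 0.0, sxy / np.sqrt(np.where(degenerate, 1.0, den)))
    coh = np.clip(coh, 0.0, 1.0)
    n1, n2 = len(roi1_idx), len(roi2_idx)
    pairs = [(i, j) for i in range(n1) for j in range(n2)]
    return coh.reshape(n1 * n2, coh.shape[2], coh.shape[3]), pairs, n_degenerate


def all_pair_coherence(dataset, config) -> list[CoherenceMap]:
    """One CoherenceMap per subject x condition over all N x M cross-ROI pairs.

    Within-ROI pairs are excluded.  Deterministic; epoch order does not
    matter because the estimator sums over epochs.
    """
    sets = _check_consistent(dataset)
    maps = []
    for es in sets:
        tfd = wavelet_transform(
            es, config.freqs, config.n_cycles, config.decim, config.edge_sigmas
        )
        roi1_idx, roi2_idx = es.roi_indices
        coh, pairs, n_deg = _pair_coherence_from_tfd(tfd, roi1_idx, roi2_idx)
        maps.append(
            CoherenceMap(
                subject_id=es.subject_id,
                condition_id=es.condition_id,
                coh=coh,
                pair_index=pairs,
                freqs=tfd.freqs,
                times=tfd.times[tfd.valid_times],
                n_degenerate=n_deg,
            )
        )
    return maps


def averaged_roi_coherence(dataset, config) -> list[CoherenceMap]:
    """Conventional-baseline estimator: ROI-mean series, single-pair coherence.

    Sub-ROI series are averaged (unweighted) within each ROI first, then
    coherence is computed between the two mean series.
    """
    sets = _check_consistent(dataset)
    maps = []
    for es in sets:
        roi1_idx, roi2_idx = es.roi_indices
        mean_data = np.stack(
            [es.data[roi1_idx].mean(axis=0), es.data[roi2_idx].mean(axis=0)]
        )
        mean_es = EpochSet(
            subject_id=es.subject_id,
            condition_id=es.condition_id,
            data=mean_data,
            times=es.times,
            roi_membership=np.array([0, 1]),
            sampling_rate=es.sampling_rate,
        )
        tfd = wavelet_transform(
            mean_es, config.freqs, config.n_cycles, config.decim, config.edge_sigmas
        )
        coh, n_deg = coherence(
            tfd.coeffs[0][:, :, tfd.valid_times],
            tfd.coeffs[1][:, :, tfd.valid_times],
            return_n_degenerate=True,
        )
        maps.append(
            CoherenceMap(
                subject_id=es.subject_id,
                condition_id=es.condition_id,
                coh=coh[np.newaxis],
                pair_index=[(0, 0)],
                freqs=tfd.freqs,
                times=tfd.times[tfd.valid_times],
                n_degenerate=n_deg,
            )
        )
    return maps
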