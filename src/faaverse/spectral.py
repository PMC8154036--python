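"""Spectral estimation: from referenced time series to log alpha-band power.

The pipeline is: common-average re-reference, drop the first seconds after
rest onset (eye-closing artifacts), Welch power spectra from 2-s Hann windows
stepped by 0.5 s with windows overlapping any rejected 1-s segment excluded,
then mean power in the 8-13 Hz band, natural-log transformed.

Numerical conventions (the analyses are invariant to all of them, because
they work on log-differences and z-scores): Hann taper, one-sided PSD in
power-per-Hz units, natural logarithm, band edges inclusive.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import get_window

from .datasets import BandPower, RawStudy, SpectralDataset

__all__ = ["apply_average_reference", "crop_rest", "welch_psd", "band_log_power"]


def apply_average_reference(raw: RawStudy) -> RawStudy:
    """Subtract the instantaneous mean across channels from every channel.

    Idempotent; the output channel mean is zero at every sample.
    """
    if raw.data.shape[1] < 2:
        raise ValueError("reference undefined: need >= 2 channels")
    data = raw.data - raw.data.mean(axis=1, keepdims=True)
    return dataclasses.replace(raw, data=data)


def crop_rest(raw: RawStudy, skip_s: int = 2) -> RawStudy:
    """Drop the first ``skip_s`` seconds of data and the matching mask segments.

    ``skip_s`` must be a whole number of seconds so the 1-s bad-segment mask
    stays aligned: output segment k corresponds to input segment k + skip_s.
    """
    if skip_s != int(skip_s) or skip_s < 0:
        raise ValueError("skip_s must be a non-negative integer number of seconds")
    skip_s = int(skip_s)
    if skip_s == 0:
        return raw
    if raw.duration <= skip_s:
        raise ValueError(f"duration {raw.duration:g} s <= skip {skip_s} s")
    n_skip = int(round(skip_s * raw.sfreq))
    return dataclasses.replace(
        raw, data=raw.data[:, :, n_skip:], bad_mask=raw.bad_mask[:, skip_s:]
    )


def _good_window_starts(bad_mask_row: np.ndarray, sfreq: float, n_samples: int,
                        win: int, step: int) -> np.ndarray:
    """Start samples of windows whose span overlaps no rejected 1-s segment."""
    seg_len = int(round(sfreq))
    bad_samples = np.zeros(n_samples, dtype=bool)
    masked_len = min(n_samples, len(bad_mask_row) * seg_len)
    bad_samples[:masked_len] = np.repeat(bad_mask_row, seg_len)[:masked_len]
    csum = np.concatenate([[0], np.cumsum(bad_samples)])
    starts = np.arange(0, n_samples - win + 1, step)
    n_bad_in_window = csum[starts + win] - csum[starts]
    return starts[n_bad_in_window == 0]


def welch_psd(raw: RawStudy, win_s: float = 2.0, step_s: float = 0.5,
              window: str = "hann") -> SpectralDataset:
    """Welch power spectral density with bad-segment-aware window selection.

    Tapered periodograms of ``win_s``-long windows at ``step_s`` stride are
    averaged per subject and channel; any window whose time span overlaps a
    rejected 1-s segment is discarded.  Frequency resolution is 1 / win_s Hz.
    Output is invariant to the sample values inside rejected segments.
    """
    sfreq = raw.sfreq
    win = int(round(win_s * sfreq))
    step = int(round(step_s * sfreq))
    if win < 2 or step < 1 or win > raw.data.shape[2]:
        raise ValueError("window/step incompatible with data length")
    taper = get_window(window, win, fftbins=True)
    scale = 1.0 / (sfreq * (taper ** 2).sum())
    freqs = np.fft.rfftfreq(win, 1.0 / sfreq)

    n_sub, n_ch, n_samp = raw.data.shape
    power = np.empty((n_sub, n_ch, len(freqs)))
    for s in range(n_sub):
        starts = _good_window_starts(raw.bad_mask[s], sfreq, n_samp, win, step)
        if len(starts) == 0:
            sid = raw.meta["subject_id"].iloc[s] if len(raw.meta) > s else s
            raise ValueError(f"no Welch window survives the bad-segment mask "
                             f"for subject {sid}")
        views = np.lib.stride_tricks.sliding_window_view(raw.data[s], win, axis=-1)
        segs = views[:, starts, :] * taper  # (channels, windows, win)
        spec = np.abs(np.fft.rfft(segs, axis=-1)) ** 2 * scale
        spec[..., 1:] *= 2.0  # one-sided
        if win % 2 == 0:
            spec[..., -1] /= 2.0  # Nyquist bin is not doubled
        power[s] = spec.mean(axis=1)
    return SpectralDataset(power=power, freqs=freqs, layout=raw.layout,
                           meta=raw.meta, space="avg", study_id=raw.study_id)


def band_log_power(spec: SpectralDataset,
                   band: tuple[float, float] = (8.0, 13.0)) -> BandPower:
    """Natural log of mean power over frequency bins with low <= f <= high."""
    low, high = band
    sel = (spec.freqs >= low - 1e-9) & (spec.freqs <= high + 1e-9)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band}")
    mean_power = spec.power[:, :, sel].mean(axis=2)
    if (mean_power <= 0).any():
        raise ValueError("zero band power: log undefined")
    return BandPower(values=np.log(mean_power), band=(float(low), float(high)),
                     layout=spec.layout, meta=spec.meta, space=spec.space,
                     study_id=spec.study_id)
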