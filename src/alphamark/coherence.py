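"""Magnitude-squared coherence over the electrode pairs of interest.

Coherence at frequency f between signals x and y is

    C(f) = |S_xy(f)|^2 / (S_xx(f) S_yy(f))

with the cross-spectrum S_xy and autospectra S_xx, S_yy averaged across
the same kept 2-s Hanning-windowed epochs before the ratio is formed
(the Welch estimator; a single segment gives identically 1, so at least
two kept epochs are required). Values lie in [0, 1]: 0 marks no linear
coupling, 1 perfect coupling. No bias correction is applied — the finite-
epoch bias floor (about 1/L for L epochs of independent noise) is
characterized empirically in the test suite instead.

Summaries follow the three pair sets used for hemispheric coupling
analyses: left and right intrahemispheric (fronto-temporal F3-T3/F4-T4,
temporo-parietal T3-P3/T4-P4, fronto-parietal F3-P3/F4-P4) and
interhemispheric (F3-F4, T3-T4, P3-P4).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.signal

from .errors import EmptyInputError, MontageError
from .montage import PAIR_SETS, pair_name
from .preprocess import EpochSet
from .spectral import GRID_HI, GRID_LO, BandScheme, PowerSpectrum, _TOL


def _epoch_ffts(es: EpochSet, idx: int) -> np.ndarray:
    """Hanning-windowed rFFT of every kept epoch of one channel."""
    x = es.kept()[:, idx, :]
    x = x - x.mean(axis=1, keepdims=True)
    window = scipy.signal.get_window("hann", x.shape[1])
    return np.fft.rfft(x * window, axis=1)


def ms_coherence(es: EpochSet, pair: tuple[str, str]) -> PowerSpectrum:
    """Per-bin magnitude-squared coherence for one electrode pair.

    Returns a single-"channel" :class:`~alphamark.spectral.PowerSpectrum`
    on the 2-45 Hz grid whose power row holds the coherence values.
    """
    if es.n_kept < 2:
        raise EmptyInputError(
            f"coherence needs >= 2 kept epochs, got {es.n_kept}")
    try:
        ia = es.channel_labels.index(pair[0])
        ib = es.channel_labels.index(pair[1])
    except ValueError as exc:
        raise MontageError(f"pair {pair} not in montage") from exc
    fx = _epoch_ffts(es, ia)
    fy = _epoch_ffts(es, ib)
    sxy = (fx * np.conj(fy)).mean(axis=0)
    sxx = (fx * np.conj(fx)).real.mean(axis=0)
    syy = (fy * np.conj(fy)).real.mean(axis=0)
    den = sxx * syy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(den > 0, np.abs(sxy) ** 2 / den, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    freqs = np.fft.rfftfreq(es.epochs.shape[2], d=1.0 / es.sampling_rate)
    mask = (freqs >= GRID_LO - _TOL) & (freqs <= GRID_HI + _TOL)
    return PowerSpectrum(
        freqs=freqs[mask],
        power=coh[mask],
        epochs_used=es.n_kept,
        channel_labels=[pair_name(pair)],
    )


def band_coherence(coh_bins: PowerSpectrum, scheme: BandScheme) -> dict[str, float]:
    """Mean per-band coherence (same bin-membership rule as band powers)."""
    from .errors import BandError

    out: dict[str, float] = {}
    values = coh_bins.power[0]
    for name in scheme.bands:
        mask = scheme.bin_mask(name, coh_bins.freqs)
        if not mask.any():
            lo, hi = scheme.bands[name]
            raise BandError(f"band {name} [{lo}, {hi}) contains no grid bins")
        out[name] = float(values[mask].mean())
    return out


def coherence_profile(es: EpochSet, scheme: BandScheme) -> pd.DataFrame:
    """Coherence for all nine pairs of interest, per band.

    Returns a long-format table with columns ``pair_set``, ``pair``,
    ``band``, ``coherence``, ``epochs_used`` (9 pairs x 8 bands rows).
    """
    for pairs in PAIR_SETS.values():
        for a, b in pairs:
            if a not in es.channel_labels or b not in es.channel_labels:
                raise MontageError(f"channel {a if a not in es.channel_labels else b}"
                                   " missing from montage")
    rows = []
    for set_name, pairs in PAIR_SETS.items():
        for pair in pairs:
            coh = ms_coherence(es, pair)
            per_band = band_coherence(coh, scheme)
            for band, value in per_band.items():
                rows.append({
                    "pair_set": set_name,
                    "pair": pair_name(pair),
                    "band": band,
                    "coherence": value,
                    "epochs_used": coh.epochs_used,
                })
    return pd.DataFrame(rows)
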