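"""Welch spectra, individual anchor frequencies, and individualized bands.

The analysis follows the individually anchored band framework for resting
EEG: a Welch power spectrum (Hanning-windowed 2-s epochs, 0.5 Hz
resolution, 2-45 Hz) is averaged across electrodes; two anchor frequencies
are located on it —

* **IAF** (individual alpha frequency): the frequency of maximum power in
  the extended alpha range 5-14 Hz;
* **TF** (theta/alpha transition frequency): the frequency of minimum
  power between the theta and alpha bumps, i.e. where the two spectra
  intersect;

and the per-subject band scheme is anchored on them: delta [TF-4, TF-2),
theta [TF-2, TF), alpha1 [TF, mid), alpha2 [mid, IAF), alpha3 [IAF, IAF+2)
with mid the midpoint of the TF-IAF range. Relative power is each bin's
power over the channel's mean power across 2-45 Hz; a band's relative
power is the mean relative power of the bins it contains, and the
alpha3/alpha2 ratio of those band powers is the biomarker of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .errors import AnchorError, BandError, EmptyInputError
from .preprocess import EpochSet

#: Canonical band order.
BAND_NAMES = (
    "delta", "theta", "alpha1", "alpha2", "alpha3", "beta1", "beta2", "gamma",
)

GRID_LO = 2.0
GRID_HI = 45.0
_TOL = 1e-9


@dataclass
class PowerSpectrum:
    """Per-channel power density on the analysis grid.

    ``power`` is ``(n_channels, n_bins)`` in uV^2/Hz (or dimensionless for
    relative spectra); ``freqs`` is the bin grid in Hz.
    """

    freqs: np.ndarray
    power: np.ndarray
    epochs_used: int
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.power.shape[1] != self.freqs.size:
            raise ValueError("power and freqs bin counts differ")

    @property
    def df(self) -> float:
        """Grid spacing in Hz."""
        return float(self.freqs[1] - self.freqs[0])

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]


def welch_psd(es: EpochSet) -> PowerSpectrum:
    """Welch power spectral density from the kept epochs.

    Each kept epoch is Hanning-windowed and periodogram-transformed
    (density scaling, per-epoch mean removal); the per-channel PSD is the
    unweighted average over kept epochs, restricted to the 2-45 Hz grid.
    The native resolution is 1/epoch_length (0.5 Hz for 2-s epochs).
    """
    kept = es.kept()
    if kept.shape[0] == 0:
        raise EmptyInputError("no kept epochs")
    freqs, per_epoch = scipy.signal.periodogram(
        kept,
        fs=es.sampling_rate,
        window="hann",
        detrend="constant",
        scaling="density",
        axis=2,
    )
    psd = per_epoch.mean(axis=0)  # (channel, bin)
    mask = (freqs >= GRID_LO - _TOL) & (freqs <= GRID_HI + _TOL)
    return PowerSpectrum(
        freqs=freqs[mask],
        power=psd[:, mask],
        epochs_used=int(kept.shape[0]),
        channel_labels=list(es.channel_labels),
    )


def grand_average_spectrum(ps: PowerSpectrum) -> PowerSpectrum:
    """Unweighted mean over channels, as a single-channel spectrum."""
    if ps.n_channels < 1:
        raise EmptyInputError("no channels to average")
    return PowerSpectrum(
        freqs=ps.freqs,
        power=ps.power.mean(axis=0, keepdims=True),
        epochs_used=ps.epochs_used,
        channel_labels=["grand-average"],
    )


def _as_single_channel(ps: PowerSpectrum) -> np.ndarray:
    if ps.n_channels != 1:
        ps = grand_average_spectrum(ps)
    return ps.power[0]


def detect_iaf(avg_spectrum: PowerSpectrum, lo: float = 5.0, hi: float = 14.0) -> float:
    """Individual alpha frequency: argmax power in the extended alpha range.

    The search interval is closed, ``[lo, hi]``; ties break toward the
    lower frequency (np.argmax's first-occurrence rule, documented
    behavior).
    """
    power = _as_single_channel(avg_spectrum)
    mask = (avg_spectrum.freqs >= lo - _TOL) & (avg_spectrum.freqs <= hi + _TOL)
    if not mask.any():
        raise AnchorError(f"grid does not cover [{lo}, {hi}] Hz")
    window = power[mask]
    if np.all(window <= 0):
        raise AnchorError("spectrum is zero throughout the alpha search range")
    return float(avg_spectrum.freqs[mask][int(np.argmax(window))])


def detect_tf(avg_spectrum: PowerSpectrum, iaf: float, search_lo: float = 3.0) -> float:
    """Theta/alpha transition frequency: argmin power in ``[search_lo, iaf)``.

    Ties break toward the higher frequency (the bin closest to the alpha
    rise); a monotone spectrum therefore returns the window edge nearest
    the alpha peak only if it is a strict minimum, otherwise ``search_lo``.
    """
    if search_lo >= iaf:
        raise AnchorError(f"search window [{search_lo}, {iaf}) is empty")
    power = _as_single_channel(avg_spectrum)
    mask = (avg_spectrum.freqs >= search_lo - _TOL) & (avg_spectrum.freqs < iaf - _TOL)
    if not mask.any():
        raise AnchorError(f"no grid bins in [{search_lo}, {iaf})")
    window = power[mask]
    freqs = avg_spectrum.freqs[mask]
    # argmin with ties toward the higher frequency
    reverse_idx = window.size - 1 - int(np.argmin(window[::-1]))
    return float(freqs[reverse_idx])


@dataclass(frozen=True)
class AnchorFrequencies:
    """The two subject-specific anchors (Hz)."""

    tf: float
    iaf: float

    def __post_init__(self) -> None:
        if not (self.tf < self.iaf):
            raise AnchorError(f"TF ({self.tf}) must be below IAF ({self.iaf})")
        if not (5.0 - _TOL <= self.iaf <= 14.0 + _TOL):
            raise AnchorError(f"IAF {self.iaf} outside the 5-14 Hz range")


@dataclass(frozen=True)
class BandScheme:
    """Named frequency intervals, each ``[lo, hi)``; gamma is closed at 45 Hz."""

    bands: dict[str, tuple[float, float]]

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]

    def bin_mask(self, name: str, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of grid bins belonging to band ``name``.

        Membership is the half-open interval ``lo <= f < hi``, evaluated on
        the exact real-valued boundaries (no rounding, so a midpoint off
        the grid never double-counts a bin). The top band additionally
        includes its closing edge so the grid's last bin is not orphaned.
        """
        lo, hi = self.bands[name]
        mask = (freqs >= lo - _TOL) & (freqs < hi - _TOL)
        if name == list(self.bands)[-1]:
            mask |= np.isclose(freqs, hi, atol=_TOL)
        return mask


def build_band_scheme(
    anchors: AnchorFrequencies,
    b1_hi: float = 19.2,
    b2_hi: float = 32.4,
    gamma_hi: float = GRID_HI,
) -> BandScheme:
    """Construct the individualized band scheme from the anchors.

    delta [TF-4, TF-2), theta [TF-2, TF), alpha1 [TF, mid), alpha2
    [mid, IAF), alpha3 [IAF, IAF+2) with mid = (TF+IAF)/2, then beta1
    [IAF+2, b1_hi), beta2 [b1_hi, b2_hi), gamma [b2_hi, gamma_hi]. The
    beta/gamma internal edges default to the fixed values 19.2 and 32.4 Hz
    and are configurable. A delta lower edge below the 2 Hz grid floor is
    clipped with a warning.
    """
    tf, iaf = anchors.tf, anchors.iaf
    delta_lo = tf - 4.0
    if delta_lo < GRID_LO - _TOL:
        warnings.warn(
            f"delta lower edge TF-4 = {delta_lo:.2f} Hz below the 2 Hz grid; "
            "clipping to 2 Hz",
            stacklevel=2,
        )
        delta_lo = GRID_LO
    mid = (tf + iaf) / 2.0
    if not (iaf + 2.0 <= b1_hi <= b2_hi <= gamma_hi):
        raise BandError(
            f"beta/gamma edges must satisfy IAF+2 <= {b1_hi} <= {b2_hi} <= {gamma_hi}"
        )
    bands = {
        "delta": (delta_lo, tf - 2.0),
        "theta": (tf - 2.0, tf),
        "alpha1": (tf, mid),
        "alpha2": (mid, iaf),
        "alpha3": (iaf, iaf + 2.0),
        "beta1": (iaf + 2.0, b1_hi),
        "beta2": (b1_hi, b2_hi),
        "gamma": (b2_hi, gamma_hi),
    }
    return BandScheme(bands=bands)


def relative_power(ps: PowerSpectrum) -> PowerSpectrum:
    """Normalize each channel by its mean power over the 2-45 Hz grid.

    The relative spectrum's mean over the grid is exactly 1 per channel,
    so relative band powers are scale-invariant.
    """
    mean = ps.power.mean(axis=1, keepdims=True)
    if np.any(mean <= 0):
        bad = [ps.channel_labels[i] if ps.channel_labels else str(i)
               for i in np.nonzero(mean[:, 0] <= 0)[0]]
        raise BandError(f"zero-power channel(s): {bad}")
    return PowerSpectrum(
        freqs=ps.freqs,
        power=ps.power / mean,
        epochs_used=ps.epochs_used,
        channel_labels=list(ps.channel_labels),
    )


@dataclass
class BandPowerRecord:
    """Per-subject relative band powers, ratios, and anchors."""

    subject_id: str
    rel_power: dict[str, float]
    alpha3_alpha2: float
    theta_gamma: float
    anchors: AnchorFrequencies


def band_powers(
    rel_spectrum: PowerSpectrum,
    scheme: BandScheme,
    subject_id: str = "",
    anchors: AnchorFrequencies | None = None,
) -> BandPowerRecord:
    """Mean relative power per band, plus the alpha3/alpha2 and
    theta/gamma ratios.

    Multi-channel input is averaged across channels (every channel shares
    the grid, so channel-then-bin averaging equals bin-then-channel).
    """
    power = rel_spectrum.power.mean(axis=0)
    out: dict[str, float] = {}
    for name in scheme.bands:
        mask = scheme.bin_mask(name, rel_spectrum.freqs)
        if not mask.any():
            lo, hi = scheme.bands[name]
            raise BandError(f"band {name} [{lo}, {hi}) contains no grid bins")
        out[name] = float(power[mask].mean())
    if anchors is None:
        tf_guess = scheme.bands["theta"][1]
        iaf_guess = scheme.bands["alpha3"][0]
        anchors = AnchorFrequencies(tf=tf_guess, iaf=iaf_guess)
    return BandPowerRecord(
        subject_id=subject_id,
        rel_power=out,
        alpha3_alpha2=out["alpha3"] / out["alpha2"] if out["alpha2"] > 0 else np.inf,
        theta_gamma=out["theta"] / out["gamma"] if out["gamma"] > 0 else np.inf,
        anchors=anchors,
    )
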