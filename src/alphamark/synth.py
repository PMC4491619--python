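"""Synthetic resting-state EEG with recoverable spectral ground truth.

The generator emulates eyes-closed resting EEG as a sum of narrow-band
stochastic oscillators over a 1/f^beta background:

* a **theta** oscillator band-passed over [TF-2, TF];
* a **low-alpha** oscillator over [TF, IAF] (sets the alpha1/alpha2 skirt
  and makes the theta/alpha trough land near the intended TF);
* a **high-alpha** oscillator over [IAF, IAF+2];
* a narrow **alpha-peak** oscillator centered on the IAF (width 1 Hz) so
  the electrode-averaged spectrum has a unique, recoverable peak;
* 1/f^beta background noise produced by spectral shaping of white noise.

Each oscillator is white noise passed through a Butterworth band-pass and
scaled *analytically* (via the filter's frequency response) to a requested
RMS amplitude, so the expected one-sided PSD of every component is known
in closed form. That analytic spectrum is the generator's ground truth:
the realized transition frequency is defined as the argmin of the analytic
spectrum between 3 Hz and the IAF (TF is a property of the spectrum, not a
free dial), and cohort amplitude targets are solved against the analytic
alpha3/alpha2 band-power ratio.

Pairwise coupling is injected as a shared band-limited source ``s`` added
to one channel in full and to the other scaled by a mixing coefficient in
[0, 1], so measured magnitude-squared coherence rises monotonically with
the mixing coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict, replace
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.signal
import yaml

from .errors import AlphamarkError, GenerationError, InvalidSpecError
from .montage import MONTAGE_10_20
from .preprocess import Recording

FS_DEFAULT = 250.0

#: Table-1-style cohort defaults: group sizes, target alpha3/alpha2 ranges,
#: and per-group covariate distributions (mean, sd, lo, hi) / female counts.
DEFAULT_GROUP_SIZES = {"low": 18, "middle": 38, "high": 18}
DEFAULT_RATIO_TARGETS = {
    "low": (0.77, 0.98),
    "middle": (1.00, 1.16),
    "high": (1.17, 1.52),
}
DEFAULT_COVARIATES = {
    "low": {"age": (70.4, 7.4, 57, 80), "education": (8.3, 4.7, 3, 18),
            "mmse": (26.9, 1.2, 23, 30), "female_frac": 14 / 18},
    "middle": {"age": (68.4, 8.2, 52, 83), "education": (7.6, 3.7, 3, 17),
               "mmse": (27.4, 1.3, 24, 30), "female_frac": 24 / 38},
    "high": {"age": (70.4, 6.7, 60, 85), "education": (6.6, 3.6, 4, 18),
             "mmse": (27.0, 1.7, 23, 29), "female_frac": 13 / 18},
}
GROUP_ORDER = ("low", "middle", "high")


# ---------------------------------------------------------------------------
# specs

@dataclass
class SubjectSpec:
    """Ground-truth parameters for one synthetic subject.

    Amplitudes are oscillator RMS values in uV; ``noise_exponent`` is the
    1/f^beta slope of the background and ``noise_scale`` its RMS in uV.
    ``coupling`` lists ``((label_a, label_b), mix)`` entries: a shared
    band-limited source (RMS ``coupling_amp``, centered on
    ``coupling_center`` Hz) is added to ``label_a`` in full and to
    ``label_b`` scaled by ``mix``.
    """

    iaf_true: float = 10.9
    tf_true: float = 6.9
    alpha2_amp: float = 4.0
    alpha3_amp: float = 4.0
    theta_amp: float = 2.0
    peak_amp: float = 3.0
    noise_exponent: float = 1.5
    noise_scale: float = 12.0
    coupling: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    coupling_amp: float = 3.0
    coupling_center: float = 5.9
    coupling_bw: float = 2.0
    duration: float = 300.0
    sampling_rate: float = FS_DEFAULT
    seed: int = 0
    subject_id: str = "S000"

    def __post_init__(self) -> None:
        if not (5.0 <= self.iaf_true <= 14.0):
            raise InvalidSpecError(f"iaf_true {self.iaf_true} outside [5, 14] Hz")
        if not (self.tf_true < self.iaf_true):
            raise InvalidSpecError("tf_true must be below iaf_true")
        for name in ("alpha2_amp", "alpha3_amp", "theta_amp", "peak_amp",
                     "noise_scale", "coupling_amp"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        if self.duration <= 0:
            raise InvalidSpecError("duration must be positive")
        for (a, b), mix in self.coupling:
            if not (0.0 <= mix <= 1.0):
                raise InvalidSpecError(f"mixing coefficient {mix} outside [0, 1]")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["coupling"] = [[list(pair), mix] for pair, mix in self.coupling]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SubjectSpec":
        d = yaml.safe_load(text)
        d["coupling"] = [((p[0][0], p[0][1]), float(p[1]))
                         for p in d.get("coupling", [])]
        return cls(**d)


@dataclass
class CohortSpec:
    """A whole cohort: group sizes, target ratio ranges, covariates."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    ratio_targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATIO_TARGETS))
    covariates: dict[str, dict] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_COVARIATES.items()})
    duration: float = 300.0
    coupling: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    master_seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise InvalidSpecError(f"group {g} size must be >= 1")
        ordered = [self.ratio_targets[g] for g in GROUP_ORDER
                   if g in self.ratio_targets]
        for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
            if not (lo1 < hi1 <= lo2 < hi2):
                raise InvalidSpecError(
                    "ratio_targets must be ordered, non-overlapping "
                    "low < middle < high")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["ratio_targets"] = {g: list(v) for g, v in self.ratio_targets.items()}
        d["coupling"] = [[list(pair), mix] for pair, mix in self.coupling]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        d = yaml.safe_load(text)
        d["ratio_targets"] = {g: tuple(v) for g, v in d["ratio_targets"].items()}
        d["coupling"] = [((p[0][0], p[0][1]), float(p[1]))
                         for p in d.get("coupling", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# component filters and their analytic spectra

@lru_cache(maxsize=4096)
def _bandpass_sos(lo: float, hi: float, fs: float, order: int = 4):
    lo = max(lo, 0.1)
    return scipy.signal.butter(order, [lo, hi], btype="bandpass",
                               fs=fs, output="sos")


def _filter_gain_sq(sos, freqs: np.ndarray, fs: float) -> np.ndarray:
    _, h = scipy.signal.sosfreqz(sos, worN=2.0 * np.pi * freqs / fs)
    return np.abs(h) ** 2


_FINE_N = 8192


@lru_cache(maxsize=512)
def _bp_norm(lo: float, hi: float, fs: float, order: int = 4) -> float:
    """``integral_0^{fs/2} |H(f)|^2 df`` for the band-pass (cached)."""
    sos = _bandpass_sos(lo, hi, fs, order)
    fine = np.linspace(0.0, fs / 2.0, _FINE_N)
    return float(np.trapezoid(_filter_gain_sq(sos, fine, fs), fine))


def _component_density(sos, fs: float, lo: float | None = None,
                       hi: float | None = None):
    """One-sided PSD shape of unit-RMS filtered white noise.

    Returns a callable ``psd(freqs)`` normalized so the density integrates
    to 1 over [0, fs/2]. When the band edges are given the normalization
    integral is looked up from the cache.
    """
    if lo is not None and hi is not None:
        norm = _bp_norm(lo, hi, fs)
    else:
        fine = np.linspace(0.0, fs / 2.0, _FINE_N)
        norm = np.trapezoid(_filter_gain_sq(sos, fine, fs), fine)
    return lambda freqs: _filter_gain_sq(sos, np.asarray(freqs, float), fs) / norm


def _noise_shape(freqs: np.ndarray, beta: float, f0: float = 0.5) -> np.ndarray:
    """Amplitude-squared shape of the 1/f^beta background (clipped below f0)."""
    f = np.maximum(np.asarray(freqs, dtype=float), f0)
    return f ** (-beta)


@lru_cache(maxsize=64)
def _noise_norm(fs: float, beta: float) -> float:
    fine = np.linspace(0.0, fs / 2.0, _FINE_N)
    return float(np.trapezoid(_noise_shape(fine, beta), fine))


def _noise_density(fs: float, beta: float):
    norm = _noise_norm(fs, beta)
    return lambda freqs: _noise_shape(np.asarray(freqs, float), beta) / norm


def _oscillator(rng: np.random.Generator, n: int, lo: float, hi: float,
                fs: float, rms: float) -> np.ndarray:
    """Unit-variance white noise band-passed and analytically scaled to
    the requested RMS (deterministic scale; no per-realization fitting)."""
    if rms == 0.0:
        return np.zeros(n)
    sos = _bandpass_sos(lo, hi, fs)
    # var(out) = (2/fs) * integral_0^{fs/2} |H|^2 df  for unit-variance input
    var = (2.0 / fs) * _bp_norm(max(lo, 0.1), hi, fs)
    white = rng.standard_normal(n)
    return rms / np.sqrt(var) * scipy.signal.sosfilt(sos, white)


def _pink(rng: np.random.Generator, n: int, fs: float, beta: float,
          rms: float) -> np.ndarray:
    """1/f^beta noise via spectral shaping, analytically scaled to RMS."""
    if rms == 0.0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.sqrt(_noise_shape(freqs, beta))
    spec = np.fft.rfft(rng.standard_normal(n)) * amp
    x = np.fft.irfft(spec, n=n)
    # expected variance of the shaped series for unit white input
    w = np.ones_like(freqs)
    if n % 2 == 0:
        w[-1] = 0.5  # Nyquist bin counted once
    w[0] = 0.5
    exp_var = 2.0 * np.sum(w * amp**2) / n
    return rms / np.sqrt(exp_var) * x


def _component_bands(spec: SubjectSpec) -> dict[str, tuple[float, float, float]]:
    """(lo, hi, rms) of each oscillator component for a subject spec."""
    tf, iaf = spec.tf_true, spec.iaf_true
    # The theta oscillator occupies the lower half of the theta band and
    # the low-alpha oscillator starts half a bin above TF, so the spectrum
    # keeps a clear background-floored notch between theta activity and
    # the alpha rise (real eyes-closed spectra decline into that trough).
    return {
        "theta": (tf - 2.0, tf - 1.0, spec.theta_amp),
        "low_alpha": (tf + 0.5, iaf, spec.alpha2_amp),
        "high_alpha": (iaf, iaf + 2.0, spec.alpha3_amp),
        "peak": (iaf - 0.5, iaf + 0.5, spec.peak_amp),
    }


def analytic_spectrum(spec: SubjectSpec, freqs: np.ndarray,
                      montage_average: bool = False) -> np.ndarray:
    """Expected one-sided PSD (uV^2/Hz) of the subject's signal.

    With ``montage_average=False`` this is the spectrum of one uncoupled
    channel; with ``montage_average=True`` the expected electrode-averaged
    spectrum, which additionally carries each coupling source's power
    spread over the full montage (the quantity the anchor detectors see).
    """
    freqs = np.asarray(freqs, dtype=float)
    total = np.zeros_like(freqs)
    fs = spec.sampling_rate
    for lo, hi, rms in _component_bands(spec).values():
        if rms > 0:
            dens = _component_density(_bandpass_sos(lo, hi, fs), fs,
                                       lo=max(lo, 0.1), hi=hi)
            total = total + rms**2 * dens(freqs)
    if spec.noise_scale > 0:
        total = total + spec.noise_scale**2 * _noise_density(
            fs, spec.noise_exponent)(freqs)
    if montage_average and spec.coupling and spec.coupling_amp > 0:
        lo = max(spec.coupling_center - spec.coupling_bw / 2, 0.1)
        hi = spec.coupling_center + spec.coupling_bw / 2
        dens = _component_density(_bandpass_sos(lo, hi, fs), fs, lo=lo, hi=hi)
        weight = sum(1.0 + mix**2 for _, mix in spec.coupling)
        total = total + (weight / len(MONTAGE_10_20)) * (
            spec.coupling_amp**2) * dens(freqs)
    return total


def analysis_grid(fs: float = FS_DEFAULT, epoch_length: float = 2.0) -> np.ndarray:
    """The downstream 2-45 Hz analysis grid (0.5 Hz for 2-s epochs)."""
    df = 1.0 / epoch_length
    all_f = np.arange(0.0, fs / 2.0 + df / 2, df)
    return all_f[(all_f >= 2.0 - 1e-9) & (all_f <= 45.0 + 1e-9)]


def analytic_anchors(spec: SubjectSpec) -> tuple[float, float]:
    """Ground-truth (tf, iaf) read off the analytic spectrum on the grid.

    IAF truth is the grid argmax in [5, 14]; TF truth is the grid argmin
    in [3, IAF), ties toward the higher frequency — the same rules the
    detectors apply, evaluated on the noise-free expected spectrum.
    """
    freqs = analysis_grid(spec.sampling_rate)
    psd = analytic_spectrum(spec, freqs, montage_average=True)
    alpha = (freqs >= 5.0) & (freqs <= 14.0)
    iaf = float(freqs[alpha][int(np.argmax(psd[alpha]))])
    win = (freqs >= 3.0) & (freqs < iaf - 1e-9)
    w = psd[win]
    idx = w.size - 1 - int(np.argmin(w[::-1]))
    tf = float(freqs[win][idx])
    return tf, iaf


def analytic_ratio(spec: SubjectSpec) -> float:
    """Expected alpha3/alpha2 band-power ratio from the analytic spectrum.

    Band edges are anchored on the analytic anchors; the relative-power
    normalizer cancels in the ratio, so absolute densities are used.
    """
    from .spectral import AnchorFrequencies, build_band_scheme

    freqs = analysis_grid(spec.sampling_rate)
    psd = analytic_spectrum(spec, freqs, montage_average=True)
    tf, iaf = analytic_anchors(spec)
    scheme = build_band_scheme(AnchorFrequencies(tf=tf, iaf=iaf))
    a2 = psd[scheme.bin_mask("alpha2", freqs)].mean()
    a3 = psd[scheme.bin_mask("alpha3", freqs)].mean()
    return float(a3 / a2)


# ---------------------------------------------------------------------------
# generators

def generate_subject(spec: SubjectSpec) -> Recording:
    """Generate one 19-channel recording from a subject spec.

    Every channel receives independent oscillator and background
    realizations (scaled by a per-channel gain in [0.9, 1.1], which leaves
    all relative powers and ratios unchanged); coupling entries add a
    shared source across the named channel pair. Deterministic given
    ``spec.seed``.
    """
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    if n < 1:
        raise InvalidSpecError("duration too short for one sample")
    rng = np.random.default_rng(spec.seed)
    labels = list(MONTAGE_10_20)
    gains = rng.uniform(0.9, 1.1, size=len(labels))
    components = _component_bands(spec)
    data = np.zeros((len(labels), n))
    for ci in range(len(labels)):
        ch = np.zeros(n)
        for lo, hi, rms in components.values():
            if rms > 0:
                ch += _oscillator(rng, n, lo, hi, fs, rms)
        ch += _pink(rng, n, fs, spec.noise_exponent, spec.noise_scale)
        data[ci] = gains[ci] * ch
    # shared sources for coupled pairs
    for (lab_a, lab_b), mix in spec.coupling:
        if spec.coupling_amp == 0.0:
            continue
        source = _oscillator(
            rng, n, spec.coupling_center - spec.coupling_bw / 2,
            spec.coupling_center + spec.coupling_bw / 2, fs, spec.coupling_amp)
        ia, ib = labels.index(lab_a), labels.index(lab_b)
        data[ia] += source
        data[ib] += mix * source
    return Recording(
        channel_labels=labels,
        sampling_rate=fs,
        samples=data,
        reference="linked-mastoid",
        subject_id=spec.subject_id,
    )


def generate_coupled_pair(
    common_amp: float,
    mix: float,
    noise_amp: float,
    duration: float = 60.0,
    seed: int = 0,
    center: float = 10.0,
    bw: float = 2.0,
    fs: float = FS_DEFAULT,
) -> Recording:
    """Two channels sharing a band-limited source: ``x = s + n1``,
    ``y = mix*s + n2`` with independent white noises of RMS ``noise_amp``.

    Expected magnitude-squared coherence at the source frequencies is
    ``mix^2 Ps^2 / ((Ps+Pn)(mix^2 Ps + Pn))`` — increasing in ``mix`` and
    in the source-to-noise ratio (see :func:`analytic_pair_coherence`).
    """
    if not (0.0 <= mix <= 1.0):
        raise InvalidSpecError(f"mix {mix} outside [0, 1]")
    if common_amp < 0 or noise_amp < 0 or duration <= 0:
        raise InvalidSpecError("amplitudes must be >= 0 and duration > 0")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    s = (_oscillator(rng, n, center - bw / 2, center + bw / 2, fs, common_amp)
         if common_amp else np.zeros(n))
    n1 = noise_amp * rng.standard_normal(n) if noise_amp else np.zeros(n)
    n2 = noise_amp * rng.standard_normal(n) if noise_amp else np.zeros(n)
    data = np.vstack([s + n1, mix * s + n2])
    return Recording(channel_labels=["X1", "X2"], sampling_rate=fs,
                     samples=data, reference="other", subject_id="pair")


def analytic_pair_coherence(
    common_amp: float, mix: float, noise_amp: float, freqs: np.ndarray,
    center: float = 10.0, bw: float = 2.0, fs: float = FS_DEFAULT,
) -> np.ndarray:
    """Closed-form magnitude-squared coherence of the coupled-pair model."""
    freqs = np.asarray(freqs, dtype=float)
    sos = _bandpass_sos(center - bw / 2, center + bw / 2, fs)
    ps = common_amp**2 * _component_density(
        sos, fs, lo=max(center - bw / 2, 0.1), hi=center + bw / 2)(freqs)
    pn = np.full_like(freqs, noise_amp**2 * 2.0 / fs)  # white one-sided density
    num = mix**2 * ps**2
    den = (ps + pn) * (mix**2 * ps + pn)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(den > 0, num / den, 1.0 if mix > 0 else 0.0)
    return coh


def inject_burst(
    rec: Recording, start: float, length: float = 0.5, amplitude: float = 500.0,
    channel: str | None = None,
) -> Recording:
    """Add a high-amplitude square burst (uV) to exercise artifact rejection.

    Applied to one channel (default: the first) from ``start`` seconds for
    ``length`` seconds; returns a new Recording.
    """
    data = rec.samples.copy()
    i0 = int(round(start * rec.sampling_rate))
    i1 = min(i0 + int(round(length * rec.sampling_rate)), rec.n_samples)
    idx = rec.channel_labels.index(channel) if channel else 0
    data[idx, i0:i1] += amplitude
    return replace(rec, samples=data)


# ---------------------------------------------------------------------------
# cohort generation

def _measured_ratio(rec: Recording) -> float:
    """The default measurement pipeline's alpha3/alpha2 ratio for one
    recording (common average -> 2-s epochs -> rejection -> Welch ->
    grand average -> anchors -> bands -> relative band powers)."""
    from .preprocess import common_average_reference, reject_artifacts, segment_epochs
    from .spectral import (
        AnchorFrequencies, band_powers, build_band_scheme, detect_iaf,
        detect_tf, grand_average_spectrum, relative_power, welch_psd,
    )

    es = reject_artifacts(segment_epochs(common_average_reference(rec)))
    ps = welch_psd(es)
    avg = grand_average_spectrum(ps)
    iaf = detect_iaf(avg)
    tf = detect_tf(avg, iaf)
    scheme = build_band_scheme(AnchorFrequencies(tf=tf, iaf=iaf))
    rec_bp = band_powers(relative_power(ps), scheme)
    return rec_bp.alpha3_alpha2


def _solve_ratio_amps(base: SubjectSpec, target: float) -> tuple[float, float]:
    """Solve the alpha amplitudes so the analytic ratio hits ``target``.

    A single knob ``t`` scales the high-alpha oscillator up and the
    low-alpha oscillator down (``a3 = a3_0 * t``, ``a2 = a2_0 / t``).
    Extreme ``t`` can drag the analytic anchors away from the intended
    alpha peak (a strong low-alpha plateau can out-power the peak
    oscillator), so candidates are scanned over a bounded grid, kept only
    while their analytic anchors stay within one bin of the intended IAF
    and 1.5 Hz of the intended TF, and the root is bracketed between
    adjacent valid candidates. Returns ``(alpha2_amp, alpha3_amp)``.
    """
    from scipy.optimize import brentq

    a2_0, a3_0 = base.alpha2_amp, base.alpha3_amp

    def candidate(t: float) -> SubjectSpec:
        return replace(base, alpha2_amp=a2_0 / t, alpha3_amp=a3_0 * t)

    def valid(spec: SubjectSpec) -> bool:
        tf_a, iaf_a = analytic_anchors(spec)
        return (abs(iaf_a - spec.iaf_true) <= 0.55
                and abs(tf_a - spec.tf_true) <= 1.55)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        grid_t = np.geomspace(0.3, 3.5, 25)
        ratios = []
        valids = []
        for t in grid_t:
            cand = candidate(float(t))
            valids.append(valid(cand))
            ratios.append(analytic_ratio(cand))
        for i in range(len(grid_t) - 1):
            if not (valids[i] and valids[i + 1]):
                continue
            lo_r, hi_r = ratios[i], ratios[i + 1]
            if (lo_r - target) * (hi_r - target) <= 0:
                t = float(brentq(
                    lambda tt: analytic_ratio(candidate(tt)) - target,
                    float(grid_t[i]), float(grid_t[i + 1]), xtol=1e-4))
                return a2_0 / t, a3_0 * t
    raise GenerationError(
        f"target ratio {target:.3f} not reachable with stable anchors "
        f"(scanned ratios {min(ratios):.2f}..{max(ratios):.2f})")


def _draw_covariates(rng: np.random.Generator, dist: dict) -> dict:
    out = {}
    for name in ("age", "education", "mmse"):
        mean, sd, lo, hi = dist[name]
        out[name] = float(np.clip(np.round(rng.normal(mean, sd)), lo, hi))
    out["sex"] = "F" if rng.random() < dist["female_frac"] else "M"
    return out


def generate_cohort(spec: CohortSpec) -> tuple[list[Recording], pd.DataFrame]:
    """Generate a cohort whose realized alpha3/alpha2 ratios fall inside
    each group's target range.

    For each subject a target ratio is drawn from the inner 80% of the
    group's range, the high-alpha amplitude is solved against the analytic
    spectrum, and the realized ratio is verified with the default
    measurement pipeline; subjects falling outside the range are redrawn
    (up to 8 attempts, deterministic from ``master_seed``) before a
    :class:`GenerationError` naming the group is raised.

    Returns the recordings and a truth table (subject, group, iaf_true,
    tf_true, realized ratio, covariates).
    """
    recordings: list[Recording] = []
    rows: list[dict] = []
    subj_idx = 0
    for group in GROUP_ORDER:
        if group not in spec.group_sizes:
            continue
        lo, hi = spec.ratio_targets[group]
        margin = 0.1 * (hi - lo)
        cov_dist = spec.covariates[group]
        for _ in range(spec.group_sizes[group]):
            sid = f"S{subj_idx:03d}"
            accepted = None
            for attempt in range(8):
                rng = np.random.default_rng(
                    [spec.master_seed, subj_idx, attempt])
                target = rng.uniform(lo + margin, hi - margin)
                iaf = float(np.clip(rng.normal(10.9, 0.8), 9.0, 12.5))
                tf = float(np.clip(iaf - 4.0 + rng.normal(0.0, 0.3),
                                   6.0, iaf - 2.5))
                base = SubjectSpec(
                    iaf_true=iaf, tf_true=tf,
                    duration=spec.duration,
                    coupling=list(spec.coupling),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    subject_id=sid,
                )
                try:
                    a2, a3 = _solve_ratio_amps(base, target)
                except GenerationError:
                    continue  # anchors unstable for this draw; redraw
                subj_spec = replace(base, alpha2_amp=a2, alpha3_amp=a3)
                rec = generate_subject(subj_spec)
                try:
                    realized = _measured_ratio(rec)
                except AlphamarkError:
                    continue  # degenerate measured spectrum; redraw
                if lo <= realized <= hi:
                    accepted = (subj_spec, rec, realized, rng)
                    break
            if accepted is None:
                raise GenerationError(
                    f"could not realize a ratio in [{lo}, {hi}] for group "
                    f"{group!r} (subject {sid})")
            subj_spec, rec, realized, rng = accepted
            tf_real, iaf_real = analytic_anchors(subj_spec)
            row = {
                "subject": sid,
                "group": group,
                "iaf_true": iaf_real,
                "tf_true": tf_real,
                "ratio_true": realized,
                **_draw_covariates(rng, cov_dist),
            }
            rows.append(row)
            recordings.append(rec)
            subj_idx += 1
    truth = pd.DataFrame(rows)
    return recordings, truth


def write_cohort(recordings: list[Recording], truth: pd.DataFrame,
                 out_dir) -> None:
    """Write one EDF per subject plus the truth table CSV."""
    from pathlib import Path

    from .io import write_edf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_edf(rec, out / f"{rec.subject_id}.edf")
    truth.to_csv(out / "truth.csv", index=False)
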