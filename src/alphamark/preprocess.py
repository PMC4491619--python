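"""Recording containers, re-referencing, epoching, and artifact rejection.

The preprocessing chain mirrors standard clinical resting-state practice:
re-reference the multichannel signal to the common average, cut it into
consecutive non-overlapping fixed-length epochs, and drop epochs whose
amplitude or sample-to-sample gradient exceeds configurable thresholds
(an automated, reproducible stand-in for expert visual rejection).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyInputError, FormatError
from .montage import is_eog


@dataclass
class Recording:
    """One subject's multichannel EEG.

    Parameters
    ----------
    channel_labels
        Ordered channel names (10-20 names where applicable).
    sampling_rate
        Sampling frequency in Hz.
    samples
        ``(n_channels, n_samples)`` array in microvolts.
    reference
        Referencing tag: ``"linked-mastoid"``, ``"common-average"``, or
        ``"other"``.
    """

    channel_labels: list[str]
    sampling_rate: float
    samples: np.ndarray
    reference: str = "other"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise FormatError("samples must be a channel x time matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise FormatError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} signal rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise FormatError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        from .errors import MontageError

        try:
            idx = self.channel_labels.index(label)
        except ValueError as exc:
            raise MontageError(f"channel {label!r} not in montage") from exc
        return self.samples[idx]


@dataclass
class EpochSet:
    """A recording segmented into fixed-length epochs with a keep mask."""

    epochs: np.ndarray          # (n_epochs, n_channels, n_times), uV
    epoch_length: float         # seconds
    keep_mask: np.ndarray       # bool, (n_epochs,)
    channel_labels: list[str] = field(default_factory=list)
    sampling_rate: float = 0.0

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        if self.epochs.ndim != 3:
            raise FormatError("epochs must be (epoch, channel, time)")
        if self.keep_mask.shape != (self.epochs.shape[0],):
            raise FormatError("keep_mask length must equal the epoch count")
        expected = int(round(self.epoch_length * self.sampling_rate))
        if self.sampling_rate and self.epochs.shape[2] != expected:
            raise FormatError(
                f"epoch sample count {self.epochs.shape[2]} != "
                f"epoch_length * rate = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())

    def kept(self) -> np.ndarray:
        """The kept epochs, ``(n_kept, n_channels, n_times)``."""
        return self.epochs[self.keep_mask]


def common_average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average.

    Each scalp channel has the instantaneous mean across all scalp channels
    subtracted. EOG channels, if present, are excluded from the average and
    left untouched. Idempotent: the channel mean of the output is zero at
    every sample, so applying it twice is a no-op.
    """
    if rec.n_channels < 2:
        raise FormatError("common average reference needs >= 2 channels")
    scalp = np.array([not is_eog(lb) for lb in rec.channel_labels])
    out = rec.samples.copy()
    mean = out[scalp].mean(axis=0, keepdims=True)
    out[scalp] = out[scalp] - mean
    return replace(rec, samples=out, reference="common-average")


def segment_epochs(rec: Recording, epoch_length: float = 2.0) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    The trailing partial epoch is discarded; every epoch starts kept.
    """
    n_per = int(round(epoch_length * rec.sampling_rate))
    n_epochs = rec.n_samples // n_per
    if n_epochs < 1:
        raise EmptyInputError(
            f"recording of {rec.duration:.2f}s shorter than one "
            f"{epoch_length}s epoch"
        )
    trimmed = rec.samples[:, : n_epochs * n_per]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs.copy(),
        epoch_length=epoch_length,
        keep_mask=np.ones(n_epochs, dtype=bool),
        channel_labels=list(rec.channel_labels),
        sampling_rate=rec.sampling_rate,
    )


def reject_artifacts(
    es: EpochSet, amp_limit: float = 100.0, grad_limit: float = 50.0
) -> EpochSet:
    """Flag artifactual epochs by amplitude and gradient thresholds.

    An epoch is rejected when any channel exceeds ``|x| > amp_limit`` (uV)
    or any sample-to-sample step exceeds ``grad_limit`` (uV/sample).
    Rejection only ever clears keep flags (monotone in the thresholds);
    epoch data are not modified.
    """
    if amp_limit <= 0 or grad_limit <= 0:
        raise ValueError("rejection limits must be positive")
    amp_bad = np.abs(es.epochs).max(axis=(1, 2)) > amp_limit
    grad_bad = np.abs(np.diff(es.epochs, axis=2)).max(axis=(1, 2)) > grad_limit
    keep = es.keep_mask & ~(amp_bad | grad_bad)
    return EpochSet(
        epochs=es.epochs,
        epoch_length=es.epoch_length,
        keep_mask=keep,
        channel_labels=list(es.channel_labels),
        sampling_rate=es.sampling_rate,
    )
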