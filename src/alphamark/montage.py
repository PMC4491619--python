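"""The 19-channel 10-20 montage and the electrode pairs of interest.

Channel order follows the conventional left-to-right, front-to-back listing
of the 10-20 system used for clinical resting-state recordings.
"""

from __future__ import annotations

MONTAGE_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# Canonical capitalisation lookup for label normalisation (EDF files often
# carry labels like "EEG FP1-REF" or lower case variants).
_CANONICAL = {name.upper(): name for name in MONTAGE_10_20}


def normalize_label(raw: str) -> str:
    """Map a raw channel label onto its 10-20 name where recognizable.

    Strips common "EEG " prefixes and "-REF"/"-LE" reference suffixes and
    fixes capitalisation; labels that are not 10-20 names are returned
    stripped but otherwise untouched.
    """
    label = raw.strip()
    upper = label.upper()
    if upper.startswith("EEG "):
        upper = upper[4:].strip()
        label = label[4:].strip()
    for suffix in ("-REF", "-LE", "-AVG"):
        if upper.endswith(suffix):
            upper = upper[: -len(suffix)]
            label = label[: -len(suffix)]
    return _CANONICAL.get(upper, label)


def is_eog(label: str) -> bool:
    """True for electrooculogram channels (excluded from all analyses)."""
    return "EOG" in label.upper()


#: Intra- and interhemispheric electrode pairs of interest.
PAIR_SETS: dict[str, tuple[tuple[str, str], ...]] = {
    "left_intra": (("F3", "T3"), ("T3", "P3"), ("F3", "P3")),
    "right_intra": (("F4", "T4"), ("T4", "P4"), ("F4", "P4")),
    "inter": (("F3", "F4"), ("T3", "T4"), ("P3", "P4")),
}


def pair_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"
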