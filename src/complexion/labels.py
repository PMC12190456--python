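"""The five TCM complexion categories and their ordinal codes.

Diagnostic practice divides pathological facial complexion into dark, red,
pallid, sallow and normal; the pipelines number them 1-5 in that order and
the stacking meta-features are exactly these codes.  Cyan, the sixth
classical category, is not part of the taxonomy here.
"""

from __future__ import annotations

from enum import Enum


class ComplexionLabel(Enum):
    DARK = "dark"
    RED = "red"
    PALLID = "pallid"
    SALLOW = "sallow"
    NORMAL = "normal"

    @property
    def code(self) -> int:
        return _CODES[self]

    @classmethod
    def from_name(cls, name: str) -> "ComplexionLabel":
        try:
            return cls(name.strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(f"unknown complexion label {name!r}; valid labels: {valid}") from None

    @classmethod
    def from_code(cls, code: int) -> "ComplexionLabel":
        for member, c in _CODES.items():
            if c == int(code):
                return member
        raise ValueError(f"unknown complexion code {code!r}; valid codes: 1-5")


_CODES = {
    ComplexionLabel.DARK: 1,
    ComplexionLabel.RED: 2,
    ComplexionLabel.PALLID: 3,
    ComplexionLabel.SALLOW: 4,
    ComplexionLabel.NORMAL: 5,
}

LABELS: tuple[ComplexionLabel, ...] = tuple(_CODES)
N_CLASSES = len(LABELS)


def encode_label(name: str) -> int:
    """Map a label name (case-insensitive) to its ordinal code 1-5."""
    return ComplexionLabel.from_name(name).code


def decode_label(code: int) -> str:
    """Inverse of :func:`encode_label`."""
    return ComplexionLabel.from_code(code).value
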