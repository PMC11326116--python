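"""Media composition: amino-acid fractions, glucose, and the mannose switch.

Amino-acid levels are expressed as fractions of defined reference molarities
("100%"): Leu 762 µM, Trp 245 µM, Ura 178 µM, His 95.4 µM.  Free mannose
saturates bacterial type-I fimbriae so bacteria can no longer adhere to
yeast-wall mannoproteins: the mannose flag deterministically disables clump
formation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import InvalidParameterError, UnknownNutrientError

#: 100% molarities (µM) of the defined media amino acids.
REFERENCE_UM = {"Leu": 762.0, "Trp": 245.0, "Ura": 178.0, "His": 95.4}

_ALIASES = {"L": "Leu", "W": "Trp", "U": "Ura", "H": "His",
            "Leu": "Leu", "Trp": "Trp", "Ura": "Ura", "His": "His"}


def canonical_nutrient(aa: str) -> str:
    try:
        return _ALIASES[aa]
    except KeyError:
        raise UnknownNutrientError(f"unknown nutrient id {aa!r}") from None


@dataclass(frozen=True)
class MediaConfig:
    """Fresh-media recipe for one experimental condition."""

    f_L: float = 1.0
    f_W: float = 1.0
    f_U: float = 1.0
    f_H: float = 1.0
    glucose_gL: float = 20.0  # 2% glucose
    mannose: bool = False

    def __post_init__(self):
        for name in ("f_L", "f_W", "f_U", "f_H"):
            v = getattr(self, name)
            if not 0.0 <= v <= 10.0:
                raise InvalidParameterError(f"{name}={v} outside [0, 10]")
        if self.glucose_gL < 0:
            raise InvalidParameterError("glucose_gL must be >= 0")

    @property
    def fractions(self) -> dict:
        return {"Leu": self.f_L, "Trp": self.f_W, "Ura": self.f_U, "His": self.f_H}

    def with_mannose(self, mannose: bool = True) -> "MediaConfig":
        return replace(self, mannose=mannose)


def concentration(media: MediaConfig, aa: str) -> float:
    """Concentration (µM) of amino acid ``aa`` in fresh media.

    ``aa`` accepts either single-letter (L/W/U/H) or three-letter ids.
    """
    name = canonical_nutrient(aa)
    return media.fractions[name] * REFERENCE_UM[name]
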