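"""Strain genotypes for the coculture system.

The system couples an *E. coli* donor with an *S. cerevisiae* recipient.
Crossfeeder variants are auxotrophic for one amino acid the partner
overproduces (bacteria: Leu-, Trp++; yeast: Trp-, Leu++), which lets media
composition tune steady-state population ratios.  Donors mobilize a plasmid
either in cis (the T4SS plasmid itself carries oriT and yeast markers) or in
trans (a second oriT plasmid is transferred); transconjugants can never
re-donate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import InvalidParameterError

AMINO_ACIDS = ("Leu", "Trp", "Ura", "His")
SPECIES = ("bacterium", "yeast")
DONOR_MODES = ("cis", "trans", "none")
PAYLOADS = ("none", "rescue_markers", "crispr_cutter", "crispr_no_oriT")


@dataclass(frozen=True)
class StrainGenotype:
    """Auxotrophies, overproductions and conjugative role of one population.

    ``payload`` describes what the mobilized plasmid does to recipients:
    ``rescue_markers`` carries URA3/HIS3 so transconjugants drop those
    requirements; ``crispr_cutter`` destroys the recipient's episomal URA3 so
    transconjugants *gain* a uracil requirement; ``crispr_no_oriT`` is the
    transfer-dead negative control (conjugation rate is exactly zero).
    """

    species: str
    auxotrophies: frozenset = field(default_factory=frozenset)
    overproduces: frozenset = field(default_factory=frozenset)
    donor_mode: str = "none"
    payload: str = "none"
    name: str = ""

    def __post_init__(self):
        if self.species not in SPECIES:
            raise InvalidParameterError(f"unknown species {self.species!r}")
        if self.donor_mode not in DONOR_MODES:
            raise InvalidParameterError(f"unknown donor_mode {self.donor_mode!r}")
        if self.payload not in PAYLOADS:
            raise InvalidParameterError(f"unknown payload {self.payload!r}")
        object.__setattr__(self, "auxotrophies", frozenset(self.auxotrophies))
        object.__setattr__(self, "overproduces", frozenset(self.overproduces))
        bad = self.auxotrophies - set(AMINO_ACIDS)
        if bad:
            raise InvalidParameterError(f"unknown auxotrophies {sorted(bad)}")
        if not self.overproduces <= {"Leu", "Trp"}:
            raise InvalidParameterError("overproduction limited to Leu/Trp")
        if self.species == "yeast" and self.donor_mode != "none":
            raise InvalidParameterError("a yeast can never be a conjugative donor")

    @property
    def can_donate(self) -> bool:
        """True when this strain contributes a nonzero conjugative flux."""
        return self.donor_mode != "none" and self.payload != "crispr_no_oriT"


def derive_transconjugant(recipient: StrainGenotype, donor: StrainGenotype) -> StrainGenotype:
    """Genotype of the transconjugant: recipient kinetics, marker changes only.

    ``rescue_markers`` grants Ura/His prototrophy; ``crispr_cutter`` cuts the
    recipient's URA3-bearing plasmid, adding a uracil requirement.
    """
    aux = set(recipient.auxotrophies)
    if donor.payload == "rescue_markers":
        aux -= {"Ura", "His"}
    elif donor.payload == "crispr_cutter":
        aux |= {"Ura"}
    return replace(
        recipient,
        auxotrophies=frozenset(aux),
        donor_mode="none",
        payload="none",
        name=(recipient.name + "_T") if recipient.name else "T",
    )


# Strain presets used throughout the study conditions.
E_WT = StrainGenotype("bacterium", donor_mode="cis", name="E")
E_CROSS = StrainGenotype(
    "bacterium", auxotrophies={"Leu"}, overproduces={"Trp"}, donor_mode="cis",
    name="E_cross",
)
S_WT = StrainGenotype("yeast", name="S")
S_CROSS = StrainGenotype(
    "yeast", auxotrophies={"Trp"}, overproduces={"Leu"}, name="S_cross",
)

PAIRING_PRESETS = {
    "Ecross-Scross": (E_CROSS, S_CROSS),
    "Ecross-S": (E_CROSS, S_WT),
    "E-Scross": (E_WT, S_CROSS),
    "E-S": (E_WT, S_WT),
}
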