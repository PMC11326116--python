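"""Kinetic parameters of the coculture model and their packed numeric layout.

Units are per 200 µL well: cell counts are cells/well, amino acids are
well-average µM, glucose is g/L, rates are per hour.  All defaults are listed
with their rationale in the methods note; the two transfer terms default to
the fitted-band values gamma = 2e-5 (free collisions) and gamma_c = 3e-4
(clumped collisions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import InvalidParameterError
from .genotypes import StrainGenotype, derive_transconjugant
from .media import MediaConfig

#: nutrient order used everywhere in packed arrays: 4 amino acids + glucose.
NUTRIENTS = ("Leu", "Trp", "Ura", "His", "Glc")

COLLISION_MODES = ("per_total_cell", "mass_action_density")

# ---------------------------------------------------------------------------
# packed parameter-vector layout (shared with the compiled kernel)
# ---------------------------------------------------------------------------
PP_MU = 0            # mu_B, mu_Y, mu_T
PP_DEATH = 3         # d_B, d_Y, d_T
PP_K = 6             # K[pop, nutrient] -> 6 + pop*5 + nutrient (3x5)
PP_U = 21            # u[pop, nutrient] -> 21 + pop*5 + nutrient (3x5)
PP_REQ = 36          # required-nutrient mask, same layout (3x5)
PP_SEC_L_Y = 51      # leucine secretion per recipient-yeast cell (µM/h)
PP_SEC_L_T = 52      # leucine secretion per transconjugant cell (µM/h)
PP_SEC_W_B = 53      # tryptophan secretion per donor-bacterium cell (µM/h)
PP_P = 54            # proximity multiplier
PP_TAU = 55          # clump-local residence time (h)
PP_KA = 56           # clump association rate (1/(cell·h)); 0 under mannose
PP_KD = 57           # clump dissociation rate (1/h)
PP_GAMMA = 58        # free transfer term (per collision per h)
PP_GAMMA_C = 59      # clumped transfer term
PP_MODE = 60         # 0 = per_total_cell, 1 = mass_action_density
PP_VOL = 61          # well volume (µL)
PP_LEN = 62

# state-vector layout
SV_BF, SV_BC, SV_YF, SV_YC, SV_TF, SV_TC = range(6)
SV_N0 = 6            # nutrients y[6:11] in NUTRIENTS order
SV_CUM = 11          # cumulative conjugation events (never diluted)
SV_LEN = 12


@dataclass(frozen=True)
class PopulationKinetics:
    """Growth/death/uptake constants for one population.

    ``u_aa`` is the amino-acid requisition per new cell (µM·well/cell),
    applied only to that population's required amino acids; ``u_glc`` is the
    glucose requisition per new cell (g/L per cell, well-average).
    """

    mu: float                      # max specific growth rate (1/h)
    death: float = 0.01            # first-order death rate (1/h)
    K_aa: float = 5.0              # Monod half-saturation for amino acids (µM)
    K_glc: float = 0.2             # Monod half-saturation for glucose (g/L)
    u_aa: float = 1e-5             # amino-acid consumption per new cell (µM/cell)
    u_glc: float = 2e-8            # glucose consumption per new cell (g/L/cell)

    def __post_init__(self):
        for name in ("mu", "death", "u_aa", "u_glc"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("K_aa", "K_glc"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")


#: default kinetics; see docs/methods.md for the derivation of each number.
DEFAULT_BACTERIUM = PopulationKinetics(mu=0.40, death=0.01, K_aa=5.0, K_glc=0.2,
                                       u_aa=1e-5, u_glc=2e-8)
DEFAULT_YEAST = PopulationKinetics(mu=0.30, death=0.01, K_aa=5.0, K_glc=0.2,
                                   u_aa=3.5e-6, u_glc=6e-7)


@dataclass(frozen=True)
class ModelParams:
    """All kinetic constants of the clumped conjugation model."""

    bacterium: PopulationKinetics = DEFAULT_BACTERIUM
    yeast: PopulationKinetics = DEFAULT_YEAST
    transconjugant: Optional[PopulationKinetics] = None  # defaults to yeast

    sigma_L: float = 2e-7        # leucine secreted per overproducer yeast (µM/h/cell)
    sigma_L_basal: float = 5e-9  # basal leucine secretion per WT yeast
    sigma_W: float = 5e-8        # tryptophan secreted per overproducer bacterium
    tau_loc: float = 1.0         # clump-local residence time (h)
    P: float = 1.0               # proximity multiplier (dimensionless)

    k_a: float = 1e-7            # clump association (1/(cell·h))
    k_d: float = 0.05            # clump dissociation (1/h)

    gamma: float = 2e-5          # free transfer term (per collision per h)
    gamma_c: float = 3e-4        # clumped transfer term
    collision_norm: str = "per_total_cell"
    volume_uL: float = 200.0

    def __post_init__(self):
        if self.collision_norm not in COLLISION_MODES:
            raise InvalidParameterError(
                f"collision_norm must be one of {COLLISION_MODES}")
        for name in ("sigma_L", "sigma_L_basal", "sigma_W", "tau_loc", "P",
                     "k_a", "k_d", "gamma", "gamma_c"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.volume_uL <= 0:
            raise InvalidParameterError("volume_uL must be > 0")

    def evolve(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def required_mask(genotype: StrainGenotype) -> np.ndarray:
    """0/1 mask over NUTRIENTS: the auxotrophies plus glucose (always)."""
    m = np.zeros(len(NUTRIENTS))
    for i, n in enumerate(NUTRIENTS[:4]):
        if n in genotype.auxotrophies:
            m[i] = 1.0
    m[4] = 1.0
    return m


def pack_params(params: ModelParams, donor: StrainGenotype,
                recipient: StrainGenotype, media: MediaConfig) -> np.ndarray:
    """Flatten params + genotypes + media into the kernel's parameter vector."""
    if donor.species != "bacterium" or recipient.species != "yeast":
        raise InvalidParameterError(
            "expected a bacterial donor and a yeast recipient")
    trans = derive_transconjugant(recipient, donor)
    kin = {
        0: params.bacterium,
        1: params.yeast,
        2: params.transconjugant or params.yeast,
    }
    geno = {0: donor, 1: recipient, 2: trans}
    pp = np.zeros(PP_LEN)
    for p in range(3):
        k = kin[p]
        pp[PP_MU + p] = k.mu
        pp[PP_DEATH + p] = k.death
        req = required_mask(geno[p])
        pp[PP_REQ + 5 * p: PP_REQ + 5 * p + 5] = req
        for a in range(5):
            pp[PP_K + 5 * p + a] = k.K_glc if a == 4 else k.K_aa
            # consumption only of required nutrients (prototrophs synthesize)
            if req[a]:
                pp[PP_U + 5 * p + a] = k.u_glc if a == 4 else k.u_aa
    pp[PP_SEC_L_Y] = params.sigma_L if "Leu" in recipient.overproduces else params.sigma_L_basal
    pp[PP_SEC_L_T] = params.sigma_L if "Leu" in trans.overproduces else params.sigma_L_basal
    pp[PP_SEC_W_B] = params.sigma_W if "Trp" in donor.overproduces else 0.0
    pp[PP_P] = params.P
    pp[PP_TAU] = params.tau_loc
    pp[PP_KA] = 0.0 if media.mannose else params.k_a
    pp[PP_KD] = params.k_d
    pp[PP_GAMMA] = params.gamma if donor.can_donate else 0.0
    pp[PP_GAMMA_C] = params.gamma_c if donor.can_donate else 0.0
    pp[PP_MODE] = float(COLLISION_MODES.index(params.collision_norm))
    pp[PP_VOL] = params.volume_uL
    return pp
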