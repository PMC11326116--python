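"""Synthetic data with the statistical structure the analysis assumes.

Generates every input the pipeline consumes without any external download:
plate-reader-like fluorescence traces on a 15-minute grid, flow-cytometry-
like daily counts, Poisson CFU platings with the lawn/detection conventions,
and two-channel colony image pairs with tunable colocalization.  Noise
models are stand-ins (lognormal multiplicative fluorescence noise, Poisson
counts); they emulate instrument variability, not any measured calibration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .genotypes import PAIRING_PRESETS, StrainGenotype
from .media import MediaConfig
from .model import BatchProtocol, Trajectory, initial_state, run_batch_protocol
from .params import ModelParams
from .quantify import CFU_LAWN_VALUE, adjust_cfu

#: per-cell fluorescence yields (arbitrary units per cell) per channel
DEFAULT_YIELDS = {"mCherry": 1e-3, "ymCitrine": 5e-3, "yeBFP": 5e-3}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise stand-in for fluorimeter and plating readouts."""

    cv: float = 0.05                      # lognormal CV on fluorescence
    yields: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_YIELDS))
    count_sampling: str = "poisson"       # {"poisson", "none"}
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise InvalidParameterError("cv must be >= 0")
        if self.count_sampling not in ("poisson", "none"):
            raise InvalidParameterError("count_sampling must be poisson|none")


@dataclass(frozen=True)
class ColonySpec:
    """Recipe for one synthetic two-channel colony image pair."""

    shape: Tuple[int, int] = (256, 256)
    pattern: str = "gaussian_blobs"       # {"gaussian_blobs", "sectors"}
    rho: float = 0.0                      # colocalization in [-1, 1]
    intensity_scale: float = 1000.0
    n_features: int = 25
    seed: int = 0

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0:
            raise InvalidParameterError("rho must be in [-1, 1]")
        if self.pattern not in ("gaussian_blobs", "sectors"):
            raise InvalidParameterError(f"unknown pattern {self.pattern!r}")


# ---------------------------------------------------------------------------
# plate traces and CFU platings
# ---------------------------------------------------------------------------

def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=n)


def simulate_plate_traces(trajectory: Trajectory, noise: NoiseModel,
                          well: str = "A1", culture_type: str = "coculture",
                          rng: Optional[np.random.Generator] = None
                          ) -> pd.DataFrame:
    """Fluorescence readings: per-cell yield x species total x lognormal noise.

    Channels follow the reporter assignment of the study system: mCherry
    tracks bacteria, ymCitrine all yeast (recipients and transconjugants),
    yeBFP transconjugants only.
    """
    rng = rng or np.random.default_rng(noise.seed)
    t = trajectory.times
    species_signal = {
        "mCherry": trajectory.states[:, 0] + trajectory.states[:, 1],
        "ymCitrine": trajectory.states[:, 2:6].sum(axis=1),
        "yeBFP": trajectory.states[:, 4] + trajectory.states[:, 5],
    }
    frames = []
    for channel, signal in species_signal.items():
        y = noise.yields.get(channel, 0.0)
        frames.append(pd.DataFrame({
            "well": well, "t_h": t, "channel": channel,
            "value": y * signal * _lognormal_factor(rng, noise.cv, len(t)),
            "culture_type": culture_type}))
    return pd.concat(frames, ignore_index=True)


def simulate_cfu_plating(t_totals: Sequence[float], noise: NoiseModel,
                         plating_volume_uL: float = 100.0,
                         well_volume_uL: float = 200.0,
                         rng: Optional[np.random.Generator] = None
                         ) -> pd.DataFrame:
    """Daily selective-plate CFU from transconjugant well totals.

    The plated 100 µL of a 200 µL well carries half the cells on average;
    counts are Poisson-sampled when enabled, lawn-capped at 500, and flagged
    via the CFU conventions.
    """
    rng = rng or np.random.default_rng(noise.seed)
    expected = np.asarray(t_totals, dtype=float) * plating_volume_uL / well_volume_uL
    if (expected < 0).any():
        raise InvalidParameterError("transconjugant totals must be >= 0")
    if noise.count_sampling == "poisson":
        # clip the Poisson mean: anything this dense is a lawn anyway
        sampled = rng.poisson(np.minimum(expected, 1e6)).astype(float)
    else:
        sampled = np.round(expected)
    raw = ["lawn" if s >= CFU_LAWN_VALUE else s for s in sampled]
    out = adjust_cfu(raw)
    out.insert(0, "day", np.arange(1, len(out) + 1))
    out["expected"] = expected
    return out


def simulate_flow_counts(trajectory: Trajectory, noise: NoiseModel,
                         rng: Optional[np.random.Generator] = None
                         ) -> pd.DataFrame:
    """Flow-cytometry-like daily counts per species (cells/well)."""
    rng = rng or np.random.default_rng(noise.seed)
    rows = []
    for s in trajectory.daily:
        for species, total in (("bacteria", s.B_total),
                               ("yeast", s.Y_total + s.T_total),
                               ("transconjugant", s.T_total)):
            if noise.count_sampling == "poisson" and total < 1e7:
                count = float(rng.poisson(total))
            else:  # Poisson noise is negligible at this density
                count = float(np.round(total))
            rows.append({"day": s.day, "species": species, "count": count})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# colony image pairs
# ---------------------------------------------------------------------------

def _pattern(spec: ColonySpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros((h, w))
    if spec.pattern == "gaussian_blobs":
        for _ in range(spec.n_features):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            s = rng.uniform(min(h, w) / 40, min(h, w) / 10)
            a = rng.uniform(0.3, 1.0)
            img += a * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)))
    else:  # angular sectors radiating from the colony center
        theta = np.arctan2(yy - h / 2, xx - w / 2)
        edges = np.sort(rng.uniform(-np.pi, np.pi, spec.n_features))
        levels = rng.uniform(0.1, 1.0, spec.n_features + 1)
        img = levels[np.searchsorted(edges, theta)]
        r = np.hypot(yy - h / 2, xx - w / 2)
        img = img * (r < 0.48 * min(h, w))
    return img * spec.intensity_scale


def generate_colony_image_pair(spec: ColonySpec
                               ) -> Tuple[np.ndarray, np.ndarray]:
    """Two co-registered rasters whose expected ICQ is monotone in ``rho``.

    rho=1 duplicates the structure (complete colocalization), rho=-1 inverts
    it (complete segregation), rho=0 draws an independent second channel.
    """
    rng = np.random.default_rng(spec.seed)
    a = _pattern(spec, rng)
    indep = _pattern(spec, rng)     # independent texture, same statistics
    if spec.rho >= 0:
        b = spec.rho * a + (1.0 - spec.rho) * indep
    else:
        complement = a.max() + a.min() - a
        b = (-spec.rho) * complement + (1.0 + spec.rho) * indep
    return a, b


# ---------------------------------------------------------------------------
# the pseudo-experiment bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureCondition:
    """One simulated well: pairing, media and inoculum."""

    donor: StrainGenotype
    recipient: StrainGenotype
    media: MediaConfig
    n_donor: float = 1e7
    n_recipient: float = 1e7


@dataclass
class FixtureBundle:
    """In-memory pseudo-experiment: every pipeline input plus ground truth."""

    traces: pd.DataFrame
    counts: pd.DataFrame
    cfu: pd.DataFrame
    images: Dict[float, Tuple[np.ndarray, np.ndarray]]
    conditions: Dict[str, FixtureCondition]
    manifest: dict


RHO_LEVELS = (-1.0, -2 / 3, -1 / 3, 0.0, 1 / 3, 2 / 3, 1.0)


def make_fixture_suite(master_seed: int = 0,
                       params: Optional[ModelParams] = None,
                       protocol: Optional[BatchProtocol] = None,
                       pairings: Optional[Dict[str, tuple]] = None,
                       lw_levels: Sequence[float] = (0.0, 0.05, 0.10, 0.15),
                       noise: Optional[NoiseModel] = None,
                       out_dir: Optional[str] = None,
                       include_monocultures: bool = True) -> FixtureBundle:
    """Generate the pseudo-experiment used by the recovery and pipeline tests.

    Default: 4 strain pairings x 4 %LW levels x 6 days, each in mannose-free
    and mannose arms, with the documented ground-truth transfer terms
    (gamma = 2e-5, gamma_c = 3e-4 — the package defaults), plus colony image
    pairs at 7 colocalization levels.  Deterministic for a fixed seed.
    """
    params = params or ModelParams()
    protocol = protocol or BatchProtocol()
    pairings = pairings or PAIRING_PRESETS
    noise = noise or NoiseModel(seed=master_seed)
    ss = np.random.SeedSequence(master_seed)
    rng = np.random.default_rng(ss)

    traces, counts, cfu = [], [], []
    conditions: Dict[str, FixtureCondition] = {}
    for pairing, (donor, recipient) in pairings.items():
        for lw in lw_levels:
            for mannose in (False, True):
                media = MediaConfig(f_L=lw, f_W=lw, mannose=mannose)
                cid = f"{pairing}_lw{round(lw * 100)}" + \
                    ("_mannose" if mannose else "")
                cond = FixtureCondition(donor, recipient, media)
                conditions[cid] = cond
                traj = run_batch_protocol(
                    initial_state(media, cond.n_donor, cond.n_recipient),
                    params, donor, recipient, media, protocol, method="rk4")
                tr = simulate_plate_traces(traj, noise, well=cid, rng=rng)
                tr["condition"] = cid
                traces.append(tr)
                if include_monocultures:
                    for species, (nd, nr) in (("bacteria", (1e7, 0.0)),
                                              ("yeast", (0.0, 1e7))):
                        mono = run_batch_protocol(
                            initial_state(media, nd, nr), params, donor,
                            recipient, media, protocol, method="rk4")
                        mtr = simulate_plate_traces(
                            mono, noise, well=f"{cid}_mono_{species}",
                            culture_type="monoculture", rng=rng)
                        mtr["condition"] = cid
                        traces.append(mtr)
                fc = simulate_flow_counts(traj, noise, rng=rng)
                fc["condition"] = cid
                counts.append(fc)
                pc = simulate_cfu_plating(
                    [s.T_total for s in traj.daily], noise,
                    protocol.plating_volume_uL, protocol.well_volume_uL,
                    rng=rng)
                pc["condition"] = cid
                cfu.append(pc)

    image_seeds = ss.generate_state(len(RHO_LEVELS))
    images = {rho: generate_colony_image_pair(
        ColonySpec(rho=rho, seed=int(image_seeds[i])))
        for i, rho in enumerate(RHO_LEVELS)}

    manifest = {
        "master_seed": master_seed,
        "ground_truth": {"gamma": params.gamma, "gamma_c": params.gamma_c,
                         "k_a": params.k_a, "k_d": params.k_d},
        "noise": {"cv": noise.cv, "count_sampling": noise.count_sampling},
        "protocol": asdict(protocol),
        "conditions": {cid: {
            "donor": c.donor.name, "recipient": c.recipient.name,
            "f_L": c.media.f_L, "f_W": c.media.f_W,
            "mannose": c.media.mannose,
            "n_donor": c.n_donor, "n_recipient": c.n_recipient}
            for cid, c in conditions.items()},
        "rho_levels": list(RHO_LEVELS),
    }
    bundle = FixtureBundle(
        traces=pd.concat(traces, ignore_index=True),
        counts=pd.concat(counts, ignore_index=True),
        cfu=pd.concat(cfu, ignore_index=True),
        images=images, conditions=conditions, manifest=manifest)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: FixtureBundle, out_dir: Path) -> None:
    import tifffile

    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.traces.to_csv(out_dir / "traces.csv", index=False)
    bundle.counts.to_csv(out_dir / "counts.csv", index=False)
    bundle.cfu.to_csv(out_dir / "cfu.csv", index=False)
    files = {"traces": "traces.csv", "counts": "counts.csv", "cfu": "cfu.csv",
             "images": {}}
    for rho, (a, b) in bundle.images.items():
        name = f"colony_rho{rho:+.2f}.tiff"
        hi = max(a.max(), b.max()) or 1.0
        stack = np.stack([a, b]) / hi * 65535
        tifffile.imwrite(out_dir / name, stack.astype(np.uint16))
        files["images"][f"{rho:+.2f}"] = name
    manifest = dict(bundle.manifest, files=files)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def colocalization_sweep(levels: Sequence[float] = None,
                         params: Optional[ModelParams] = None,
                         protocol: Optional[BatchProtocol] = None,
                         pairing: str = "Ecross-Scross", lw: float = 0.15,
                         seed: int = 0) -> pd.DataFrame:
    """Joint image/model sweep over a shared colocalization level in [0, 1].

    The level scales both the image-pair correlation (rho = 2*level - 1) and
    the clump association rate, so stronger colocalization should yield both
    higher ICQ and (through the clumped transfer term) higher IDC counts.
    """
    from .quantify import compute_icq

    levels = np.asarray(levels if levels is not None
                        else np.linspace(0.0, 1.0, 7))
    params = params or ModelParams()
    protocol = protocol or BatchProtocol()
    donor, recipient = PAIRING_PRESETS[pairing]
    media = MediaConfig(f_L=lw, f_W=lw)
    seeds = np.random.SeedSequence(seed).generate_state(len(levels))
    rows = []
    for i, lvl in enumerate(levels):
        a, b = generate_colony_image_pair(
            ColonySpec(rho=2 * float(lvl) - 1, seed=int(seeds[i])))
        p = params.evolve(k_a=params.k_a * float(lvl))
        traj = run_batch_protocol(initial_state(media), p, donor, recipient,
                                  media, protocol, method="rk4")
        rows.append({"level": float(lvl), "icq": compute_icq(a, b),
                     "idc_count": traj.daily[-1].expected_cfu})
    return pd.DataFrame(rows)
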