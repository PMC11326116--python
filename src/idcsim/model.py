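"""Deterministic ODE core of the clumped conjugation model.

State tracks free and clumped pools of donor bacteria (B), recipient yeast
(Y) and transconjugants (T), four amino acids, glucose, and a cumulative
conjugation-event counter.  Growth is multiplicative Monod over each
population's required nutrients; overproducers secrete at a constant
per-cell rate; consumption is growth-coupled; death is first order.
Bacteria and yeast form reversible 1:1 clumps (mass-action association
``k_a``, dissociation ``k_d``); free mannose forces ``k_a`` to zero.
Conjugation converts recipients to transconjugants within each compartment
at per-collision rates ``gamma`` (free) and ``gamma_c`` (clumped);
transconjugants never donate, so recipient + transconjugant totals change
only through growth and death.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import params as _p
from ._kernel import _rhs, _rk4_day
from .errors import InvalidParameterError, InvalidStateError, SolverError
from .genotypes import StrainGenotype
from .media import MediaConfig, concentration
from .params import ModelParams, NUTRIENTS, pack_params

logger = logging.getLogger(__name__)

_STATE_FIELDS = ("B_f", "B_c", "Y_f", "Y_c", "T_f", "T_c",
                 "n_Leu", "n_Trp", "n_Ura", "n_His", "n_Glc", "cumulative_idc")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def monod_factor(conc: float, K: float, required: bool = True) -> float:
    """Saturating growth dependence conc/(K+conc); exactly 1 for prototrophs."""
    if not required:
        return 1.0
    if K <= 0:
        raise InvalidParameterError(f"Monod K must be > 0, got {K}")
    if conc < 0:
        raise InvalidParameterError(f"concentration must be >= 0, got {conc}")
    return conc / (K + conc)


def effective_concentration(bulk: float, P: float, sigma: float,
                            partners: float, tau_loc: float,
                            clumped: bool) -> float:
    """Nutrient concentration perceived by a (possibly clumped) bacterium.

    Clumped cells see the bulk plus the proximity-scaled standing pool
    ``P * sigma * partners * tau_loc`` secreted by their clumped yeast
    partners; free cells see the bulk only.
    """
    if not clumped:
        return bulk
    return bulk + P * sigma * partners * tau_loc


def conjugation_rate(donors: float, recipients: float, bystanders: float,
                     gamma: float, mode: str = "per_total_cell",
                     volume_uL: float = 200.0) -> float:
    """Conjugative flux (new transconjugants per hour).

    ``per_total_cell`` normalizes donor-recipient collisions by the total
    cell count: gamma * D * R / (D + R + bystanders).  With 1,000 donors,
    1,000 recipients and the literature transfer term gamma = 0.004 this
    yields exactly 2 new transconjugants per unit step.
    ``mass_action_density`` is the Levin form on densities (gamma then
    carries µL/(cell·h)).
    """
    for name, v in (("donors", donors), ("recipients", recipients),
                    ("bystanders", bystanders), ("gamma", gamma)):
        if v < 0:
            raise InvalidParameterError(f"{name} must be >= 0, got {v}")
    if mode not in _p.COLLISION_MODES:
        raise InvalidParameterError(f"unknown collision mode {mode!r}")
    if donors == 0 or recipients == 0:
        return 0.0
    if mode == "per_total_cell":
        total = donors + recipients + bystanders
        return gamma * donors * recipients / total if total > 0 else 0.0
    return gamma * donors * recipients / volume_uL


# ---------------------------------------------------------------------------
# state / protocol containers
# ---------------------------------------------------------------------------

@dataclass
class CocultureState:
    """Cell pools (cells/well), nutrients (µM; glucose g/L) and time (h)."""

    B_f: float = 0.0
    B_c: float = 0.0
    Y_f: float = 0.0
    Y_c: float = 0.0
    T_f: float = 0.0
    T_c: float = 0.0
    n_Leu: float = 0.0
    n_Trp: float = 0.0
    n_Ura: float = 0.0
    n_His: float = 0.0
    n_Glc: float = 0.0
    cumulative_idc: float = 0.0
    t: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _STATE_FIELDS])

    @classmethod
    def from_vector(cls, y: Sequence[float], t: float = 0.0) -> "CocultureState":
        return cls(**dict(zip(_STATE_FIELDS, np.asarray(y, dtype=float))), t=t)

    @property
    def B_total(self) -> float:
        return self.B_f + self.B_c

    @property
    def Y_total(self) -> float:
        return self.Y_f + self.Y_c

    @property
    def T_total(self) -> float:
        return self.T_f + self.T_c

    def validate(self, tol: float = 1e-6) -> None:
        for f in _STATE_FIELDS:
            v = getattr(self, f)
            if math.isnan(v):
                raise InvalidStateError(f"state component {f} is NaN")
            if v < -tol:
                raise InvalidStateError(f"state component {f} = {v} is negative")


def initial_state(media: MediaConfig, n_donor: float = 1e7,
                  n_recipient: float = 1e7, n_trans: float = 0.0) -> CocultureState:
    """All-free inoculum in fresh media (the study's 1e7-cells-per-well setup)."""
    return CocultureState(
        B_f=n_donor, Y_f=n_recipient, T_f=n_trans,
        n_Leu=concentration(media, "Leu"), n_Trp=concentration(media, "Trp"),
        n_Ura=concentration(media, "Ura"), n_His=concentration(media, "His"),
        n_Glc=media.glucose_gL,
    )


@dataclass(frozen=True)
class BatchProtocol:
    """Daily serial-dilution batch protocol (default: 6 days of 24 h, 1:10)."""

    n_days: int = 6
    day_length_h: float = 24.0
    fresh_fraction: float = 0.9
    carryover_fraction: float = 0.1
    sampling_interval_h: float = 0.25
    plating_volume_uL: float = 100.0
    well_volume_uL: float = 200.0
    mannose_switch_day: Optional[int] = None

    def __post_init__(self):
        if self.n_days < 0:
            raise InvalidParameterError("n_days must be >= 0")
        if abs(self.fresh_fraction + self.carryover_fraction - 1.0) > 1e-12:
            raise InvalidParameterError("fresh + carryover fractions must sum to 1")
        n = self.day_length_h / self.sampling_interval_h
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError(
                "sampling interval must divide the day length")

    @property
    def samples_per_day(self) -> int:
        return round(self.day_length_h / self.sampling_interval_h)

    @property
    def plating_fraction(self) -> float:
        return self.plating_volume_uL / self.well_volume_uL


@dataclass(frozen=True)
class DailySample:
    """End-of-day observables recorded just before each dilution."""

    day: int
    t_h: float
    B_total: float
    Y_total: float
    T_total: float
    expected_cfu: float          # transconjugants in the plated volume
    cumulative_idc: float
    mannose: bool


@dataclass
class Trajectory:
    """Dense simulated time course plus per-day samples."""

    times: np.ndarray
    states: np.ndarray           # shape (n_times, 12)
    daily: List[DailySample] = field(default_factory=list)
    clip_events: int = 0
    day_length_h: float = 24.0

    def state_at(self, i: int) -> CocultureState:
        return CocultureState.from_vector(self.states[i], t=self.times[i])

    @property
    def final_state(self) -> CocultureState:
        return self.state_at(len(self.times) - 1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (day, t_h, compartment, value)."""
        day = np.maximum(1, np.ceil(self.times / self.day_length_h - 1e-12)
                         .astype(int))
        day[self.times == 0.0] = 1
        frames = []
        for j, name in enumerate(_STATE_FIELDS):
            frames.append(pd.DataFrame({
                "day": day, "t_h": self.times, "compartment": name,
                "value": self.states[:, j]}))
        return pd.concat(frames, ignore_index=True)

    def daily_frame(self) -> pd.DataFrame:
        rows = [{"day": s.day, "t_h": s.t_h, "B_total": s.B_total,
                 "Y_total": s.Y_total, "T_total": s.T_total,
                 "expected_cfu": s.expected_cfu,
                 "cumulative_idc": s.cumulative_idc, "mannose": s.mannose}
                for s in self.daily]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def derivatives(state: CocultureState, params: ModelParams,
                donor: StrainGenotype, recipient: StrainGenotype,
                media: MediaConfig) -> CocultureState:
    """Time derivatives of every state component (same shape as the state)."""
    state.validate()
    pp = pack_params(params, donor, recipient, media)
    dy = _rhs(state.t, state.to_vector(), pp)
    return CocultureState.from_vector(dy, t=state.t)


def reduced_two_species_derivatives(B: float, Y_total: float,
                                    nutrients: Sequence[float],
                                    params: ModelParams,
                                    donor: StrainGenotype,
                                    recipient: StrainGenotype,
                                    media: MediaConfig
                                    ) -> Tuple[float, float, np.ndarray]:
    """Two-ODE reduction: total bacteria and total yeast (incl. transconjugants).

    Identical growth/secretion/consumption laws as the full model with all
    clumped pools empty and transfer off; used for stage-1 (mannose) fitting.
    Returns (dB/dt, dY_total/dt, dn/dt over Leu, Trp, Ura, His, Glc).
    """
    st = CocultureState(B_f=B, Y_f=Y_total,
                        n_Leu=nutrients[0], n_Trp=nutrients[1],
                        n_Ura=nutrients[2], n_His=nutrients[3],
                        n_Glc=nutrients[4])
    p0 = params.evolve(k_a=0.0, gamma=0.0, gamma_c=0.0)
    d = derivatives(st, p0, donor, recipient, media)
    dn = np.array([d.n_Leu, d.n_Trp, d.n_Ura, d.n_His, d.n_Glc])
    return d.B_f, d.Y_f + d.T_f, dn


def integrate_day(state: CocultureState, params: ModelParams,
                  donor: StrainGenotype, recipient: StrainGenotype,
                  media: MediaConfig, duration_h: float,
                  sampling_interval_h: float = 0.25,
                  method: str = "lsoda", rtol: float = 1e-8,
                  atol: float = 1e-6, steps_per_sample: int = 12,
                  ) -> Tuple[np.ndarray, np.ndarray, int]:
    """Integrate one batch day, reporting on the uniform sampling grid.

    ``method='lsoda'`` is the adaptive stiff-capable reference path;
    ``method='rk4'`` is the fixed-step screening path used by fitting loops.
    Returns (times within the day, states, clip-event count).
    """
    if duration_h <= 0:
        raise InvalidParameterError("duration_h must be > 0")
    state.validate()
    n_samples = round(duration_h / sampling_interval_h)
    if abs(n_samples * sampling_interval_h - duration_h) > 1e-9 or n_samples < 1:
        raise InvalidParameterError("sampling interval must divide the duration")
    grid = np.linspace(0.0, duration_h, n_samples + 1)
    pp = pack_params(params, donor, recipient, media)
    y0 = np.clip(state.to_vector(), 0.0, None)

    if method == "rk4":
        ys = _rk4_day(y0, pp, duration_h, n_samples * steps_per_sample,
                      steps_per_sample)
        return grid, ys, 0
    if method != "lsoda":
        raise InvalidParameterError(f"unknown integration method {method!r}")

    sol = solve_ivp(_rhs, (0.0, duration_h), y0, method="LSODA",
                    t_eval=grid, args=(pp,), rtol=rtol, atol=atol)
    if not sol.success:
        raise SolverError(f"LSODA failed: {sol.message}",
                          final_state=CocultureState.from_vector(
                              sol.y[:, -1], t=state.t + sol.t[-1]))
    ys = sol.y.T
    clips = int(np.sum(ys < -atol))
    if clips:
        logger.debug("clipped %d negative components to zero", clips)
    ys = np.clip(ys, 0.0, None)
    return grid, ys, clips


def apply_dilution(state: CocultureState, fresh_media: MediaConfig,
                   fresh_fraction: float = 0.9,
                   carryover_fraction: float = 0.1) -> CocultureState:
    """1:10 daily transfer: cells scaled by carryover, nutrients replenished.

    The cumulative conjugation counter is an event tally, not a well content,
    and is left untouched.
    """
    if abs(fresh_fraction + carryover_fraction - 1.0) > 1e-12:
        raise InvalidParameterError("fractions must sum to 1")
    c = carryover_fraction
    f = fresh_fraction
    return CocultureState(
        B_f=state.B_f * c, B_c=state.B_c * c,
        Y_f=state.Y_f * c, Y_c=state.Y_c * c,
        T_f=state.T_f * c, T_c=state.T_c * c,
        n_Leu=f * concentration(fresh_media, "Leu") + c * state.n_Leu,
        n_Trp=f * concentration(fresh_media, "Trp") + c * state.n_Trp,
        n_Ura=f * concentration(fresh_media, "Ura") + c * state.n_Ura,
        n_His=f * concentration(fresh_media, "His") + c * state.n_His,
        n_Glc=f * fresh_media.glucose_gL + c * state.n_Glc,
        cumulative_idc=state.cumulative_idc,
        t=state.t,
    )


def release_clumps(state: CocultureState) -> CocultureState:
    """Instantaneously move every clumped cell to its free pool."""
    return replace(state,
                   B_f=state.B_f + state.B_c, B_c=0.0,
                   Y_f=state.Y_f + state.Y_c, Y_c=0.0,
                   T_f=state.T_f + state.T_c, T_c=0.0)


def run_batch_protocol(initial: CocultureState, params: ModelParams,
                       donor: StrainGenotype, recipient: StrainGenotype,
                       media: MediaConfig, protocol: BatchProtocol,
                       method: str = "lsoda", rtol: float = 1e-8,
                       atol: float = 1e-6, steps_per_sample: int = 12,
                       ) -> Trajectory:
    """Alternate day-long integrations with 1:10 dilutions for ``n_days``.

    A ``DailySample`` is recorded at each pre-dilution instant, with the
    expected selective-plate CFU = T_total * plating_volume / well_volume.
    If ``mannose_switch_day`` is set, media switch to mannose after that
    day's dilution and all clumped cells are released instantly.
    """
    initial.validate()
    state = initial
    times = [0.0]
    states = [np.clip(initial.to_vector(), 0.0, None)]
    traj = Trajectory(times=np.array(times), states=np.array(states),
                      day_length_h=protocol.day_length_h)
    clip_total = 0
    switch = protocol.mannose_switch_day

    for day in range(1, protocol.n_days + 1):
        mannose_now = media.mannose or (switch is not None and day > switch)
        media_day = media.with_mannose(True) if mannose_now else media
        try:
            grid, ys, clips = integrate_day(
                state, params, donor, recipient, media_day,
                protocol.day_length_h, protocol.sampling_interval_h,
                method=method, rtol=rtol, atol=atol,
                steps_per_sample=steps_per_sample)
        except SolverError as err:
            raise SolverError(f"day {day}: {err}",
                              final_state=err.final_state, day=day) from err
        clip_total += clips
        t0 = state.t
        times.extend((t0 + grid[1:]).tolist())
        states.extend(list(ys[1:]))
        state = CocultureState.from_vector(ys[-1], t=t0 + protocol.day_length_h)
        traj.daily.append(DailySample(
            day=day, t_h=state.t,
            B_total=state.B_total, Y_total=state.Y_total,
            T_total=state.T_total,
            expected_cfu=state.T_total * protocol.plating_fraction,
            cumulative_idc=state.cumulative_idc, mannose=mannose_now))
        if day < protocol.n_days:
            # the post-dilution state is not appended to the dense trace: a
            # plate reader samples each instant once, and times must be
            # strictly increasing; the next day's grid reflects the dilution
            state = apply_dilution(state, media, protocol.fresh_fraction,
                                   protocol.carryover_fraction)
            if switch is not None and day == switch:
                state = release_clumps(state)

    traj.times = np.asarray(times)
    traj.states = np.asarray(states)
    traj.clip_events = clip_total
    return traj
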