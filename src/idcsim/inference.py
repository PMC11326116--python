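"""Latin Hypercube parameter estimation and model sweeps.

The fitting strategy mirrors the staged procedure used to calibrate the
coculture model: growth/consumption constants are fit first against
clump-free (mannose) traces with the reduced two-species model; the free
transfer term ``gamma`` is then fit against mannose-arm transconjugant
counts; finally the clumped transfer term ``gamma_c`` is fit against
mannose-free counts with ``gamma`` held fixed.  Each stage runs iterative
Latin Hypercube Sampling: sample, score, keep the best fraction, shrink each
range to the keepers' span, resample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .errors import DataError, InvalidParameterError, SolverError
from .genotypes import StrainGenotype
from .media import MediaConfig
from .model import BatchProtocol, Trajectory, initial_state, run_batch_protocol
from .params import ModelParams

logger = logging.getLogger(__name__)

OBSERVABLES = ("transconjugants_per_plated_volume", "species_totals",
               "fluorescence_proxy")


# ---------------------------------------------------------------------------
# parameter ranges and LHS sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamRange:
    """Sampling range for one free parameter; log-scaled ranges are
    stratified in log10 space."""

    lo: float
    hi: float
    log: bool = False

    def __post_init__(self):
        if self.lo > self.hi:
            raise InvalidParameterError(f"range lo {self.lo} > hi {self.hi}")
        if self.log and self.lo <= 0:
            raise InvalidParameterError("log-scaled range requires lo > 0")


def lhs_sample(ranges: Dict[str, ParamRange], n: int, seed: int) -> pd.DataFrame:
    """n parameter vectors with the Latin property per marginal."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    names = sorted(ranges)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    cols = {}
    for j, name in enumerate(names):
        r = ranges[name]
        if r.log:
            lo, hi = math.log10(r.lo), math.log10(r.hi)
            cols[name] = 10 ** (lo + unit[:, j] * (hi - lo))
        else:
            cols[name] = r.lo + unit[:, j] * (r.hi - r.lo)
    return pd.DataFrame(cols)


def set_param(base: ModelParams, name: str, value: float) -> ModelParams:
    """Return params with one (possibly dotted, e.g. ``bacterium.mu``) field set."""
    if "." in name:
        pop, attr = name.split(".", 1)
        kin = getattr(base, pop)
        if kin is None:  # transconjugant defaulting to yeast kinetics
            kin = base.yeast
        return base.evolve(**{pop: replace(kin, **{attr: value})})
    return base.evolve(**{name: value})


def apply_theta(base: ModelParams, theta: Dict[str, float]) -> ModelParams:
    p = base
    for k, v in theta.items():
        p = set_param(p, k, v)
    return p


# ---------------------------------------------------------------------------
# error definitions
# ---------------------------------------------------------------------------

def normalize_post_cutoff(t: np.ndarray, v: np.ndarray,
                          cutoff_h: float = 24.0) -> np.ndarray:
    post = v[t >= cutoff_h]
    m = post.max() if post.size else 0.0
    if m <= 0:
        raise DataError("no positive readings after the cutoff")
    return v / m


def trajectory_error(sim: pd.DataFrame, data: pd.DataFrame,
                     cutoff_h: float = 24.0) -> float:
    """Summed squared difference between after-day-1-normalized model and
    data traces, over all shared species, on the data's time grid.

    Both inputs are tidy tables (t_h, species, value); the simulation is
    interpolated onto each species' data grid before normalization.
    """
    if data.empty:
        raise DataError("empty data traces")
    err = 0.0
    shared = set(sim["species"]) & set(data["species"])
    if not shared:
        raise DataError("no shared species between simulation and data")
    for sp in sorted(shared):
        d = data[data["species"] == sp].sort_values("t_h")
        s = sim[sim["species"] == sp].sort_values("t_h")
        sim_on_grid = np.interp(d["t_h"].to_numpy(), s["t_h"].to_numpy(),
                                s["value"].to_numpy())
        dn = normalize_post_cutoff(d["t_h"].to_numpy(), d["value"].to_numpy(),
                                   cutoff_h)
        sn = normalize_post_cutoff(d["t_h"].to_numpy(), sim_on_grid, cutoff_h)
        err += float(np.sum((sn - dn) ** 2))
    return err


def count_series_error(model_counts: Sequence[float],
                       data_counts: Sequence[float]) -> float:
    """SSE on log10(count + 1); robust across the decades CFU counts span."""
    m = np.log10(np.asarray(model_counts, dtype=float) + 1.0)
    d = np.log10(np.asarray(data_counts, dtype=float) + 1.0)
    if m.shape != d.shape:
        raise DataError("count series must be paired")
    return float(np.sum((m - d) ** 2))


# ---------------------------------------------------------------------------
# iterative LHS fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    best_params: Dict[str, float]
    best_error: float
    history: List[pd.DataFrame]           # per round: sampled theta + error
    ranking: List[Tuple[str, float]]
    final_ranges: Dict[str, ParamRange] = field(default_factory=dict)
    report: Dict[str, bool] = field(default_factory=dict)


def rank_parameters(samples: pd.DataFrame, errors: Sequence[float]
                    ) -> List[Tuple[str, float]]:
    """Spearman rank-correlation magnitude of each parameter against the
    error, sorted descending; ties broken alphabetically."""
    errors = np.asarray(errors, dtype=float)
    finite = np.isfinite(errors)
    if finite.sum() < 10:
        raise DataError("need >= 10 scored samples to rank parameters")
    if np.all(errors[finite] == errors[finite][0]):
        logger.warning("constant error vector; all sensitivities zero")
        return sorted((name, 0.0) for name in samples.columns)
    scores = []
    for name in samples.columns:
        x = samples[name].to_numpy()[finite]
        if np.all(x == x[0]):
            rho = 0.0
        else:
            rho = stats.spearmanr(x, errors[finite]).statistic
            if not np.isfinite(rho):
                rho = 0.0
        scores.append((name, abs(float(rho))))
    return sorted(scores, key=lambda kv: (-kv[1], kv[0]))


def _shrink(ranges: Dict[str, ParamRange], keepers: pd.DataFrame
            ) -> Dict[str, ParamRange]:
    """Shrink each range to the keepers' min-max; never expands."""
    out = {}
    for name, r in ranges.items():
        lo = max(r.lo, float(keepers[name].min()))
        hi = min(r.hi, float(keepers[name].max()))
        if lo > hi:
            lo = hi = float(keepers[name].iloc[0])
        out[name] = ParamRange(lo, hi, r.log)
    return out


def iterative_lhs_fit(objective: Callable[[Dict[str, float]], float],
                      ranges: Dict[str, ParamRange], n_samples: int = 500,
                      n_rounds: int = 3, keep_fraction: float = 0.2,
                      seed: int = 0) -> FitResult:
    """Sample, score, keep the best fraction, shrink, resample.

    Failed evaluations score +inf (they keep the Latin structure of each
    round but rank last).  Raises if every sample of a round fails.
    """
    if not 0 < keep_fraction <= 1:
        raise InvalidParameterError("keep_fraction must be in (0, 1]")
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_rounds)
    cur = dict(ranges)
    history: List[pd.DataFrame] = []
    best_theta: Optional[Dict[str, float]] = None
    best_err = math.inf
    for rnd in range(n_rounds):
        samples = lhs_sample(cur, n_samples, int(rng_seeds[rnd]))
        errs = np.empty(len(samples))
        for i, theta in enumerate(samples.to_dict("records")):
            try:
                errs[i] = objective(theta)
            except SolverError:
                errs[i] = math.inf
        tab = samples.copy()
        tab["error"] = errs
        tab["round"] = rnd
        history.append(tab)
        if not np.isfinite(errs).any():
            raise SolverError(
                f"all {n_samples} samples failed in round {rnd}")
        i_best = int(np.argmin(errs))
        if errs[i_best] < best_err:
            best_err = float(errs[i_best])
            best_theta = samples.iloc[i_best].to_dict()
        if rnd < n_rounds - 1:
            n_keep = max(1, int(round(keep_fraction * n_samples)))
            keep_idx = np.argsort(errs, kind="stable")[:n_keep]
            keepers = samples.iloc[keep_idx]
            # the incumbent best must stay inside the shrunk ranges
            keepers = pd.concat(
                [keepers, pd.DataFrame([best_theta])], ignore_index=True)
            cur = _shrink(cur, keepers)
    all_rounds = pd.concat(history, ignore_index=True)
    ranking = rank_parameters(all_rounds[list(ranges)], all_rounds["error"])
    return FitResult(best_params=best_theta, best_error=best_err,
                     history=history, ranking=ranking, final_ranges=cur)


# ---------------------------------------------------------------------------
# sweeps and phase maps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    axes: List[Tuple[str, np.ndarray]]
    table: pd.DataFrame


def _observable_series(traj: Trajectory, observable: str,
                       fluorescence_yield: float) -> pd.DataFrame:
    rows = []
    for s in traj.daily:
        if observable == "transconjugants_per_plated_volume":
            rows.append({"day": s.day, "value": s.expected_cfu})
        elif observable == "species_totals":
            rows.append({"day": s.day, "value": s.B_total,
                         "species": "bacteria"})
            rows.append({"day": s.day, "value": s.Y_total + s.T_total,
                         "species": "yeast"})
        else:  # fluorescence_proxy: donor-channel signal
            rows.append({"day": s.day,
                         "value": s.B_total * fluorescence_yield})
    return pd.DataFrame(rows)


def parameter_sweep(base_params: ModelParams, axes: List[Tuple[str, Sequence[float]]],
                    donor: StrainGenotype, recipient: StrainGenotype,
                    media: MediaConfig, protocol: BatchProtocol,
                    observable: str = "transconjugants_per_plated_volume",
                    n_donor: float = 1e7, n_recipient: float = 1e7,
                    matched_value: Optional[float] = None,
                    matched_rtol: float = 0.25,
                    fluorescence_yield: float = 1.0,
                    method: str = "rk4") -> SweepResult:
    """Run the batch protocol over a 1- or 2-parameter grid.

    Cells whose solve fails are recorded as NaN without aborting the sweep.
    ``matched_value`` marks grid cells whose day-``n_days`` observable falls
    within ``matched_rtol`` of a supplied experimental value (the heat-marker
    role in the transfer-term heatmaps).
    """
    if observable not in OBSERVABLES:
        raise InvalidParameterError(f"unknown observable {observable!r}")
    if not 1 <= len(axes) <= 2 or any(len(g) == 0 for _, g in axes):
        raise InvalidParameterError("need 1-2 non-empty axes")
    grids = [np.asarray(g, dtype=float) for _, g in axes]
    names = [n for n, _ in axes]
    mesh = np.stack([m.ravel() for m in np.meshgrid(*grids, indexing="ij")], axis=1)
    rows = []
    for point in mesh:
        p = base_params
        for name, v in zip(names, point):
            p = set_param(p, name, float(v))
        cell = {n: v for n, v in zip(names, point)}
        try:
            traj = run_batch_protocol(
                initial_state(media, n_donor, n_recipient), p, donor,
                recipient, media, protocol, method=method)
        except SolverError as err:
            logger.warning("sweep cell %s failed: %s", cell, err)
            rows.append({**cell, "day": np.nan, "observable": observable,
                         "value": np.nan, "matched": False})
            continue
        obs = _observable_series(traj, observable, fluorescence_yield)
        for _, r in obs.iterrows():
            matched = bool(
                matched_value is not None
                and r["day"] == protocol.n_days
                and matched_value > 0
                and abs(r["value"] - matched_value) <= matched_rtol * matched_value)
            rows.append({**cell, "day": int(r["day"]),
                         "observable": observable, "value": r["value"],
                         **({"species": r["species"]} if "species" in r and
                            isinstance(r.get("species"), str) else {}),
                         "matched": matched})
    return SweepResult(axes=list(zip(names, grids)), table=pd.DataFrame(rows))


def rescue_phase_map(base_params: ModelParams, L_fractions: Sequence[float],
                     H_fractions: Sequence[float], donor: StrainGenotype,
                     recipient: StrainGenotype, protocol: BatchProtocol,
                     f_W: float = 1.0, f_U: float = 1.0,
                     n_donor: float = 1e7, n_recipient: float = 1e7,
                     collapse_threshold: float = 1e5,
                     rescued_threshold: float = 5e6,
                     method: str = "rk4") -> SweepResult:
    """Day-final recipient+transconjugant totals and IDC counts over a
    leucine x histidine media grid, classified into collapse / suppressed /
    rescued by configurable thresholds.

    Rescue conditions: the recipient is a His (or Ura) auxotroph and the
    donor payload restores prototrophy in transconjugants.
    """
    rows = []
    for f_L in L_fractions:
        for f_H in H_fractions:
            media = MediaConfig(f_L=float(f_L), f_W=f_W, f_U=f_U, f_H=float(f_H))
            try:
                traj = run_batch_protocol(
                    initial_state(media, n_donor, n_recipient), base_params,
                    donor, recipient, media, protocol, method=method)
            except SolverError as err:
                logger.warning("phase-map cell (%s, %s) failed: %s", f_L, f_H, err)
                rows.append({"f_L": f_L, "f_H": f_H, "recipient_total": np.nan,
                             "idc_count": np.nan, "classification": "failed"})
                continue
            last = traj.daily[-1]
            total = last.Y_total + last.T_total
            if total < collapse_threshold:
                cls = "collapse"
            elif total >= rescued_threshold:
                cls = "rescued"
            else:
                cls = "suppressed"
            rows.append({"f_L": float(f_L), "f_H": float(f_H),
                         "recipient_total": total,
                         "idc_count": last.expected_cfu,
                         "classification": cls})
    return SweepResult(axes=[("f_L", np.asarray(L_fractions, dtype=float)),
                             ("f_H", np.asarray(H_fractions, dtype=float))],
                       table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# staged fit against a pseudo-experiment bundle
# ---------------------------------------------------------------------------

DEFAULT_STAGE1_RANGES = {
    "bacterium.mu": ParamRange(0.1, 1.0),
    "yeast.mu": ParamRange(0.05, 0.8),
    "bacterium.u_aa": ParamRange(1e-6, 1e-4, log=True),
    "yeast.u_aa": ParamRange(3.5e-7, 3.5e-5, log=True),
}
#: transfer-term search spans the literature value 4e-3 and the fitted bands
GAMMA_RANGE = ParamRange(1e-7, 1e-2, log=True)


@dataclass
class StagedFitResult:
    stage1: FitResult
    stage2: FitResult
    stage3: FitResult
    params: ModelParams
    report: Dict[str, bool]

    @property
    def gamma(self) -> float:
        return self.stage2.best_params["gamma"]

    @property
    def gamma_c(self) -> float:
        return self.stage3.best_params["gamma_c"]


def _sim_traces(params, condition, protocol, method="rk4"):
    traj = run_batch_protocol(
        initial_state(condition.media, condition.n_donor, condition.n_recipient),
        params, condition.donor, condition.recipient, condition.media,
        protocol, method=method)
    t = traj.times
    b = traj.states[:, 0] + traj.states[:, 1]
    y = traj.states[:, 2:6].sum(axis=1)
    return traj, pd.DataFrame({
        "t_h": np.concatenate([t, t]),
        "species": ["bacteria"] * len(t) + ["yeast"] * len(t),
        "value": np.concatenate([b, y])})


def staged_fit(bundle, condition_id: str, base_params: ModelParams,
               protocol: BatchProtocol, n_samples: int = 500,
               n_rounds: int = 3, keep_fraction: float = 0.2, seed: int = 0,
               stage1_ranges: Optional[Dict[str, ParamRange]] = None
               ) -> StagedFitResult:
    """Three-stage LHS calibration against a pseudo-experiment bundle.

    Stage 1 fits growth/consumption constants on the mannose (clump-free)
    arm with transfer off, scoring both the normalized fluorescence traces
    and the absolute daily flow counts (the dual measurement scheme: shapes
    alone leave per-cell consumption nearly scale-invariant, absolute counts
    pin it).  Stage 2 fits ``gamma`` on mannose-arm daily transconjugant
    counts; stage 3 fits ``gamma_c`` on the mannose-free counts with
    ``gamma`` fixed.  ``bundle`` must expose ``traces``, ``counts`` (tidy
    tables with a ``condition`` column whose ids end in ``_mannose`` for the
    mannose arm) and ``conditions`` metadata.
    """
    seeds = np.random.SeedSequence(seed).generate_state(3)
    cond_free = bundle.conditions[condition_id + "_mannose"]
    cond_clump = bundle.conditions[condition_id]

    man_traces = bundle.traces[
        bundle.traces["condition"] == condition_id + "_mannose"]
    man_traces = man_traces[man_traces.get("culture_type", "coculture")
                            == "coculture"]
    channel_species = {"mCherry": "bacteria", "ymCitrine": "yeast"}
    data_traces = man_traces[man_traces["channel"].isin(channel_species)].copy()
    data_traces["species"] = data_traces["channel"].map(channel_species)
    if data_traces.empty:
        raise DataError(f"no mannose traces for condition {condition_id!r}")

    cnt = bundle.counts[bundle.counts["condition"] == condition_id + "_mannose"]
    data_b = cnt[cnt["species"] == "bacteria"].sort_values("day")["count"].to_numpy()
    data_y = cnt[cnt["species"] == "yeast"].sort_values("day")["count"].to_numpy()
    count_weight = 10.0  # log-count SSE units vs normalized-trace SSE units

    def stage1_objective(theta):
        p = apply_theta(base_params, theta).evolve(gamma=0.0, gamma_c=0.0)
        traj, sim = _sim_traces(p, cond_free, protocol)
        model_b = np.array([s.B_total for s in traj.daily])
        model_y = np.array([s.Y_total + s.T_total for s in traj.daily])
        return (trajectory_error(sim, data_traces)
                + count_weight * (count_series_error(model_b, data_b)
                                  + count_series_error(model_y, data_y)))

    stage1 = iterative_lhs_fit(stage1_objective,
                               stage1_ranges or DEFAULT_STAGE1_RANGES,
                               n_samples, n_rounds, keep_fraction,
                               int(seeds[0]))
    growth_params = apply_theta(base_params, stage1.best_params)

    def t_counts(cond_id):
        c = bundle.counts
        sel = c[(c["condition"] == cond_id) & (c["species"] == "transconjugant")]
        return sel.sort_values("day")["count"].to_numpy()

    data_t_free = t_counts(condition_id + "_mannose")
    data_t_clump = t_counts(condition_id)

    def daily_t(params, condition):
        traj, _ = _sim_traces(params, condition, protocol)
        return np.array([s.T_total for s in traj.daily])

    def stage2_objective(theta):
        p = apply_theta(growth_params, theta)
        return count_series_error(daily_t(p, cond_free), data_t_free)

    stage2 = iterative_lhs_fit(stage2_objective, {"gamma": GAMMA_RANGE},
                               n_samples, n_rounds, keep_fraction,
                               int(seeds[1]))
    gamma = stage2.best_params["gamma"]

    def stage3_objective(theta):
        p = apply_theta(growth_params, theta).evolve(gamma=gamma)
        return count_series_error(daily_t(p, cond_clump), data_t_clump)

    stage3 = iterative_lhs_fit(stage3_objective, {"gamma_c": GAMMA_RANGE},
                               n_samples, n_rounds, keep_fraction,
                               int(seeds[2]))

    fitted = growth_params.evolve(gamma=gamma,
                                  gamma_c=stage3.best_params["gamma_c"])
    report = _qualitative_report(fitted, cond_clump, protocol, bundle,
                                 condition_id)
    return StagedFitResult(stage1=stage1, stage2=stage2, stage3=stage3,
                           params=fitted, report=report)


def _qualitative_report(params, condition, protocol, bundle, condition_id):
    """The three named qualitative checks: supplementation response,
    steady-state survival, approximate donor-to-recipient ratio."""
    traj, _ = _sim_traces(params, condition, protocol)
    last = traj.daily[-1]
    richer = replace(condition.media,
                     f_L=min(10.0, condition.media.f_L * 2 + 0.05),
                     f_W=min(10.0, condition.media.f_W * 2 + 0.05))
    traj_rich = run_batch_protocol(
        initial_state(richer, condition.n_donor, condition.n_recipient),
        params, condition.donor, condition.recipient, richer, protocol,
        method="rk4")
    rich_last = traj_rich.daily[-1]
    report = {
        "supplementation_response": bool(
            rich_last.B_total + rich_last.Y_total
            > last.B_total + last.Y_total),
        "steady_state_survival": bool(last.B_total > 1e3
                                      and last.Y_total > 1e3),
    }
    c = bundle.counts
    sel = c[c["condition"] == condition_id]
    by = sel.pivot_table(index="day", columns="species", values="count")
    if {"bacteria", "yeast"} <= set(by.columns):
        data_dr = (by["bacteria"] / by["bacteria"].max()) / \
            (by["yeast"] / by["yeast"].max())
        model_b = np.array([s.B_total for s in traj.daily])
        model_y = np.array([s.Y_total + s.T_total for s in traj.daily])
        model_dr = (model_b / model_b.max()) / (model_y / model_y.max())
        final_ratio = model_dr[-1] / data_dr.iloc[-1]
        report["approximate_dr_match"] = bool(0.2 < final_ratio < 5.0)
    else:
        report["approximate_dr_match"] = False
    return report
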