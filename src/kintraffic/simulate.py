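"""Gillespie simulation driver: configuration, outputs, and measurement.

The heavy lifting happens in the compiled kernel (:mod:`kintraffic._kernel`);
this module prepares buffers, converts the raw event records into tidy
pandas tables, and computes the empirical observables that mirror the
mean-field predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .params import ModelParams, PausingParams

DETACH_CAUSE_LABELS = {
    _kernel.CAUSE_SPONTANEOUS: "spontaneous",
    _kernel.CAUSE_FACILITATED: "facilitated",
    _kernel.CAUSE_TRUNCATED: "truncated",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Ring size, time window, sampling, and seeding of one simulation."""

    L: int = 2000
    t_end: float = 60.0
    burn_in: float = 10.0
    frame_interval: float = 0.1
    seed: int = 0
    tracer_fraction: float = 1.0
    record_frames: bool = True

    def __post_init__(self) -> None:
        if self.L < 4:
            raise ValueError("L must be at least 4")
        if not (0 <= self.burn_in < self.t_end):
            raise ValueError("need 0 <= burn_in < t_end")
        if not (0.0 <= self.tracer_fraction <= 1.0):
            raise ValueError("tracer_fraction must be in [0, 1]")


@dataclass
class SimulationOutput:
    """Raw tables and summary counters from one Gillespie run."""

    config: SimulationConfig
    params: ModelParams
    pausing: PausingParams
    frames: pd.DataFrame       # motor_id, frame, time_s, position_sites, active
    runs: pd.DataFrame         # per-binding-event records
    summary: dict = field(default_factory=dict)

    @property
    def trajectories(self) -> pd.DataFrame:
        """Frame-sampled tracer trajectories (TrajectoryTable).

        Columns: motor_id, time_s, position_sites, active, bound.  When
        ``tracer_fraction`` < 1 a seeded per-motor subsample is returned.
        """
        df = self.frames
        frac = self.config.tracer_fraction
        if frac < 1.0 and len(df):
            uids = df["motor_id"].unique()
            rng = np.random.default_rng(self.config.seed + 987654321)
            keep = uids[rng.random(len(uids)) < frac]
            df = df[df["motor_id"].isin(keep)]
        out = df.copy()
        out["bound"] = True
        return out


def _default_burn_in(params: ModelParams) -> float:
    # several dwell times; 20/omega_D when spontaneous detachment is present
    return 20.0 / params.omega_D if params.omega_D > 0 else 10.0 / params.nu


def run_gillespie(params: ModelParams,
                  pausing: PausingParams | None = None,
                  config: SimulationConfig | None = None,
                  initial_fronts=None) -> SimulationOutput:
    """Run one statistically exact trajectory of the lattice gas.

    Identical ``(seed, config, params)`` give identical output.  The lattice
    starts empty unless ``initial_fronts`` lists front-head sites of motors
    present at time zero.
    """
    if pausing is None:
        pausing = PausingParams.disabled()
    if config is None:
        config = SimulationConfig()
    L, t_end = config.L, config.t_end
    r_in = pausing.r_inactivation if pausing.enabled else 0.0
    r_act = pausing.r_activation if pausing.enabled else 0.0

    nframes = int(np.floor(t_end / config.frame_interval)) + 1
    frame_start_k = int(np.ceil(config.burn_in / config.frame_interval))
    if config.record_frames:
        frame_cap = max(1, (nframes - frame_start_k + 1) * (L // 2))
    else:
        frame_cap = 1
    mean_attach = params.omega_A * L * t_end
    run_cap = int(mean_attach + 6 * np.sqrt(mean_attach + 1)) + L // 2 + 64

    run_uid = np.empty(run_cap, np.int64)
    run_t0 = np.empty(run_cap, np.float64)
    run_t1 = np.empty(run_cap, np.float64)
    run_site0 = np.empty(run_cap, np.int32)
    run_steps = np.empty(run_cap, np.int64)
    run_cause = np.empty(run_cap, np.int8)
    fr_uid = np.empty(frame_cap, np.int64)
    fr_k = np.empty(frame_cap, np.int32)
    fr_pos = np.empty(frame_cap, np.int64)
    fr_active = np.empty(frame_cap, np.bool_)

    if initial_fronts is None:
        initial = np.empty(0, np.int64)
    else:
        initial = np.asarray(initial_fronts, np.int64)

    (run_count, frame_count, acc_bound, acc_pe, hops_measured,
     attach_count, det_s, det_f, frames_dropped, runs_dropped,
     consistent) = _kernel.run_kernel(
        L, params.nu, params.omega_A, params.omega_D, params.theta,
        r_in, r_act,
        t_end, config.burn_in, config.frame_interval, frame_start_k,
        config.record_frames, np.int64(config.seed) % np.int64(2**31 - 1),
        initial,
        run_uid, run_t0, run_t1, run_site0, run_steps, run_cause,
        fr_uid, fr_k, fr_pos, fr_active)

    if not consistent:
        raise AssertionError("channel-count bookkeeping lost consistency")

    runs = pd.DataFrame({
        "motor_id": run_uid[:run_count],
        "attach_time": run_t0[:run_count],
        "detach_time": run_t1[:run_count],
        "attach_site": run_site0[:run_count],
        "steps": run_steps[:run_count],
        "detach_cause": pd.Categorical.from_codes(
            run_cause[:run_count], categories=[
                DETACH_CAUSE_LABELS[0], DETACH_CAUSE_LABELS[1],
                DETACH_CAUSE_LABELS[2]]),
    })
    runs["dwell"] = runs["detach_time"] - runs["attach_time"]
    runs["run_length_sites"] = runs["steps"]

    frames = pd.DataFrame({
        "motor_id": fr_uid[:frame_count],
        "frame": fr_k[:frame_count],
        "position_sites": fr_pos[:frame_count],
        "active": fr_active[:frame_count],
    })
    frames["time_s"] = frames["frame"] * config.frame_interval

    T = t_end - config.burn_in
    summary = {
        "t_measured": T,
        "rho": acc_bound / (T * L),
        "pair_vacancy": acc_pe / (T * L),
        "j": hops_measured / (T * L),
        "total_steps_measured": int(hops_measured),
        "attach_events": int(attach_count),
        "detach_spontaneous": int(det_s),
        "detach_facilitated": int(det_f),
        "frames_dropped": int(frames_dropped),
        "runs_dropped": int(runs_dropped),
    }
    return SimulationOutput(config=config, params=params, pausing=pausing,
                            frames=frames, runs=runs, summary=summary)


@dataclass(frozen=True)
class EmpiricalObservables:
    """Measured counterparts of the mean-field (rho, j, tau, V, l, lam)."""

    rho: float
    j: float
    tau: float
    V: float
    l: float
    lam: float
    n_runs: int
    facilitated_fraction: float


def tracer_landing_count(outputs, params: ModelParams | None = None,
                         assay_rings: int = 64, seed: int = 0) -> tuple:
    """Simulated tracer-landing count of a multi-filament landing assay.

    Labelled tracers at the reference concentration are too dilute to
    perturb the lattice, so given the pair-vacancy trajectory their
    landings form a Poisson process with intensity lambda0 (per um of
    filament per second) times the pair-vacancy fraction.  This draws the
    landing count of an assay of ``assay_rings`` filaments statistically
    identical to each simulated ring and returns ``(count, lam_hat, se)``
    with ``lam_hat = count / (filament length x observation time)`` in
    um^-1 s^-1 and the Poisson counting error.  Mirrors how landing rates
    (and their uncertainties) are obtained experimentally.
    """
    if not isinstance(outputs, (list, tuple)):
        outputs = [outputs]
    if params is None:
        params = outputs[0].params
    area = 0.0      # um * s observed
    intensity = 0.0  # expected landings
    for out in outputs:
        T = out.summary["t_measured"]
        length_um = out.config.L * params.a
        area += length_um * T * assay_rings
        lam = params.lambda0 * out.summary["pair_vacancy"]
        intensity += lam * length_um * T * assay_rings
    count = int(np.random.default_rng(seed).poisson(intensity))
    lam_hat = count / area
    se = np.sqrt(max(count, 1)) / area
    return count, lam_hat, se


def measure_observables(output: SimulationOutput,
                        params: ModelParams | None = None
                        ) -> EmpiricalObservables:
    """Empirical observables from a simulation.

    Density and current are time averages over the measurement window; dwell
    time and run length are means over completed (non-truncated) binding
    events that started after burn-in; velocity is the mean per-run speed;
    the landing rate is lambda0 times the time-averaged probability that a
    random adjacent site pair is empty (tracer landing follows from pair
    vacancy, no labelled species is simulated).
    """
    if params is None:
        params = output.params
    s = output.summary
    runs = output.runs
    done = runs[(runs["detach_cause"] != "truncated")
                & (runs["attach_time"] >= output.config.burn_in)]
    if len(done) == 0:
        raise ValueError("no completed runs in the measurement window; "
                         "increase t_end")
    tau = float(done["dwell"].mean())
    l_um = float(done["run_length_sites"].mean()) * params.a
    V = float((done["run_length_sites"] * params.a / done["dwell"]).mean())
    det = s["detach_spontaneous"] + s["detach_facilitated"]
    return EmpiricalObservables(
        rho=s["rho"],
        j=s["j"],
        tau=tau,
        V=V,
        l=l_um,
        lam=params.lambda0 * s["pair_vacancy"],
        n_runs=int(len(done)),
        facilitated_fraction=s["detach_facilitated"] / det if det else 0.0,
    )
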