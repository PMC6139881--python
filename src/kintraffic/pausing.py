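"""Detection and statistics of periods of no or slow motion.

Single-particle trajectories sampled at a fixed frame interval are scanned
with a displacement-threshold protocol: a frame-to-frame displacement below
``d_c`` is SMALL (backward motion counts as small — the 1D collapse of the
experimental off-axis angle criterion), a period of no or slow motion starts
after ``onset_run`` consecutive small displacements, tolerates isolated
large displacements, and ends after ``termination_run`` consecutive large
ones.  Because only periods lasting at least ``cutoff`` seconds are
detectable, observed counts are extrapolated below the cutoff with an
exponential (memoryless) tail fit.

An alternative detector uses the simulator's ground truth: a motor is in a
period when it is inactive or trapped in a contiguous traffic jam behind an
inactive motor; stochastically assembled jams with no inactive member are
excluded by construction.  The analytic jam-amplification estimate
N = T V / (g - V/nu), with mean gap g = 1/rho - 2 (spaced jams) or
1/rho - 1 (compact jams), closes the loop between the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DetectionConfig, ModelParams, SITE_LENGTH_UM

PERIOD_COLUMNS = ["motor_id", "start_time", "end_time", "duration",
                  "progression", "progression_inclusive", "truncated"]


@dataclass(frozen=True)
class PauseStatistics:
    """Corrected frequency and mean duration of periods of no/slow motion."""

    n_detected: int
    tau_hat: float            # fitted mean duration, s
    corrected_count: float    # extrapolated below the detection cutoff
    per_step_probability: float
    total_steps: int


def add_localization_noise(traj: pd.DataFrame, sigma_nm: float,
                           a: float = SITE_LENGTH_UM,
                           seed: int = 0) -> pd.DataFrame:
    """Add i.i.d. Gaussian localisation offsets to recorded positions.

    ``sigma_nm`` is the per-frame localisation error in nanometres,
    converted to lattice sites through the site length ``a`` (um).
    """
    if sigma_nm < 0:
        raise ValueError("sigma must be non-negative")
    out = traj.copy()
    if sigma_nm == 0 or not len(out):
        return out
    rng = np.random.default_rng(seed)
    sigma_sites = sigma_nm / (a * 1e3)
    out["position_sites"] = (out["position_sites"].to_numpy(dtype=float)
                             + rng.normal(0.0, sigma_sites, len(out)))
    return out


def _detect_single(x: np.ndarray, t: np.ndarray,
                   cfg: DetectionConfig) -> list[tuple]:
    """Run the threshold protocol on one trajectory.

    Returns (start_idx, end_idx, end_confirm_idx, truncated) tuples.  A
    displacement is SMALL when strictly below ``d_c`` and terminating when
    strictly above it; on integer lattice positions a displacement of
    exactly ``d_c`` is neither (it neither extends an onset run nor counts
    toward — nor continues — a terminating run; with continuous or noisy
    positions the distinction is measure-zero).  A period starts at the
    frame preceding the first of ``onset_run`` consecutive small
    displacements; ``end_idx`` is the frame preceding the first of
    ``termination_run`` consecutive terminating displacements (the last
    frame of slow motion, used for durations) and ``end_confirm_idx`` the
    frame at which termination is confirmed (used for the progression
    between the detection boundaries).  A period cut off by the trajectory
    end is flagged truncated with both ends at the last frame.
    """
    n = len(x)
    if n < cfg.onset_run + 1:
        raise ValueError(
            f"need at least {cfg.onset_run + 1} frames, got {n}")
    d = np.diff(x)
    small = d < cfg.d_c
    large = d > cfg.d_c
    periods = []
    k = 0
    nd = len(d)
    while k < nd:
        # onset: onset_run consecutive small displacements starting at k
        if not (small[k] and k + cfg.onset_run <= nd
                and small[k:k + cfg.onset_run].all()):
            k += 1
            continue
        start = k
        j = k + cfg.onset_run
        consecutive_large = 0
        end = None
        end_confirm = None
        truncated = False
        while j < nd:
            if large[j]:
                consecutive_large += 1
                if consecutive_large == cfg.termination_run:
                    end = j - cfg.termination_run + 1
                    end_confirm = j + 1
                    break
            else:
                consecutive_large = 0
            j += 1
        if end is None:
            end = nd  # last frame index is nd (= n-1)
            end_confirm = nd
            truncated = True
        periods.append((start, end, end_confirm, truncated))
        k = j + 1
    return periods


def detect_periods(traj: pd.DataFrame, cfg: DetectionConfig,
                   min_duration: float | None = None) -> pd.DataFrame:
    """Detect periods of no or slow motion in a trajectory table.

    ``traj`` needs columns ``motor_id``, ``time_s``, ``position_sites``
    sampled at the protocol's uniform frame interval.  Motors with fewer
    than ``onset_run + 1`` frames cannot contain a detectable period and are
    skipped.  Only periods with duration >= cutoff are reported; periods cut
    short by the trajectory end are flagged ``truncated``.

    The returned table carries two displacement measures per period:
    ``progression`` is the displacement over the slow-motion interval
    (start to last slow frame) and ``progression_inclusive`` the
    displacement between the detection boundaries, i.e. including the
    ``termination_run`` displacements that confirm the end of the period
    (for truncated periods the two coincide).
    """
    if min_duration is None:
        min_duration = cfg.cutoff
    rows = []
    for mid, g in traj.groupby("motor_id", sort=False):
        g = g.sort_values("time_s")
        t = g["time_s"].to_numpy(dtype=float)
        x = g["position_sites"].to_numpy(dtype=float)
        if len(x) < cfg.onset_run + 1:
            continue
        dt = np.diff(t)
        if len(dt) and not np.allclose(dt, cfg.frame_interval, rtol=1e-6):
            raise ValueError(
                f"motor {mid}: frames are not uniform at "
                f"{cfg.frame_interval} s")
        for s, e, ec, trunc in _detect_single(x, t, cfg):
            duration = t[e] - t[s]
            if duration < min_duration - 1e-12:
                continue
            rows.append((mid, t[s], t[e], duration, x[e] - x[s],
                         x[ec] - x[s], trunc))
    return pd.DataFrame(rows, columns=PERIOD_COLUMNS)


def exponential_tail_correct(durations, cfg: DetectionConfig,
                             total_steps: int,
                             min_tail: int = 20) -> PauseStatistics:
    """Correct detected period counts for the detection cutoff.

    The memoryless property of the exponential makes the shifted mean a
    maximum-likelihood fit of the tail: tau_hat is fitted from the excess of
    durations over ``tail_min``.  Durations measured on frame-sampled
    trajectories are integer multiples of the frame interval; for such data
    the naive mean excess underestimates the decay time, so the excess
    frame counts are fitted with their geometric MLE and converted back to
    the exponential time constant.  The count of all periods (detected plus
    those too short to detect) follows from the exponential survival at the
    cutoff, and dividing by the number of steps taken by the analysed motors
    gives the per-step probability of entering such a period.
    """
    durations = np.asarray(durations, dtype=float)
    tail = durations[durations >= cfg.tail_min - 1e-12]
    if len(tail) < min_tail:
        raise ValueError(
            f"insufficient tail sample: {len(tail)} durations >= "
            f"{cfg.tail_min} s (need {min_tail})")
    excess = tail - cfg.tail_min
    dt = cfg.frame_interval
    frames = excess / dt
    if np.allclose(frames, np.round(frames), atol=1e-6):
        ebar = float(np.mean(frames))
        if ebar <= 0:
            raise ValueError("tail has no variation above tail_min; "
                             "cannot fit an exponential")
        q = ebar / (1.0 + ebar)  # geometric MLE of the per-frame survival
        tau_hat = -dt / np.log(q)
    else:
        tau_hat = float(np.mean(excess))
    n_detected = int(len(durations))
    corrected = n_detected / np.exp(-cfg.cutoff / tau_hat)
    p = corrected / total_steps if total_steps > 0 else np.nan
    return PauseStatistics(
        n_detected=n_detected,
        tau_hat=tau_hat,
        corrected_count=float(corrected),
        per_step_probability=float(p),
        total_steps=int(total_steps),
    )


def jam_membership_periods(frames: pd.DataFrame, L: int,
                           cfg: DetectionConfig) -> pd.DataFrame:
    """Periods during which a motor is inactive or jammed behind one.

    ``frames`` is simulator output with columns ``motor_id``, ``frame``,
    ``position_sites`` (unwrapped) and ``active``.  At each frame a motor is
    IN-STATE iff it is inactive, or its front head sits exactly one site
    behind the back head of an IN-STATE motor (strict-adjacency chain toward
    the minus end).  Maximal runs of IN-STATE frames become periods; their
    duration is the time between the first and last in-state frame,
    matching the anchor convention of the displacement protocol (a single
    in-state frame has zero duration and falls below any positive cutoff).
    """
    if "active" not in frames.columns:
        raise ValueError("frames table lacks the 'active' flag column")
    in_state: dict[int, list[int]] = {}
    for k, g in frames.groupby("frame", sort=True):
        sites = g["position_sites"].to_numpy() % L
        uids = g["motor_id"].to_numpy()
        act = g["active"].to_numpy()
        site_of = dict(zip(sites, range(len(uids))))
        flags = ~act  # inactive motors are in-state
        for idx in np.flatnonzero(flags):
            s = sites[idx]
            while True:
                s = (s - 2) % L
                j = site_of.get(s)
                if j is None or flags[j]:
                    break
                flags[j] = True
        for uid in uids[flags]:
            in_state.setdefault(int(uid), []).append(int(k))
    rows = []
    dt = cfg.frame_interval
    for uid, ks in in_state.items():
        ks = np.asarray(sorted(ks))
        breaks = np.flatnonzero(np.diff(ks) > 1)
        for run in np.split(ks, breaks + 1):
            duration = (len(run) - 1) * dt
            rows.append((uid, run[0] * dt, run[-1] * dt, duration,
                         np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=PERIOD_COLUMNS)


def jam_state_frequency(frames: pd.DataFrame, L: int, cfg: DetectionConfig,
                        total_steps: int) -> PauseStatistics:
    """Cutoff-corrected frequency of ground-truth jam/inactive periods.

    Applies the same cutoff and exponential tail correction as the
    displacement protocol to the jam-membership periods.
    """
    periods = jam_membership_periods(frames, L, cfg)
    durations = periods["duration"].to_numpy()
    durations = durations[durations >= cfg.cutoff - 1e-12]
    return exponential_tail_correct(durations, cfg, total_steps)


def jam_size(T: float, params: ModelParams, rho: float,
             spacing: str = "spaced") -> float:
    """Expected number of motors caught in the jam behind one paused motor.

    Summing the geometric cascade of secondary jams that form while earlier
    ones dissolve gives N = T V / (g - V/nu) with the mean gap g = 1/rho - 2
    when jammed motors keep their two-site footprint ("spaced") or
    1/rho - 1 when they pack onto single sites ("compact").  Returns
    ``inf`` when the gap closes slower than the jam grows (g <= V/nu).
    """
    if not (0 < rho < 0.5):
        raise ValueError("rho must lie strictly inside (0, 1/2)")
    if spacing not in ("spaced", "compact"):
        raise ValueError(f"unknown spacing {spacing!r}")
    V = params.nu * (1.0 - 2.0 * rho) / (1.0 - rho)  # sites/s
    g = 1.0 / rho - (2.0 if spacing == "spaced" else 1.0)
    denom = g - V / params.nu
    if denom <= 0:
        return np.inf
    return T * V / denom


def period_probability(p_inactivation: float, N: float) -> float:
    """Per-step probability of entering a period of no or slow motion.

    One intrinsic pause is also seen by the N motors jammed behind it,
    so p = p_inactivation * (1 + N).
    """
    if p_inactivation < 0 or N < 0:
        raise ValueError("inputs must be non-negative")
    return p_inactivation * (1.0 + N)
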