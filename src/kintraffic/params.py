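"""Model parameters, unit conversions, and closed-form scalar relations.

All internal lengths are measured in lattice sites (one tubulin heterodimer,
``a`` = 8.4 nm); micrometres and nanometres appear only at I/O boundaries.
Time is in seconds throughout, so every rate carries units of s^-1.
Concentrations are in nM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import yaml

#: Tubulin heterodimer length (site length) in micrometres.
SITE_LENGTH_UM = 0.0084

#: Number of protofilaments a motor can land on in a TIRF assay
#: (roughly half of the 13 protofilaments of a microtubule).
ACCESSIBLE_PROTOFILAMENTS = 6.5


def rate_from_speed(V0: float, a: float = SITE_LENGTH_UM) -> float:
    """Convert a free-motor speed to a hopping rate, ``nu = V0 / a``.

    Parameters
    ----------
    V0 : float
        Free (uncrowded) velocity in um/s.
    a : float
        Site length in um.

    Returns
    -------
    float
        Hopping rate in s^-1.
    """
    if a <= 0:
        raise ValueError(f"site length must be positive, got a={a}")
    if V0 < 0:
        raise ValueError(f"speed must be non-negative, got V0={V0}")
    return V0 / a


def attachment_rate(omega_a: float, c: float) -> float:
    """Bulk attachment rate ``omega_A = omega_a * c`` (s^-1).

    ``omega_a`` is the per-concentration attachment rate (nM^-1 s^-1) and
    ``c`` the motor volume concentration (nM).
    """
    if omega_a < 0 or c < 0:
        raise ValueError("omega_a and c must be non-negative")
    return omega_a * c


def weak_state_fraction(omega_D: float, theta: float) -> float:
    """Fraction of the stepping cycle spent in the weakly bound (1HB) state.

    Identifying the facilitated detachment rate ``theta`` with dissociation
    from the one-head-bound state, the time fraction ``f`` spent in that
    state during an unobstructed step satisfies ``omega_D = f * theta``.
    """
    if theta == 0:
        raise ZeroDivisionError("theta must be nonzero")
    f = omega_D / theta
    if f > 1:
        warnings.warn(
            f"weak-state fraction {f:.3g} exceeds 1; omega_D > theta is "
            "inconsistent with the 1HB interpretation",
            stacklevel=2,
        )
    return f


def tracer_site_attachment_rate(
    lambda0: float,
    c0: float,
    a: float = SITE_LENGTH_UM,
    n_protofilaments: float = ACCESSIBLE_PROTOFILAMENTS,
) -> float:
    """Per-site, per-concentration attachment rate of labelled tracer motors.

    Converts a landing rate ``lambda0`` (um^-1 s^-1, measured per length of
    microtubule at tracer concentration ``c0`` in nM) into a per-binding-site
    rate in nM^-1 s^-1, assuming landings are distributed over
    ``n_protofilaments`` accessible protofilaments.
    """
    if c0 <= 0:
        raise ValueError("tracer reference concentration must be positive")
    return lambda0 * a / (n_protofilaments * c0)


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of the dimer lattice-gas model.

    Attributes
    ----------
    nu : float
        Hopping rate toward the plus end (s^-1).
    omega_a : float
        Attachment rate per concentration (nM^-1 s^-1).
    c : float
        Motor volume concentration (nM).
    omega_D : float
        Spontaneous detachment rate (s^-1).
    theta : float
        Facilitated (motor-induced) detachment rate of the rear motor of an
        adjacent pair (s^-1).
    lambda0 : float
        Landing-rate normalisation for labelled tracers (um^-1 s^-1).
    c0_tracer : float
        Tracer reference concentration (nM).
    a : float
        Site length (um).
    landing_variant : str
        ``"two_site"`` (a dimer needs two adjacent empty sites to land) or
        ``"one_site"`` (mean-field-only variant where a single empty site
        suffices).
    """

    nu: float = 79.0
    omega_a: float = 0.054
    c: float = 0.0
    omega_D: float = 0.53
    theta: float = 2.4
    lambda0: float = 1.8e-2
    c0_tracer: float = 0.005
    a: float = SITE_LENGTH_UM
    landing_variant: str = "two_site"

    def __post_init__(self) -> None:
        for name in ("nu", "omega_a", "c", "omega_D", "theta", "lambda0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.a <= 0:
            raise ValueError("site length a must be positive")
        if self.landing_variant not in ("two_site", "one_site"):
            raise ValueError(
                f"unknown landing_variant {self.landing_variant!r}"
            )

    @property
    def omega_A(self) -> float:
        """Attachment rate omega_A = omega_a * c (s^-1)."""
        return self.omega_a * self.c

    @property
    def V0(self) -> float:
        """Free velocity V0 = nu * a (um/s)."""
        return self.nu * self.a

    def at_concentration(self, c: float) -> "ModelParams":
        """Return a copy of the parameters at concentration ``c`` (nM)."""
        return replace(self, c=c)

    def weak_state_fraction(self) -> float:
        return weak_state_fraction(self.omega_D, self.theta)


#: The parameter set extracted from the kinesin-1 concentration-series data
#: (nu and omega_D anchored at low concentration, omega_a and theta from the
#: global fit).
KINESIN1_PARAMS = ModelParams()


@dataclass(frozen=True)
class PausingParams:
    """Two-state (active/inactive) switching of bound motors.

    Inactive motors cannot step but remain bound, block other motors, and
    keep both detachment channels.
    """

    r_inactivation: float = 0.316  # 0.004 * nu at nu = 79/s
    r_activation: float = 1.0 / 0.12
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.r_inactivation < 0 or self.r_activation < 0:
            raise ValueError("switching rates must be non-negative")

    @classmethod
    def disabled(cls) -> "PausingParams":
        return cls(r_inactivation=0.0, r_activation=0.0, enabled=False)

    @classmethod
    def from_step_probability(
        cls, p_inactivation: float, T_pause: float, nu: float
    ) -> "PausingParams":
        """Build from the per-step inactivation probability and the mean
        pause duration: ``r_in = p * nu``, ``r_act = 1 / T``."""
        if T_pause <= 0:
            raise ValueError("T_pause must be positive")
        return cls(r_inactivation=p_inactivation * nu,
                   r_activation=1.0 / T_pause)

    def p_inactivation(self, nu: float) -> float:
        """Per-step inactivation probability r_inactivation / nu."""
        return self.r_inactivation / nu

    @property
    def T_pause(self) -> float:
        """Mean pause duration 1 / r_activation (s)."""
        return 1.0 / self.r_activation


@dataclass(frozen=True)
class DetectionConfig:
    """Frame-based threshold protocol for periods of no or slow motion.

    A frame-to-frame displacement is SMALL when it is strictly below the
    threshold ``d_c`` (backward motion therefore counts as small, the 1D
    collapse of the experimental off-axis angle criterion).  A period starts
    after ``onset_run`` consecutive small displacements and ends after
    ``termination_run`` consecutive large ones; a single large displacement
    inside a period is tolerated.  Only periods lasting at least ``cutoff``
    seconds are detectable, which is why ``cutoff`` must equal
    ``onset_run * frame_interval``.
    """

    frame_interval: float = 0.1
    d_c: float = 2.0  # lattice sites
    noise_sigma: float = 0.0  # localisation noise s.d., nm
    cutoff: float = 0.3
    tail_min: float = 0.5
    onset_run: int = 3
    termination_run: int = 2

    def __post_init__(self) -> None:
        if self.d_c <= 0:
            raise ValueError("d_c must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if abs(self.cutoff - self.onset_run * self.frame_interval) > 1e-12:
            raise ValueError(
                "cutoff must equal onset_run * frame_interval "
                f"({self.onset_run} * {self.frame_interval})"
            )
        if self.tail_min < self.cutoff:
            raise ValueError("tail_min must be >= cutoff")

    @classmethod
    def from_nm(cls, d_c_nm: float, a: float = SITE_LENGTH_UM,
                **kwargs) -> "DetectionConfig":
        """Build with the displacement threshold given in nanometres."""
        return cls(d_c=d_c_nm / (a * 1e3), **kwargs)


def _pick(section: dict, cls, **overrides):
    known = {f for f in cls.__dataclass_fields__}
    kwargs = {k: v for k, v in section.items() if k in known}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return cls(**kwargs)


def load_config(path, **overrides) -> dict:
    """Read a YAML config with sections model/pausing/detection/simulation/fit.

    Returns a dict with ``ModelParams`` under ``"model"``, ``PausingParams``
    under ``"pausing"``, ``DetectionConfig`` under ``"detection"``, and the
    raw ``simulation``/``fit`` sections (consumed by their modules).
    Keyword overrides (e.g. from CLI flags) take precedence over the file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model_sec = dict(raw.get("model", {}))
    if "c_pM" in model_sec:  # picomolar input converted at parse time
        model_sec["c"] = model_sec.pop("c_pM") / 1e3
    return {
        "model": _pick(model_sec, ModelParams,
                       **overrides.get("model", {})),
        "pausing": _pick(raw.get("pausing", {}), PausingParams,
                         **overrides.get("pausing", {})),
        "detection": _pick(raw.get("detection", {}), DetectionConfig,
                           **overrides.get("detection", {})),
        "simulation": dict(raw.get("simulation", {})),
        "fit": dict(raw.get("fit", {})),
    }
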