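"""Explicit ring-lattice state and event-channel enumeration.

This is the reference (readable, unoptimised) description of the stochastic
dynamics: dimeric motors on a periodic 1D lattice with exclusion, hopping,
Langmuir attachment/detachment, facilitated detachment of the rear motor of
an adjacent pair, and optional active/inactive switching.  The exact
master-equation oracle enumerates configurations through this module, and
the fast simulation kernel is validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import ModelParams, PausingParams

EMPTY = -1


@dataclass
class Motor:
    front_site: int
    active: bool = True
    labeled: bool = False
    attach_time: float = 0.0
    attach_site: int = 0
    steps_taken: int = 0


@dataclass
class LatticeState:
    """Ring occupancy plus per-motor registry.

    Each motor is a rigid dimer occupying ``front_site`` and the site behind
    it (``front_site - 1`` mod L).  The occupancy array stores the motor id
    at both sites; ``is_front`` distinguishes the two heads.
    """

    L: int
    motors: dict = field(default_factory=dict)
    _next_id: int = 0

    def __post_init__(self):
        self._rebuild_occupancy()

    def _rebuild_occupancy(self):
        self.occupancy = [EMPTY] * self.L
        self.is_front = [False] * self.L
        for mid, m in self.motors.items():
            f = m.front_site % self.L
            b = (f - 1) % self.L
            if self.occupancy[f] != EMPTY or self.occupancy[b] != EMPTY:
                raise ValueError("overlapping motors in registry")
            self.occupancy[f] = mid
            self.occupancy[b] = mid
            self.is_front[f] = True

    @classmethod
    def from_front_sites(cls, L: int, front_sites, active=None) -> "LatticeState":
        """Build a state with motors whose front heads sit at ``front_sites``."""
        motors = {}
        for k, f in enumerate(front_sites):
            is_active = True if active is None else bool(active[k])
            motors[k] = Motor(front_site=f % L, active=is_active,
                              attach_site=f % L)
        state = cls(L=L, motors=motors)
        state._next_id = len(motors)
        return state

    def add_motor(self, front_site: int, time: float = 0.0,
                  active: bool = True) -> int:
        mid = self._next_id
        self._next_id += 1
        f = front_site % self.L
        b = (f - 1) % self.L
        if self.occupancy[f] != EMPTY or self.occupancy[b] != EMPTY:
            raise ValueError(f"cannot attach at occupied pair ({b}, {f})")
        self.motors[mid] = Motor(front_site=f, active=active,
                                 attach_time=time, attach_site=f)
        self.occupancy[f] = mid
        self.occupancy[b] = mid
        self.is_front[f] = True
        return mid

    def remove_motor(self, mid: int) -> Motor:
        m = self.motors.pop(mid)
        f = m.front_site
        b = (f - 1) % self.L
        self.occupancy[f] = EMPTY
        self.occupancy[b] = EMPTY
        self.is_front[f] = False
        return m

    def hop(self, mid: int) -> None:
        m = self.motors[mid]
        f = m.front_site
        t = (f + 1) % self.L
        if self.occupancy[t] != EMPTY:
            raise ValueError(f"target site {t} occupied")
        b = (f - 1) % self.L
        self.occupancy[b] = EMPTY
        self.occupancy[t] = mid
        self.is_front[f] = False
        self.is_front[t] = True
        m.front_site = t
        m.steps_taken += 1

    def can_hop(self, mid: int) -> bool:
        m = self.motors[mid]
        return m.active and self.occupancy[(m.front_site + 1) % self.L] == EMPTY

    def is_rear_of_pair(self, mid: int) -> bool:
        """True when another motor's back head sits right ahead of this
        motor's front head (the facilitated-detachment geometry)."""
        m = self.motors[mid]
        nxt = (m.front_site + 1) % self.L
        occ = self.occupancy[nxt]
        return occ != EMPTY and not self.is_front[nxt]

    def empty_pairs(self) -> list:
        """Front sites i such that sites (i-1, i) are both empty."""
        return [i for i in range(self.L)
                if self.occupancy[i] == EMPTY
                and self.occupancy[(i - 1) % self.L] == EMPTY]

    def check_consistency(self) -> None:
        """Verify dimer integrity and registry/occupancy agreement."""
        seen = {}
        for i, mid in enumerate(self.occupancy):
            if mid != EMPTY:
                seen.setdefault(mid, []).append(i)
        if set(seen) != set(self.motors):
            raise AssertionError("registry and occupancy disagree")
        for mid, sites in seen.items():
            if len(sites) != 2:
                raise AssertionError(f"motor {mid} occupies {len(sites)} sites")
            f = self.motors[mid].front_site
            b = (f - 1) % self.L
            if sorted(sites) != sorted({f, b}):
                raise AssertionError(f"motor {mid} heads misplaced")
            if not self.is_front[f] or self.is_front[b]:
                raise AssertionError(f"motor {mid} head flags wrong")

    def key(self) -> tuple:
        """Canonical hashable configuration (front sites + activity)."""
        return tuple(sorted((m.front_site, m.active)
                            for m in self.motors.values()))


@dataclass(frozen=True)
class EventChannel:
    kind: str        # hop | attach | detach_spontaneous | detach_facilitated
    #                # | inactivate | activate
    target: int      # motor id, or front site for attach
    rate: float


def enumerate_event_rates(state: LatticeState, params: ModelParams,
                          pausing: PausingParams | None = None
                          ) -> list[EventChannel]:
    """All event channels of the current configuration with their rates.

    Channels: hop at rate nu per active motor with an empty target site;
    attachment at rate omega_A per adjacent empty site pair; spontaneous
    detachment at omega_D per bound motor; facilitated detachment at theta
    per motor whose front head has another motor's back head directly ahead
    (applied regardless of either motor's activity); inactivation at
    r_inactivation per bound active motor and activation at r_activation per
    inactive motor when pausing is enabled.
    """
    state.check_consistency()
    if pausing is None:
        pausing = PausingParams.disabled()
    channels: list[EventChannel] = []
    for mid, m in state.motors.items():
        if params.nu > 0 and state.can_hop(mid):
            channels.append(EventChannel("hop", mid, params.nu))
        if params.omega_D > 0:
            channels.append(EventChannel("detach_spontaneous", mid,
                                         params.omega_D))
        if params.theta > 0 and state.is_rear_of_pair(mid):
            channels.append(EventChannel("detach_facilitated", mid,
                                         params.theta))
        if pausing.enabled:
            if m.active and pausing.r_inactivation > 0:
                channels.append(EventChannel("inactivate", mid,
                                             pausing.r_inactivation))
            if not m.active and pausing.r_activation > 0:
                channels.append(EventChannel("activate", mid,
                                             pausing.r_activation))
    if params.omega_A > 0:
        for i in state.empty_pairs():
            channels.append(EventChannel("attach", i, params.omega_A))
    return channels


def apply_event(state: LatticeState, channel: EventChannel,
                time: float = 0.0) -> None:
    """Apply one event channel in place."""
    if channel.kind == "hop":
        state.hop(channel.target)
    elif channel.kind == "attach":
        state.add_motor(channel.target, time=time)
    elif channel.kind in ("detach_spontaneous", "detach_facilitated"):
        state.remove_motor(channel.target)
    elif channel.kind == "inactivate":
        state.motors[channel.target].active = False
    elif channel.kind == "activate":
        state.motors[channel.target].active = True
    else:
        raise ValueError(f"unknown event kind {channel.kind!r}")
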