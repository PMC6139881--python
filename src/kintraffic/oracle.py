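"""Exact master-equation solution on small rings.

Enumerates every configuration of dimers (optionally with active/inactive
flags) on a ring of up to ~10 sites, builds the full continuous-time Markov
generator from the same event-channel enumeration used to describe the
dynamics, and solves the stationary linear system.  Serves as the
independent oracle for the stochastic simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy.linalg import null_space

from .lattice import LatticeState, apply_event, enumerate_event_rates
from .params import ModelParams, PausingParams

MAX_ORACLE_SITES = 10


@dataclass(frozen=True)
class OracleResult:
    """Exact stationary observables of the small-ring model."""

    L: int
    states: list                 # canonical configuration keys
    distribution: np.ndarray     # stationary probabilities, same order
    rho: float                   # mean front-head site fraction
    j: float                     # current, motors per site (bond) per second
    detach_spontaneous_flux: float  # events per second (whole ring)
    detach_facilitated_flux: float
    facilitated_fraction: float  # share of detachments that are facilitated


def _dimer_placements(L: int):
    """All ways to place non-overlapping dimers (front-head site sets)."""
    def overlaps(fronts):
        occupied = set()
        for f in fronts:
            sites = {f, (f - 1) % L}
            if occupied & sites:
                return True
            occupied |= sites
        return False

    yield ()
    for k in range(1, L // 2 + 1):
        for fronts in combinations(range(L), k):
            if not overlaps(fronts):
                yield fronts


def enumerate_configurations(L: int, with_activity: bool):
    """Canonical keys of every configuration of the ring."""
    keys = []
    for fronts in _dimer_placements(L):
        if with_activity and fronts:
            for flags in product((True, False), repeat=len(fronts)):
                keys.append(tuple(sorted(zip(fronts, flags))))
        else:
            keys.append(tuple(sorted((f, True) for f in fronts)))
    return keys


def _state_from_key(L: int, key) -> LatticeState:
    fronts = [f for f, _ in key]
    active = [a for _, a in key]
    return LatticeState.from_front_sites(L, fronts, active=active)


def exact_small_lattice_oracle(params: ModelParams,
                               pausing: PausingParams | None = None,
                               L: int = 6,
                               initial_key: tuple | None = None
                               ) -> OracleResult:
    """Solve the stationary master equation exactly on a small ring.

    When ``initial_key`` is given, only the configurations reachable from it
    are enumerated (useful for conserved sectors, e.g. a single motor with
    all attachment/detachment switched off); otherwise the full
    configuration space is used.
    """
    if L > MAX_ORACLE_SITES:
        raise ValueError(f"state space too large for L={L} "
                         f"(max {MAX_ORACLE_SITES})")
    if pausing is None:
        pausing = PausingParams.disabled()
    with_activity = pausing.enabled

    if initial_key is None:
        keys = enumerate_configurations(L, with_activity)
    else:
        keys = _reachable_keys(L, initial_key, params, pausing)
    index = {k: i for i, k in enumerate(keys)}
    n = len(keys)

    Q = np.zeros((n, n))
    hop_flux_terms = np.zeros(n)      # nu * (# hoppable motors), per state
    spont_terms = np.zeros(n)
    fac_terms = np.zeros(n)
    front_counts = np.array([len(k) for k in keys], dtype=float)

    for i, key in enumerate(keys):
        state = _state_from_key(L, key)
        for ch in enumerate_event_rates(state, params, pausing):
            succ = _state_from_key(L, key)
            apply_event(succ, ch)
            jdx = index[succ.key()]
            Q[i, jdx] += ch.rate
            Q[i, i] -= ch.rate
            if ch.kind == "hop":
                hop_flux_terms[i] += ch.rate
            elif ch.kind == "detach_spontaneous":
                spont_terms[i] += ch.rate
            elif ch.kind == "detach_facilitated":
                fac_terms[i] += ch.rate

    ns = null_space(Q.T)
    if ns.shape[1] == 0:
        raise RuntimeError("no stationary distribution found")
    pi = ns[:, 0]
    if pi.sum() < 0:
        pi = -pi
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()

    rho = float(front_counts @ pi / L)
    j = float(hop_flux_terms @ pi / L)
    spont = float(spont_terms @ pi)
    fac = float(fac_terms @ pi)
    total_detach = spont + fac
    return OracleResult(
        L=L,
        states=keys,
        distribution=pi,
        rho=rho,
        j=j,
        detach_spontaneous_flux=spont,
        detach_facilitated_flux=fac,
        facilitated_fraction=fac / total_detach if total_detach > 0 else 0.0,
    )


def _reachable_keys(L: int, initial_key, params, pausing):
    seen = {initial_key}
    frontier = [initial_key]
    while frontier:
        key = frontier.pop()
        state = _state_from_key(L, key)
        for ch in enumerate_event_rates(state, params, pausing):
            succ = _state_from_key(L, key)
            apply_event(succ, ch)
            k2 = succ.key()
            if k2 not in seen:
                seen.add(k2)
                frontier.append(k2)
    return sorted(seen)
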