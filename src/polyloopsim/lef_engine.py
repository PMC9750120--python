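"""Stochastic 1D dynamics of loop-extruding factors (LEFs) on the monomer lattice.

A LEF is a pair of "legs" that bind chromatin on adjacent monomers and
translocate outward, enlarging a loop, until the LEF unbinds.  Legs can
be stalled by boundary elements (direction-dependently, with a pass
probability per attempt) and by collisions with other LEFs' legs, which
are either impenetrable (cohesin-like) or phantom (Z-loop, legs cross
freely).  Kinetics are simulated as an exact continuous-time Markov
chain (Gillespie sampling) over the current event set:

* each unbound LEF binds at rate ``k_bind``,
* each bound LEF unbinds at rate ``k_unbind`` (both legs release, the
  loop dissolves instantly),
* each mobile leg attempts an outward step at rate
  ``velocity_kb_per_min / monomer_size_kb`` (a stalled leg simply
  retries at the same rate).

The mean number of simultaneously bound LEFs is the user-facing density
parameter ``n_lef_target``: with a pool of ``2 * n_lef_target`` LEFs and
``k_bind = k_unbind * n_target / (pool - n_target)`` every LEF is bound
half the time, so the stationary mean bound count equals the target.

For single-LEF systems on small lattices, :func:`exact_stationary_oracle`
enumerates the full state space and returns the exact stationary
distribution of the same kinetics — the independent reference the event
engine is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .genome_config import ConfigError, GenomeAnnotation, SimulationParameters

EVENT_KINDS = (
    "bind",
    "unbind",
    "step",
    "stall_boundary",
    "stall_collision",
    "pass_boundary",
    "cross_phantom",
    "bind_rejected",
)

#: Step-attempt outcomes of :func:`attempt_leg_step`.
OUTCOMES = (
    "moved",
    "stalled_boundary",
    "stalled_collision",
    "passed_boundary",
    "crossed_phantom",
)

_OUTCOME_TO_EVENT = {
    "moved": "step",
    "stalled_boundary": "stall_boundary",
    "stalled_collision": "stall_collision",
    "passed_boundary": "pass_boundary",
    "crossed_phantom": "cross_phantom",
}


@dataclass
class Event:
    time_min: float
    kind: str
    lef_id: int
    leg: str  # "left" / "right" / "" for bind/unbind records
    position: int


EventLog = list


def write_event_log(log: Iterable[Event], path) -> None:
    """Stream an event log to tab-separated text (debugging aid)."""
    with open(path, "w") as fh:
        fh.write("time_min\tevent\tlef_id\tleg\tmonomer\n")
        for ev in log:
            fh.write(
                f"{ev.time_min:.6f}\t{ev.kind}\t{ev.lef_id}\t{ev.leg}\t{ev.position}\n"
            )


@dataclass
class LEF:
    bound: bool = False
    left_leg: int = -1
    right_leg: int = -1
    left_mobile: bool = True
    right_mobile: bool = True


class LEFSystem:
    """State of the loop-extruder population on an annotated lattice.

    The LEF pool has fixed size ``2 * n_lef_target`` (bound + unbound);
    ``occ`` counts legs per monomer (can exceed 1 in phantom mode).
    ``stats`` holds cumulative event counts and the time integrals of
    the bound-LEF count and total loop span, from which time-averaged
    quantities (mean loop length, bound fraction) are derived.
    """

    def __init__(
        self,
        params: SimulationParameters,
        genome: GenomeAnnotation,
        seed: int | np.random.SeedSequence,
        pool_size: int | None = None,
        k_bind: float | None = None,
    ) -> None:
        """``pool_size``/``k_bind`` override the density parameterization,
        e.g. a pool of exactly one LEF with an explicit binding rate for
        comparison against the single-LEF oracle."""
        if genome.n_monomers != params.n_monomers:
            raise ConfigError("genome annotation does not match chain length")
        if params.n_lef_target > genome.n_monomers // 2:
            raise ConfigError(
                f"n_lef_target={params.n_lef_target} cannot fit on "
                f"{genome.n_monomers} monomers (needs 2 monomers per bound LEF)"
            )
        self.params = params
        self.genome = genome
        self.n_monomers = genome.n_monomers
        n_t = params.n_lef_target
        self.pool_size = 2 * n_t if pool_size is None else pool_size
        self.k_unbind = params.unbind_rate_per_min
        # stationary mean bound count = pool * k_bind/(k_bind+k_unbind) = n_t
        if k_bind is not None:
            self.k_bind = k_bind
        else:
            self.k_bind = (
                self.k_unbind * n_t / (self.pool_size - n_t) if n_t > 0 else 0.0
            )
        self.step_rate = params.step_rate_per_min
        self.asymmetric = params.extrusion_mode == "asymmetric"
        self.phantom = params.collision_mode == "phantom"
        self.loading_mode = params.rebind_mode == "loading_sites"
        if self.loading_mode and not genome.loading_sites:
            raise ConfigError("rebind_mode=loading_sites but no loading sites given")
        self.perm_right, self.perm_left = genome.passage_probabilities()
        self.lefs = [LEF() for _ in range(self.pool_size)]
        self.occ = np.zeros(self.n_monomers, dtype=np.int64)
        self.bound_ids: list[int] = []
        self.unbound_ids: list[int] = list(range(self.pool_size))
        self.total_span = 0  # sum of (right-left) over bound LEFs, monomers
        self.time_min = 0.0
        self.rng = np.random.default_rng(seed)
        self.stats = {
            "bound_time": 0.0,  # integral of n_bound dt
            "span_time": 0.0,  # integral of total_span dt (monomer*min)
            "elapsed": 0.0,
            "n_bind": 0,
            "n_unbind": 0,
            "n_step": 0,
            "n_stall_boundary": 0,
            "n_stall_collision": 0,
            "n_pass_boundary": 0,
            "n_cross_phantom": 0,
            "n_bind_rejected": 0,
        }

    # -- derived -------------------------------------------------------
    @property
    def n_bound(self) -> int:
        return len(self.bound_ids)

    def loop_bonds(self) -> set[tuple[int, int]]:
        return {
            (self.lefs[i].left_leg, self.lefs[i].right_leg) for i in self.bound_ids
        }

    def mean_loop_length_kb(self) -> float:
        """Time-averaged loop length per bound LEF, in kb."""
        if self.stats["bound_time"] == 0:
            return float("nan")
        return (
            self.stats["span_time"]
            / self.stats["bound_time"]
            * self.params.monomer_size_kb
        )

    # -- binding -------------------------------------------------------
    def _draw_uniform_pair(self) -> int | None:
        """Uniform draw among admissible adjacent pairs (i, i+1); None if none."""
        n = self.n_monomers
        if self.phantom:
            return int(self.rng.integers(0, n - 1))
        # rejection sampling is uniform over the admissible subset
        for _ in range(64):
            i = int(self.rng.integers(0, n - 1))
            if self.occ[i] == 0 and self.occ[i + 1] == 0:
                return i
        free = np.flatnonzero((self.occ[:-1] == 0) & (self.occ[1:] == 0))
        if free.size == 0:
            return None
        return int(free[self.rng.integers(free.size)])

    def _draw_loading_pair(self) -> int | None:
        sites = self.genome.loading_sites
        s = sites[int(self.rng.integers(len(sites)))]
        if s + 1 >= self.n_monomers:
            return None
        if not self.phantom and (self.occ[s] > 0 or self.occ[s + 1] > 0):
            return None
        return s

    def _bind(self, lef_id: int) -> bool:
        """Attempt to bind an unbound LEF; returns True on success."""
        lef = self.lefs[lef_id]
        if lef.bound:
            raise ConfigError(f"LEF {lef_id} is already bound")
        i = self._draw_loading_pair() if self.loading_mode else self._draw_uniform_pair()
        if i is None:
            self.stats["n_bind_rejected"] += 1
            return False
        lef.bound = True
        lef.left_leg = i
        lef.right_leg = i + 1
        if self.asymmetric:
            left_is_mobile = bool(self.rng.random() < 0.5)
            lef.left_mobile = left_is_mobile
            lef.right_mobile = not left_is_mobile
        else:
            lef.left_mobile = True
            lef.right_mobile = True
        self.occ[i] += 1
        self.occ[i + 1] += 1
        self.unbound_ids.remove(lef_id)
        self.bound_ids.append(lef_id)
        self.total_span += 1
        self.stats["n_bind"] += 1
        return True

    def _unbind(self, lef_id: int) -> None:
        lef = self.lefs[lef_id]
        self.occ[lef.left_leg] -= 1
        self.occ[lef.right_leg] -= 1
        self.total_span -= lef.right_leg - lef.left_leg
        lef.bound = False
        lef.left_leg = -1
        lef.right_leg = -1
        lef.left_mobile = True
        lef.right_mobile = True
        self.bound_ids.remove(lef_id)
        self.unbound_ids.append(lef_id)
        self.stats["n_unbind"] += 1


def init_population(
    params: SimulationParameters,
    genome: GenomeAnnotation,
    seed: int | np.random.SeedSequence,
) -> LEFSystem:
    """Create a reproducible LEF population; all LEFs start unbound."""
    return LEFSystem(params, genome, seed)


def bind_lef(system: LEFSystem, lef_id: int, log: EventLog | None = None) -> bool:
    """Binding attempt for one unbound LEF; logs a rejection if no site admits it."""
    ok = system._bind(lef_id)
    if log is not None:
        lef = system.lefs[lef_id]
        if ok:
            log.append(Event(system.time_min, "bind", lef_id, "", lef.left_leg))
        else:
            log.append(Event(system.time_min, "bind_rejected", lef_id, "", -1))
    return ok


def attempt_leg_step(system: LEFSystem, lef_id: int, leg: str) -> str:
    """One outward translocation attempt for a leg; returns the outcome.

    Outcomes: ``moved``, ``stalled_boundary`` (chain end or blocking
    boundary won the permeability draw), ``passed_boundary``,
    ``stalled_collision`` (impenetrable mode), ``crossed_phantom``.
    """
    lef = system.lefs[lef_id]
    if not lef.bound:
        raise ConfigError(f"attempt_leg_step on unbound LEF {lef_id}")
    if leg == "left":
        if not lef.left_mobile:
            raise ConfigError("left leg is not mobile")
        cur, direction = lef.left_leg, -1
    elif leg == "right":
        if not lef.right_mobile:
            raise ConfigError("right leg is not mobile")
        cur, direction = lef.right_leg, +1
    else:
        raise ConfigError(f"leg must be 'left' or 'right', got {leg!r}")
    target = cur + direction
    if target < 0 or target >= system.n_monomers:
        system.stats["n_stall_boundary"] += 1
        return "stalled_boundary"
    perm = (
        system.perm_left[target] if direction < 0 else system.perm_right[target]
    )
    passed_boundary = False
    if perm < 1.0:
        if system.rng.random() >= perm:
            system.stats["n_stall_boundary"] += 1
            return "stalled_boundary"
        passed_boundary = True
    crossed = False
    if system.occ[target] > 0:
        if not system.phantom:
            system.stats["n_stall_collision"] += 1
            return "stalled_collision"
        crossed = True
    system.occ[cur] -= 1
    system.occ[target] += 1
    if leg == "left":
        lef.left_leg = target
    else:
        lef.right_leg = target
    system.total_span += 1
    if crossed:
        system.stats["n_cross_phantom"] += 1
        return "crossed_phantom"
    if passed_boundary:
        system.stats["n_pass_boundary"] += 1
        return "passed_boundary"
    system.stats["n_step"] += 1
    return "moved"


def advance_1d(
    system: LEFSystem,
    duration_min: float,
    record: bool = False,
    observer: Callable[[LEFSystem, float], None] | None = None,
) -> tuple[LEFSystem, EventLog]:
    """Advance the 1D kinetics by ``duration_min`` with Gillespie sampling.

    ``observer(system, dt)``, if given, is called with every holding
    time ``dt`` *before* the next event is applied, i.e. while the
    current state is still in force — this yields exact time-weighted
    state statistics without logging every event.  With ``record=True``
    every event (including stalled attempts and rejected bindings) is
    appended to the returned log.
    """
    if duration_min <= 0:
        raise ConfigError(f"duration_min must be > 0, got {duration_min}")
    log: EventLog = []
    t = system.time_min
    t_end = t + duration_min
    legs_per_lef = 1 if system.asymmetric else 2
    rng = system.rng
    stats = system.stats

    def _dwell(dt: float) -> None:
        stats["bound_time"] += system.n_bound * dt
        stats["span_time"] += system.total_span * dt
        stats["elapsed"] += dt
        if observer is not None:
            observer(system, dt)

    while True:
        nb = len(system.bound_ids)
        nu = len(system.unbound_ids)
        r_bind = nu * system.k_bind
        r_unbind = nb * system.k_unbind
        r_step = nb * legs_per_lef * system.step_rate
        total = r_bind + r_unbind + r_step
        if total <= 0.0:
            _dwell(t_end - t)
            t = t_end
            break
        dt = rng.exponential(1.0 / total)
        if t + dt >= t_end:
            _dwell(t_end - t)
            t = t_end
            break
        _dwell(dt)
        t += dt
        system.time_min = t
        u = rng.random() * total
        if u < r_bind:
            lef_id = system.unbound_ids[int(rng.integers(nu))]
            bind_lef(system, lef_id, log if record else None)
        elif u < r_bind + r_unbind:
            lef_id = system.bound_ids[int(rng.integers(nb))]
            pos = system.lefs[lef_id].left_leg
            system._unbind(lef_id)
            if record:
                log.append(Event(t, "unbind", lef_id, "", pos))
        else:
            lef_id = system.bound_ids[int(rng.integers(nb))]
            lef = system.lefs[lef_id]
            if system.asymmetric:
                leg = "left" if lef.left_mobile else "right"
            else:
                leg = "left" if rng.random() < 0.5 else "right"
            outcome = attempt_leg_step(system, lef_id, leg)
            if record:
                pos = lef.left_leg if leg == "left" else lef.right_leg
                log.append(Event(t, _OUTCOME_TO_EVENT[outcome], lef_id, leg, pos))
    system.time_min = t_end
    return system, log


def occupancy_accumulate(system: LEFSystem, accumulator: np.ndarray) -> np.ndarray:
    """Add the current leg occupancy (legs per monomer) to a count vector."""
    if accumulator.shape != (system.n_monomers,):
        raise ConfigError(
            f"accumulator length {accumulator.shape} != n_monomers "
            f"({system.n_monomers},)"
        )
    accumulator += system.occ
    return accumulator


# ---------------------------------------------------------------------------
# Exact single-LEF stationary-distribution oracle
# ---------------------------------------------------------------------------

State = tuple


def state_of(system: LEFSystem) -> State:
    """Canonical state tuple of a single-LEF system (for oracle comparison)."""
    bound = [system.lefs[i] for i in system.bound_ids]
    if not bound:
        return ("U",)
    (lef,) = bound
    if system.asymmetric:
        return (lef.left_leg, lef.right_leg, "L" if lef.left_mobile else "R")
    return (lef.left_leg, lef.right_leg)


def enumerate_states(n_sites: int, asymmetric: bool) -> list[State]:
    states: list[State] = [("U",)]
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            if asymmetric:
                states.append((i, j, "L"))
                states.append((i, j, "R"))
            else:
                states.append((i, j))
    return states


def exact_stationary_oracle(
    n_sites: int,
    genome: GenomeAnnotation | None,
    k_bind: float,
    k_unbind: float,
    step_rate: float,
    extrusion_mode: str = "symmetric",
    rebind_mode: str = "uniform",
) -> tuple[list[State], np.ndarray]:
    """Exact stationary distribution of a single LEF on a small lattice.

    Enumerates the unbound state plus every leg pair (i, j), i < j
    (times the mobile-leg label in asymmetric mode), builds the exact
    transition-rate matrix of the same kinetics the event engine
    implements, and solves for its stationary distribution.  Boundary
    permeability enters as an effective passage rate
    ``step_rate * permeability`` (a per-attempt pass probability thinned
    from the attempt rate); stalled attempts are self-loops and do not
    affect the stationary law.  Collision mode is irrelevant at one LEF.
    """
    if n_sites > 12:
        raise ConfigError("exact oracle supports n_sites <= 12")
    asymmetric = extrusion_mode == "asymmetric"
    if genome is None:
        genome = GenomeAnnotation(n_monomers=n_sites)
    if genome.n_monomers != n_sites:
        raise ConfigError("genome size does not match n_sites")
    perm_right, perm_left = genome.passage_probabilities()
    states = enumerate_states(n_sites, asymmetric)
    index = {s: k for k, s in enumerate(states)}
    m = len(states)
    Q = np.zeros((m, m))

    if rebind_mode == "loading_sites":
        anchors = [s for s in genome.loading_sites if s + 1 < n_sites]
    else:
        anchors = list(range(n_sites - 1))
    if not anchors:
        raise ConfigError("no admissible binding pair on this lattice")
    per_pair = k_bind / len(anchors)
    u = index[("U",)]
    for a in anchors:
        if asymmetric:
            Q[u, index[(a, a + 1, "L")]] += per_pair / 2.0
            Q[u, index[(a, a + 1, "R")]] += per_pair / 2.0
        else:
            Q[u, index[(a, a + 1)]] += per_pair

    for s in states:
        if s == ("U",):
            continue
        k = index[s]
        i, j = s[0], s[1]
        Q[k, u] += k_unbind
        left_mobile = (not asymmetric) or s[2] == "L"
        right_mobile = (not asymmetric) or s[2] == "R"
        if left_mobile and i - 1 >= 0:
            rate = step_rate * perm_left[i - 1]
            if rate > 0:
                tgt = (i - 1, j, s[2]) if asymmetric else (i - 1, j)
                Q[k, index[tgt]] += rate
        if right_mobile and j + 1 < n_sites:
            rate = step_rate * perm_right[j + 1]
            if rate > 0:
                tgt = (i, j + 1, s[2]) if asymmetric else (i, j + 1)
                Q[k, index[tgt]] += rate

    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # solve pi Q = 0, sum(pi) = 1
    A = np.vstack([Q.T, np.ones(m)])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return states, pi
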