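"""3D dynamics of the coarse-grained chromosome chain.

The chromosome is an off-lattice bead-spring homopolymer: harmonic
bonds between consecutive monomers, a bending penalty
``bend_k * (1 - cos theta)`` per triplet, and hard-core excluded
volume.  Loops created by the 1D extrusion engine enter the 3D model as
transient harmonic bonds between the two leg monomers; when a leg
advances, the bond is momentarily stretched and the following Metropolis
sweeps contract it, so beads never teleport.

Time coupling: one Monte Carlo sweep represents ``1 / sweeps_per_min``
minutes of real time.  ``run_coupled`` alternates Gillespie extrusion
kinetics over a short coupling interval with the proportional number of
sweeps, and emits conformation snapshots at the configured sampling
period after a pure-polymer burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.spatial.distance import pdist

from . import _mc
from .genome_config import ConfigError, GenomeAnnotation, SimulationParameters
from .lef_engine import LEFSystem, advance_1d, init_population


@dataclass
class EnergyModel:
    """Energy parameters of the bead-spring chain (kT and nm units).

    ``bond_min_nm``/``bond_max_nm`` are hard limits on consecutive-bead
    distances (moves outside are rejected); loop bonds share the chain
    rest length but are not range-limited so a stretched extruder spring
    can relax gradually.
    """

    bond_k: float = 0.02
    bond_rest_nm: float = 50.0
    bond_min_nm: float = 40.0
    bond_max_nm: float = 75.0
    bend_k: float = 1.0
    hardcore_nm: float = 40.0
    loop_k: float = 0.02
    max_disp_nm: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "bond_k",
            "bond_rest_nm",
            "bond_min_nm",
            "bond_max_nm",
            "bend_k",
            "hardcore_nm",
            "loop_k",
            "max_disp_nm",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.hardcore_nm > self.bond_rest_nm:
            raise ConfigError("hardcore_nm must not exceed bond_rest_nm")
        if not self.bond_min_nm <= self.bond_rest_nm <= self.bond_max_nm:
            raise ConfigError("need bond_min_nm <= bond_rest_nm <= bond_max_nm")

    @classmethod
    def from_params(cls, params: SimulationParameters) -> "EnergyModel":
        d = params.monomer_diameter_nm
        return cls(
            bond_rest_nm=d,
            bond_min_nm=0.8 * d,
            bond_max_nm=1.5 * d,
            hardcore_nm=0.8 * d,
            max_disp_nm=0.2 * d,
        )


@dataclass
class Conformation:
    """3D coordinates of every monomer plus the current extruder loops."""

    positions: np.ndarray  # (n, 3) nm
    loop_bonds: set[tuple[int, int]] = field(default_factory=set)
    time_min: float = 0.0

    @property
    def n_monomers(self) -> int:
        return int(self.positions.shape[0])

    def copy(self) -> "Conformation":
        return Conformation(
            self.positions.copy(), set(self.loop_bonds), self.time_min
        )


def init_conformation(
    n_monomers: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    model: EnergyModel | None = None,
    box_nm: float | None = None,
    max_restarts: int = 50,
) -> Conformation:
    """Grow a self-avoiding random-walk starting conformation.

    Beads are placed one by one at the bond rest length in a random
    direction, rejecting placements that violate excluded volume (or an
    optional cubic box of side ``box_nm`` centered at the origin).
    Deterministic given the seed.
    """
    if n_monomers < 2:
        raise ConfigError("need at least 2 monomers")
    model = model or EnergyModel()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    hard = model.hardcore_nm
    for _restart in range(max_restarts):
        pos = np.zeros((n_monomers, 3))
        ok = True
        for i in range(1, n_monomers):
            placed = False
            for _try in range(200):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                cand = pos[i - 1] + v * model.bond_rest_nm
                if box_nm is not None and np.any(np.abs(cand) > box_nm / 2):
                    continue
                if hard > 0 and i > 1:
                    d2 = np.sum((pos[: i - 1] - cand) ** 2, axis=1)
                    if np.any(d2 < hard * hard):
                        continue
                pos[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return Conformation(pos)
    raise ConfigError(
        "could not grow a self-avoiding conformation; try a larger box"
    )


def total_energy(conf: Conformation, model: EnergyModel) -> float:
    """Total energy: bonds + bending + hard-core penalty + loop bonds (kT)."""
    pos = conf.positions
    n = pos.shape[0]
    bonds = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    e = float(np.sum(model.bond_k * (bonds - model.bond_rest_nm) ** 2))
    if model.bend_k > 0 and n >= 3:
        v = np.diff(pos, axis=0)
        norms = np.linalg.norm(v, axis=1)
        cos_t = np.sum(v[:-1] * v[1:], axis=1) / (norms[:-1] * norms[1:])
        e += float(np.sum(model.bend_k * (1.0 - cos_t)))
    if model.hardcore_nm > 0 and n >= 3:
        d = pdist(pos)
        # consecutive beads are exempt (governed by the bond range instead)
        mask = np.ones(d.shape, dtype=bool)
        k = 0
        for i in range(n - 1):
            mask[k] = False  # pair (i, i+1)
            k += n - 1 - i
        if np.any(d[mask] < model.hardcore_nm):
            return float("inf")
    for i, j in conf.loop_bonds:
        d = float(np.linalg.norm(pos[i] - pos[j]))
        e += model.loop_k * (d - model.bond_rest_nm) ** 2
    return e


def _loop_arrays(conf: Conformation) -> tuple[np.ndarray, np.ndarray]:
    if not conf.loop_bonds:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    pairs = sorted(conf.loop_bonds)
    a = np.array([p[0] for p in pairs], dtype=np.int64)
    b = np.array([p[1] for p in pairs], dtype=np.int64)
    return a, b


def run_sweeps(
    conf: Conformation,
    model: EnergyModel,
    n_sweeps: int,
    rng: np.random.Generator,
    temperature: float = 1.0,
) -> float:
    """Run ``n_sweeps`` Metropolis sweeps in place; return acceptance fraction."""
    if n_sweeps <= 0:
        return 0.0
    a, b = _loop_arrays(conf)
    seed = int(rng.integers(2**31))
    accepted = _mc.run_sweeps(
        conf.positions,
        a,
        b,
        model.bond_k,
        model.bond_rest_nm,
        model.bond_min_nm,
        model.bond_max_nm,
        model.bend_k,
        model.hardcore_nm,
        model.loop_k,
        model.max_disp_nm,
        temperature,
        n_sweeps,
        seed,
    )
    return accepted / (n_sweeps * conf.n_monomers)


def mc_sweep(
    conf: Conformation,
    model: EnergyModel,
    temperature: float,
    rng: np.random.Generator,
) -> tuple[Conformation, float]:
    """One Metropolis sweep (n single-bead trials); returns acceptance fraction."""
    frac = run_sweeps(conf, model, 1, rng, temperature)
    return conf, frac


def sync_loops(conf: Conformation, lef_system: LEFSystem) -> Conformation:
    """Replace the conformation's loop bonds by the current bound-LEF leg pairs."""
    conf.loop_bonds = lef_system.loop_bonds()
    return conf


def check_invariants(
    conf: Conformation, model: EnergyModel, check_loop_range: bool = False
) -> None:
    """Raise if connectivity range or excluded volume is violated.

    Loop-bond distances are only checked on request: a bond attached to
    a freshly advanced leg is transiently stretched by design.
    """
    pos = conf.positions
    bonds = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    if np.any(bonds < model.bond_min_nm - 1e-9) or np.any(
        bonds > model.bond_max_nm + 1e-9
    ):
        raise AssertionError("chain bond outside [bond_min, bond_max]")
    if model.hardcore_nm > 0 and pos.shape[0] >= 3:
        n = pos.shape[0]
        d = pdist(pos)
        mask = np.ones(d.shape, dtype=bool)
        k = 0
        for i in range(n - 1):
            mask[k] = False
            k += n - 1 - i
        if np.any(d[mask] < model.hardcore_nm - 1e-9):
            raise AssertionError("excluded-volume violation")
    if check_loop_range:
        for i, j in conf.loop_bonds:
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if not model.bond_min_nm - 1e-9 <= d <= model.bond_max_nm + 1e-9:
                raise AssertionError(f"loop bond ({i},{j}) outside bond range")


def replicate_seed_sequence(seed: int, replicate: int) -> np.random.SeedSequence:
    """Stable per-replicate seed derivation (documented contract)."""
    return np.random.SeedSequence(entropy=seed, spawn_key=(replicate,))


def simulate_replicate(
    params: SimulationParameters,
    genome: GenomeAnnotation,
    seed: int,
    replicate: int = 0,
    model: EnergyModel | None = None,
) -> list[Conformation]:
    """Run one coupled 1D/3D replicate and return its snapshot list.

    Schedule: grow an initial self-avoiding conformation, burn in with
    ``equilibration_time_min`` of pure-polymer sweeps (extrusion off),
    then alternate extrusion kinetics and sweeps over coupling intervals
    for ``sim_time_min``, emitting a snapshot every
    ``snapshot_interval_min``.
    """
    model = model or EnergyModel.from_params(params)
    ss = replicate_seed_sequence(seed, replicate)
    ss_conf, ss_lef, ss_mc = ss.spawn(3)
    conf = init_conformation(genome.n_monomers, ss_conf, model)
    mc_rng = np.random.default_rng(ss_mc)

    n_eq = int(round(params.equilibration_time_min * params.sweeps_per_min))
    run_sweeps(conf, model, n_eq, mc_rng)

    system = init_population(params, genome, ss_lef)
    dt_c = params.coupling_interval_min
    interval = params.snapshot_interval_min
    t = 0.0
    next_snap = interval
    sweep_debt = 0.0
    snapshots: list[Conformation] = []
    eps = 1e-9
    while t < params.sim_time_min - eps:
        dt = min(dt_c, next_snap - t, params.sim_time_min - t)
        advance_1d(system, dt)
        sync_loops(conf, system)
        sweep_debt += dt * params.sweeps_per_min
        n_sw = int(sweep_debt)
        sweep_debt -= n_sw
        run_sweeps(conf, model, n_sw, mc_rng)
        t += dt
        if t >= next_snap - eps:
            snap = conf.copy()
            snap.time_min = t
            snapshots.append(snap)
            next_snap += interval
    return snapshots


def run_coupled(
    params: SimulationParameters,
    genome: GenomeAnnotation,
    seed: int,
    model: EnergyModel | None = None,
):
    """Yield ``(replicate_index, Conformation)`` snapshots for all replicates."""
    for r in range(params.n_replicates):
        for snap in simulate_replicate(params, genome, seed, r, model):
            yield r, snap


# ---------------------------------------------------------------------------
# Snapshot HDF5 container
# ---------------------------------------------------------------------------


def write_snapshots(
    path,
    snapshots_by_replicate: dict[int, list[Conformation]],
    params: SimulationParameters | None = None,
) -> None:
    """Write snapshots to HDF5: /replicate_R/time_T/{positions, legs}."""
    with h5py.File(path, "w") as fh:
        if params is not None:
            meta = fh.create_group("metadata")
            for key, value in vars(params).items():
                meta.attrs[key] = "" if value is None else value
        for r in sorted(snapshots_by_replicate):
            grp = fh.create_group(f"replicate_{r}")
            for snap in snapshots_by_replicate[r]:
                sg = grp.create_group(f"time_{snap.time_min:.6f}")
                sg.attrs["time_min"] = snap.time_min
                sg.create_dataset("positions", data=snap.positions)
                legs = np.array(sorted(snap.loop_bonds), dtype=np.int64).reshape(
                    -1, 2
                )
                sg.create_dataset("legs", data=legs)


def load_snapshots(path) -> dict[int, list[Conformation]]:
    """Read a snapshot HDF5 container back into per-replicate lists."""
    out: dict[int, list[Conformation]] = {}
    with h5py.File(path, "r") as fh:
        for name in fh:
            if not name.startswith("replicate_"):
                continue
            r = int(name.split("_")[1])
            snaps = []
            for tname in fh[name]:
                sg = fh[name][tname]
                legs = sg["legs"][()]
                snaps.append(
                    Conformation(
                        positions=sg["positions"][()],
                        loop_bonds={(int(a), int(b)) for a, b in legs},
                        time_min=float(sg.attrs["time_min"]),
                    )
                )
            snaps.sort(key=lambda s: s.time_min)
            out[r] = snaps
    return out


def flatten_snapshots(
    snapshots_by_replicate: dict[int, list[Conformation]]
) -> list[Conformation]:
    return [
        s for r in sorted(snapshots_by_replicate) for s in snapshots_by_replicate[r]
    ]
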