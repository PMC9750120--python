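"""Configuration parsing and 1D lattice annotation.

The simulator represents one chromosome as a lattice of coarse-grained
monomers, each carrying a fixed amount of genomic DNA (default 2 kb per
50 nm bead).  This module owns the translation from genomic coordinates
(kb, 0-based half-open) to monomer indices, validation of the full
parameter set of a run, and construction of the annotated lattice the
1D loop-extrusion engine operates on: boundary elements with orientation
and permeability, and optional LEF loading sites.

Conventions
-----------
* Genomic positions are given in kb on ``[0, chain_length_kb)``.
* A position falling anywhere inside a monomer assigns that whole
  monomer (integer division by ``monomer_size_kb``).
* A ``blocks_rightward`` boundary stalls legs moving toward increasing
  monomer indices; ``blocks_leftward`` the opposite; ``blocks_both``
  stalls either direction.  ``permeability`` is the probability that an
  arriving leg passes per attempted step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml


class ConfigError(ValueError):
    """A parameter or annotation violates a documented constraint."""


class SchemaError(ConfigError):
    """The configuration text contains an unknown key."""


ORIENTATIONS = ("blocks_rightward", "blocks_leftward", "blocks_both")
REBIND_MODES = ("uniform", "loading_sites")
EXTRUSION_MODES = ("symmetric", "asymmetric")
COLLISION_MODES = ("impenetrable", "phantom")

#: Config keys consumed by other layers (annotation / pipeline), not by
#: SimulationParameters itself.
RESERVED_SECTIONS = frozenset(
    {
        "boundaries",
        "boundaries_alternating",
        "loading_sites_kb",
        "grid",
        "reference_map",
        "variance_mode",
        "triplets",
    }
)


@dataclass
class SimulationParameters:
    """Full parameter set of one simulation run.

    Lengths are kb (genomic) or nm (physical), times are minutes and
    rates are events per minute.  ``n_lef_target`` is the stationary
    mean number of simultaneously bound loop extruders; the binding
    rate is derived from it (see :mod:`polyloopsim.lef_engine`).
    """

    chain_length_kb: int = 6000
    monomer_size_kb: int = 2
    monomer_diameter_nm: float = 50.0
    n_lef_target: int = 100
    velocity_kb_per_min: float = 100.0
    unbind_rate_per_min: float = 0.05
    rebind_mode: str = "uniform"
    extrusion_mode: str = "symmetric"
    collision_mode: str = "impenetrable"
    sim_time_min: float = 120.0
    snapshot_interval_min: float = 1.0
    n_replicates: int = 1
    equilibration_time_min: float = 5.0
    contact_cutoff_nm: float = 100.0
    hic_bin_kb: int = 10
    sweeps_per_min: float = 100.0
    dt_couple_min: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        def _positive(name: str) -> None:
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(f"{name} must be strictly positive, got {v!r}")

        for name in (
            "chain_length_kb",
            "monomer_size_kb",
            "monomer_diameter_nm",
            "velocity_kb_per_min",
            "unbind_rate_per_min",
            "sim_time_min",
            "snapshot_interval_min",
            "n_replicates",
            "contact_cutoff_nm",
            "hic_bin_kb",
            "sweeps_per_min",
        ):
            _positive(name)
        if self.n_lef_target < 0:
            raise ConfigError(
                f"n_lef_target must be >= 0, got {self.n_lef_target!r}"
            )
        if self.equilibration_time_min < 0:
            raise ConfigError(
                "equilibration_time_min must be >= 0, got "
                f"{self.equilibration_time_min!r}"
            )
        if self.dt_couple_min is not None and not self.dt_couple_min > 0:
            raise ConfigError(
                f"dt_couple_min must be strictly positive, got {self.dt_couple_min!r}"
            )
        for name, value in (
            ("chain_length_kb", self.chain_length_kb),
            ("monomer_size_kb", self.monomer_size_kb),
            ("hic_bin_kb", self.hic_bin_kb),
            ("n_lef_target", self.n_lef_target),
            ("n_replicates", self.n_replicates),
            ("seed", self.seed),
        ):
            if int(value) != value:
                raise ConfigError(f"{name} must be an integer, got {value!r}")
            setattr(self, name, int(value))
        if self.chain_length_kb % self.monomer_size_kb != 0:
            raise ConfigError(
                f"chain_length_kb={self.chain_length_kb} is not divisible by "
                f"monomer_size_kb={self.monomer_size_kb}"
            )
        if self.hic_bin_kb % self.monomer_size_kb != 0:
            raise ConfigError(
                f"hic_bin_kb={self.hic_bin_kb} must be an integer multiple of "
                f"monomer_size_kb={self.monomer_size_kb}"
            )
        if self.snapshot_interval_min > self.sim_time_min:
            raise ConfigError(
                f"snapshot_interval_min={self.snapshot_interval_min} exceeds "
                f"sim_time_min={self.sim_time_min}"
            )
        if self.rebind_mode not in REBIND_MODES:
            raise ConfigError(
                f"rebind_mode must be one of {REBIND_MODES}, got {self.rebind_mode!r}"
            )
        if self.extrusion_mode not in EXTRUSION_MODES:
            raise ConfigError(
                f"extrusion_mode must be one of {EXTRUSION_MODES}, "
                f"got {self.extrusion_mode!r}"
            )
        if self.collision_mode not in COLLISION_MODES:
            raise ConfigError(
                f"collision_mode must be one of {COLLISION_MODES}, "
                f"got {self.collision_mode!r}"
            )

    # -- derived quantities --------------------------------------------
    @property
    def n_monomers(self) -> int:
        return self.chain_length_kb // self.monomer_size_kb

    @property
    def step_rate_per_min(self) -> float:
        """Per-leg translocation attempt rate in monomer steps/min."""
        return self.velocity_kb_per_min / self.monomer_size_kb

    @property
    def coupling_interval_min(self) -> float:
        if self.dt_couple_min is not None:
            return self.dt_couple_min
        return min(0.1, self.snapshot_interval_min / 10.0)

    # -- serialization -------------------------------------------------
    def to_config_text(self) -> str:
        data = dataclasses.asdict(self)
        return yaml.safe_dump(data, sort_keys=True)


_PARAM_FIELDS = {f.name for f in dataclasses.fields(SimulationParameters)}


def load_config(config_text: str) -> SimulationParameters:
    """Parse YAML key-value configuration text into SimulationParameters.

    Keys absent from the text take their documented defaults.  Keys that
    belong to other configuration sections (boundary / loading-site
    annotation, grid definition, reference map) are ignored here and
    consumed by :func:`load_full_config`.  Any other unknown key raises
    :class:`SchemaError`.
    """
    data = yaml.safe_load(config_text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise SchemaError("configuration must be a YAML mapping at top level")
    kwargs = {}
    for key, value in data.items():
        if key in RESERVED_SECTIONS:
            continue
        if key not in _PARAM_FIELDS:
            raise SchemaError(f"unknown configuration key: {key!r}")
        kwargs[key] = value
    return SimulationParameters(**kwargs)


@dataclass(frozen=True)
class BoundaryElement:
    """A lattice site that can stall extruding legs.

    ``permeability`` is the probability that a leg arriving against the
    blocked direction passes on a given attempt (0 = impermeable,
    1 = transparent).
    """

    monomer_index: int
    orientation: str = "blocks_both"
    permeability: float = 0.0

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ConfigError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )
        if not 0.0 <= self.permeability <= 1.0:
            raise ConfigError(
                f"permeability must be in [0, 1], got {self.permeability!r}"
            )
        if self.monomer_index < 0:
            raise ConfigError(f"monomer_index must be >= 0, got {self.monomer_index}")


@dataclass
class GenomeAnnotation:
    """Annotated 1D lattice: boundaries and loading sites on monomers."""

    n_monomers: int
    boundaries: list[BoundaryElement] = field(default_factory=list)
    loading_sites: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [b.monomer_index for b in self.boundaries]
        if len(set(idx)) != len(idx):
            raise ConfigError("duplicate boundary monomer indices")
        if any(i >= self.n_monomers for i in idx):
            raise ConfigError("boundary monomer index out of range")
        self.boundaries = sorted(self.boundaries, key=lambda b: b.monomer_index)
        if len(set(self.loading_sites)) != len(self.loading_sites):
            raise ConfigError("duplicate loading-site monomer indices")
        if any(s < 0 or s >= self.n_monomers for s in self.loading_sites):
            raise ConfigError("loading-site monomer index out of range")
        self.loading_sites = sorted(int(s) for s in self.loading_sites)

    def passage_probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site passage probability for rightward / leftward arrivals.

        ``perm_right[i]`` is the probability that a leg stepping onto
        site ``i`` while moving toward larger indices is let through;
        sites without a blocking boundary have probability 1.
        """
        perm_right = np.ones(self.n_monomers)
        perm_left = np.ones(self.n_monomers)
        for b in self.boundaries:
            if b.orientation in ("blocks_rightward", "blocks_both"):
                perm_right[b.monomer_index] = b.permeability
            if b.orientation in ("blocks_leftward", "blocks_both"):
                perm_left[b.monomer_index] = b.permeability
        return perm_right, perm_left


BoundarySpec = Sequence[tuple[float, str, float]]


def build_genome(
    params: SimulationParameters,
    boundary_spec: BoundarySpec = (),
    loading_spec: Sequence[float] = (),
) -> GenomeAnnotation:
    """Translate kb-coordinate boundary/loading specs into a lattice annotation.

    Positions are converted to monomer indices by integer division by
    ``monomer_size_kb``; two positions mapping into the same monomer are
    rejected.  The output boundary list is sorted, so the result does
    not depend on input ordering.
    """
    n = params.n_monomers
    boundaries: list[BoundaryElement] = []
    seen: set[int] = set()
    for pos_kb, orientation, permeability in boundary_spec:
        if not 0 <= pos_kb < params.chain_length_kb:
            raise ConfigError(
                f"boundary position {pos_kb} kb outside [0, {params.chain_length_kb})"
            )
        idx = int(pos_kb // params.monomer_size_kb)
        if idx in seen:
            raise ConfigError(
                f"two boundary positions map to the same monomer index {idx}"
            )
        seen.add(idx)
        boundaries.append(BoundaryElement(idx, orientation, float(permeability)))
    loading: list[int] = []
    lseen: set[int] = set()
    for pos_kb in loading_spec:
        if not 0 <= pos_kb < params.chain_length_kb:
            raise ConfigError(
                f"loading site {pos_kb} kb outside [0, {params.chain_length_kb})"
            )
        idx = int(pos_kb // params.monomer_size_kb)
        if idx in lseen:
            raise ConfigError(
                f"two loading sites map to the same monomer index {idx}"
            )
        lseen.add(idx)
        loading.append(idx)
    return GenomeAnnotation(n_monomers=n, boundaries=boundaries, loading_sites=loading)


def alternating_boundaries(
    chain_length_kb: float, gaps_kb: Sequence[float]
) -> list[tuple[float, str, float]]:
    """Boundary spec with positions at cumulative sums of a cyclic gap list.

    Reproduces layouts such as "a boundary every 300 then 600 kb,
    alternating".  Boundaries default to impermeable and bidirectional.
    """
    if not gaps_kb or any(g <= 0 for g in gaps_kb):
        raise ConfigError("gaps_kb must be a non-empty list of positive gaps")
    spec: list[tuple[float, str, float]] = []
    pos = 0.0
    i = 0
    while True:
        pos += gaps_kb[i % len(gaps_kb)]
        if pos >= chain_length_kb:
            break
        spec.append((pos, "blocks_both", 0.0))
        i += 1
    return spec


def read_boundary_bed(text: str) -> list[tuple[float, str, float]]:
    """Parse a 3-column BED-like boundary file: start_kb, orientation, permeability."""
    spec = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise SchemaError(
                f"boundary file line {lineno}: expected 3 columns, got {len(parts)}"
            )
        spec.append((float(parts[0]), parts[1], float(parts[2])))
    return spec


def load_full_config(
    config_text: str,
) -> tuple[SimulationParameters, GenomeAnnotation, dict]:
    """Parse a complete run configuration: parameters, lattice annotation, extras.

    Recognized annotation sections:

    ``boundaries``
        list of ``{position_kb, orientation, permeability}`` mappings
        (orientation/permeability optional).
    ``boundaries_alternating``
        mapping with ``gaps_kb`` (cyclic gap list) expanded through
        :func:`alternating_boundaries`; merged with explicit boundaries.
    ``loading_sites_kb``
        list of kb positions.

    Extras returned verbatim: ``reference_map`` (path), ``variance_mode``,
    ``triplets`` (bool), ``grid`` (see :mod:`polyloopsim.cli`).
    """
    params = load_config(config_text)
    data = yaml.safe_load(config_text) or {}
    boundary_spec: list[tuple[float, str, float]] = []
    for entry in data.get("boundaries", []) or []:
        if not isinstance(entry, dict) or "position_kb" not in entry:
            raise SchemaError("each boundary entry needs at least position_kb")
        unknown = set(entry) - {"position_kb", "orientation", "permeability"}
        if unknown:
            raise SchemaError(f"unknown boundary keys: {sorted(unknown)}")
        boundary_spec.append(
            (
                float(entry["position_kb"]),
                entry.get("orientation", "blocks_both"),
                float(entry.get("permeability", 0.0)),
            )
        )
    alt = data.get("boundaries_alternating")
    if alt:
        if not isinstance(alt, dict) or "gaps_kb" not in alt:
            raise SchemaError("boundaries_alternating needs a gaps_kb list")
        boundary_spec.extend(
            alternating_boundaries(params.chain_length_kb, alt["gaps_kb"])
        )
    loading_spec = data.get("loading_sites_kb", []) or []
    genome = build_genome(params, boundary_spec, loading_spec)
    extras = {
        k: data[k]
        for k in ("reference_map", "variance_mode", "triplets", "grid")
        if k in data
    }
    return params, genome, extras
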