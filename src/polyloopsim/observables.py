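"""Virtual Hi-C maps, LEF occupancy tracks and three-way contact statistics.

Snapshot streams from the coupled simulation are reduced to the three
observables an experimentalist would compare against:

* a binned contact-probability matrix (two monomers are "in contact"
  when their Euclidean distance is at or below a capture radius,
  default twice the bead diameter),
* a virtual ChIP-seq track of mean extruder-leg occupancy per bin,
* optional triplet (three-way) co-contact counts.

Writers produce community formats: cooler-schema HDF5 for maps
(chroms/bins/pixels/indexes groups, upper-triangle sparse pixels) and
bedGraph for tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
from scipy.spatial import cKDTree

from .genome_config import ConfigError
from .polymer3d import Conformation


@dataclass
class ContactMap:
    """Symmetric binned contact-frequency matrix (probability form).

    ``matrix[i, j]`` is the probability that a random monomer pair from
    bins i and j is in contact in a random snapshot.  The diagonal is 1
    by convention (a bin is always in contact with itself).
    """

    matrix: np.ndarray
    bin_size_kb: int
    n_snapshots: int
    chrom_label: str = "chrSim"

    @property
    def n_bins(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def span_kb(self) -> int:
        return self.n_bins * self.bin_size_kb


@dataclass
class OccupancyTrack:
    """Per-bin mean LEF-leg occupancy (legs per bin per snapshot)."""

    values: np.ndarray
    bin_size_kb: int
    chrom_label: str = "chrSim"


@dataclass
class TripletCounts:
    """Sparse (bin_i < bin_j < bin_k) -> three-way co-contact frequency."""

    counts: dict[tuple[int, int, int], float] = field(default_factory=dict)
    bin_size_kb: int = 0
    n_snapshots: int = 0
    chrom_label: str = "chrSim"


def _bin_assignment(n_monomers: int, monomer_size_kb: int, bin_kb: int) -> np.ndarray:
    if bin_kb % monomer_size_kb != 0:
        raise ConfigError(
            f"bin_kb={bin_kb} must be a multiple of monomer_size_kb={monomer_size_kb}"
        )
    return (np.arange(n_monomers) * monomer_size_kb) // bin_kb


def contact_map(
    snapshots: Sequence[Conformation],
    cutoff_nm: float,
    bin_kb: int,
    monomer_size_kb: int = 2,
    chrom_label: str = "chrSim",
) -> ContactMap:
    """Pool monomer contacts over snapshots into a binned probability map.

    Normalization: the count of contacting monomer pairs between bins I
    and J is divided by ``n_snapshots * |I| * |J|`` (distinct pairs,
    ``|I| * (|I| - 1) / 2``, within a bin); the diagonal is then set to 1.
    """
    snapshots = list(snapshots)
    if not snapshots:
        raise ConfigError("empty snapshot stream")
    n = snapshots[0].n_monomers
    bin_of = _bin_assignment(n, monomer_size_kb, bin_kb)
    n_bins = int(bin_of[-1]) + 1
    acc = np.zeros((n_bins, n_bins))
    for snap in snapshots:
        pairs = cKDTree(snap.positions).query_pairs(cutoff_nm, output_type="ndarray")
        if pairs.size:
            bi = bin_of[pairs[:, 0]]
            bj = bin_of[pairs[:, 1]]
            lo = np.minimum(bi, bj)
            hi = np.maximum(bi, bj)
            np.add.at(acc, (lo, hi), 1.0)
    sizes = np.bincount(bin_of, minlength=n_bins).astype(float)
    denom = np.outer(sizes, sizes)
    intra = sizes * (sizes - 1) / 2.0
    np.fill_diagonal(denom, np.where(intra > 0, intra, 1.0))
    prob = np.zeros_like(acc)
    upper = np.triu_indices(n_bins, k=0)
    prob[upper] = acc[upper] / (denom[upper] * len(snapshots))
    prob = prob + np.triu(prob, k=1).T
    np.fill_diagonal(prob, 1.0)
    return ContactMap(prob, int(bin_kb), len(snapshots), chrom_label)


def chip_profile(
    snapshots: Sequence[Conformation],
    bin_kb: int,
    monomer_size_kb: int = 2,
    chrom_label: str = "chrSim",
) -> OccupancyTrack:
    """Mean number of LEF legs per bin per snapshot (virtual ChIP-seq)."""
    snapshots = list(snapshots)
    if not snapshots:
        raise ConfigError("empty snapshot stream")
    n = snapshots[0].n_monomers
    bin_of = _bin_assignment(n, monomer_size_kb, bin_kb)
    n_bins = int(bin_of[-1]) + 1
    acc = np.zeros(n_bins)
    for snap in snapshots:
        for i, j in snap.loop_bonds:
            acc[bin_of[i]] += 1.0
            acc[bin_of[j]] += 1.0
    return OccupancyTrack(acc / len(snapshots), int(bin_kb), chrom_label)


def threeway_counts(
    snapshots: Sequence[Conformation],
    cutoff_nm: float,
    bin_kb: int,
    monomer_size_kb: int = 2,
    max_triplets_per_snapshot: int | None = None,
    seed: int = 0,
    chrom_label: str = "chrSim",
) -> TripletCounts:
    """Count monomer triplets whose three pairwise distances are all <= cutoff.

    With ``max_triplets_per_snapshot`` set, snapshots exceeding the cap
    are uniformly subsampled and the retained triplets reweighted by
    ``total / cap`` so the counts stay unbiased estimates.
    """
    snapshots = list(snapshots)
    if not snapshots:
        raise ConfigError("empty snapshot stream")
    n = snapshots[0].n_monomers
    bin_of = _bin_assignment(n, monomer_size_kb, bin_kb)
    rng = np.random.default_rng(seed)
    counts: dict[tuple[int, int, int], float] = {}
    for snap in snapshots:
        pairs = cKDTree(snap.positions).query_pairs(cutoff_nm, output_type="ndarray")
        neighbors: dict[int, set[int]] = {}
        for a, b in pairs:
            neighbors.setdefault(int(a), set()).add(int(b))
            neighbors.setdefault(int(b), set()).add(int(a))
        triplets = []
        for a, b in pairs:
            a, b = int(a), int(b)
            common = neighbors[a] & neighbors[b]
            for c in common:
                if c > max(a, b):
                    triplets.append(tuple(sorted((a, b, c))))
        triplets = sorted(set(triplets))
        weight = 1.0
        if (
            max_triplets_per_snapshot is not None
            and len(triplets) > max_triplets_per_snapshot
        ):
            idx = rng.choice(
                len(triplets), size=max_triplets_per_snapshot, replace=False
            )
            weight = len(triplets) / max_triplets_per_snapshot
            triplets = [triplets[k] for k in sorted(idx)]
        for i, j, k in triplets:
            key = tuple(sorted((int(bin_of[i]), int(bin_of[j]), int(bin_of[k]))))
            counts[key] = counts.get(key, 0.0) + weight
    return TripletCounts(counts, int(bin_kb), len(snapshots), chrom_label)


def write_triplets_tsv(triplets: TripletCounts, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_i\tbin_j\tbin_k\tcount\n")
        for (i, j, k), c in sorted(triplets.counts.items()):
            fh.write(f"{i}\t{j}\t{k}\t{c:g}\n")


# ---------------------------------------------------------------------------
# cooler-schema HDF5 writer / reader
# ---------------------------------------------------------------------------

_COOLER_VERSION = 3


def write_cooler(cmap: ContactMap, path) -> None:
    """Write a ContactMap as cooler-schema HDF5 (symmetric-upper pixels).

    Layout: root attrs plus ``chroms`` (name, length), ``bins`` (chrom,
    start, end), ``pixels`` (bin1_id <= bin2_id, count) and ``indexes``
    (chrom_offset, bin1_offset).  Stored counts are the probability
    values; the write -> read round trip is exact on stored pixels.
    """
    n_bins = cmap.n_bins
    bin_bp = cmap.bin_size_kb * 1000
    triu = np.triu_indices(n_bins, k=0)
    vals = cmap.matrix[triu]
    keep = vals != 0
    b1 = triu[0][keep].astype(np.int64)
    b2 = triu[1][keep].astype(np.int64)
    counts = vals[keep].astype(np.float64)
    order = np.lexsort((b2, b1))
    b1, b2, counts = b1[order], b2[order], counts[order]
    bin1_offset = np.searchsorted(b1, np.arange(n_bins + 1), side="left").astype(
        np.int64
    )
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "HDF5::Cooler"
        fh.attrs["format-version"] = _COOLER_VERSION
        fh.attrs["bin-type"] = "fixed"
        fh.attrs["bin-size"] = bin_bp
        fh.attrs["storage-mode"] = "symmetric-upper"
        fh.attrs["nchroms"] = 1
        fh.attrs["nbins"] = n_bins
        fh.attrs["nnz"] = int(b1.size)
        fh.attrs["generated-by"] = "polyloopsim"
        fh.attrs["n-snapshots"] = cmap.n_snapshots
        chroms = fh.create_group("chroms")
        chroms.create_dataset(
            "name", data=np.array([cmap.chrom_label.encode()], dtype="S32")
        )
        chroms.create_dataset(
            "length", data=np.array([n_bins * bin_bp], dtype=np.int32)
        )
        bins = fh.create_group("bins")
        bins.create_dataset("chrom", data=np.zeros(n_bins, dtype=np.int32))
        starts = np.arange(n_bins, dtype=np.int64) * bin_bp
        bins.create_dataset("start", data=starts.astype(np.int32))
        bins.create_dataset("end", data=(starts + bin_bp).astype(np.int32))
        pixels = fh.create_group("pixels")
        pixels.create_dataset("bin1_id", data=b1)
        pixels.create_dataset("bin2_id", data=b2)
        pixels.create_dataset("count", data=counts)
        indexes = fh.create_group("indexes")
        indexes.create_dataset(
            "chrom_offset", data=np.array([0, n_bins], dtype=np.int64)
        )
        indexes.create_dataset("bin1_offset", data=bin1_offset)


def read_cooler(path) -> ContactMap:
    """Read a cooler-schema HDF5 file back to a dense symmetric ContactMap."""
    with h5py.File(path, "r") as fh:
        n_bins = int(fh.attrs["nbins"])
        bin_bp = int(fh.attrs["bin-size"])
        n_snapshots = int(fh.attrs.get("n-snapshots", 1))
        name = fh["chroms/name"][0]
        chrom = name.decode() if isinstance(name, bytes) else str(name)
        b1 = fh["pixels/bin1_id"][()]
        b2 = fh["pixels/bin2_id"][()]
        counts = fh["pixels/count"][()]
    matrix = np.zeros((n_bins, n_bins))
    matrix[b1, b2] = counts
    matrix[b2, b1] = counts
    return ContactMap(matrix, bin_bp // 1000, n_snapshots, chrom)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def write_bedgraph(track: OccupancyTrack, path) -> None:
    """Write a four-column bedGraph (0-based half-open); zeros are written out."""
    bin_bp = track.bin_size_kb * 1000
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            fh.write(f"{track.chrom_label}\t{i * bin_bp}\t{(i + 1) * bin_bp}\t{v:.10g}\n")


def read_bedgraph(path) -> OccupancyTrack:
    chroms, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            c, s, e, v = line.split("\t")
            chroms.append(c)
            starts.append(int(s))
            ends.append(int(e))
            values.append(float(v))
    if not values:
        raise ConfigError(f"no bedGraph records in {path}")
    bin_bp = ends[0] - starts[0]
    return OccupancyTrack(np.array(values), bin_bp // 1000, chroms[0])
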