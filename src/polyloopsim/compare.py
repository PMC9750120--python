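"""Quantitative comparison of model and reference contact maps.

The comparison statistic is a distance-banded, variance-normalized,
scale-aligned chi-square score

    chi2 = mean over bin pairs (i, j) in the band of
           (scale * model_ij - ref_ij)^2 / sigma2_ij

where ``scale`` aligns the mean contact-probability curves P(s) of the
two maps by least squares, and ``sigma2_ij`` comes either from the
replicate-to-replicate variance of the model map, from a Poisson
approximation of the reference, or is supplied directly.  Lower is
better; the argmin over a parameter grid defines the optimal model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np

from .genome_config import ConfigError
from .observables import ContactMap, read_cooler

VARIANCE_MODES = ("replicates", "poisson", "fixed")


@dataclass
class ComparisonResult:
    chi2: float
    n_pairs_used: int
    distance_range_kb: tuple[float, float]
    scale_factor: float
    n_zero_variance_excluded: int = 0
    variance_mode: str = "poisson"

    def to_json(self) -> str:
        d = dict(vars(self))
        d["distance_range_kb"] = list(self.distance_range_kb)
        return json.dumps(d, indent=2)


def ps_curve(cmap: ContactMap) -> tuple[np.ndarray, np.ndarray]:
    """Mean contact probability at each genomic separation (kb)."""
    n = cmap.n_bins
    seps = np.arange(n)
    means = np.array([np.mean(np.diagonal(cmap.matrix, k)) for k in seps])
    return seps * cmap.bin_size_kb, means


def _band_offsets(cmap: ContactMap, band_kb: tuple[float, float] | None):
    if band_kb is None:
        band_kb = (cmap.bin_size_kb, cmap.span_kb / 2.0)
    lo, hi = band_kb
    if lo > hi or hi <= 0:
        raise ConfigError(f"invalid distance band {band_kb}")
    offsets = [
        k
        for k in range(1, cmap.n_bins)
        if lo <= k * cmap.bin_size_kb <= hi
    ]
    if not offsets:
        raise ConfigError(f"distance band {band_kb} contains no bin pairs")
    return band_kb, offsets


def chi2_score(
    model: ContactMap,
    reference: ContactMap,
    band_kb: tuple[float, float] | None = None,
    variance_mode: str = "poisson",
    replicates: Sequence[ContactMap] | None = None,
    sigma2: float | np.ndarray | None = None,
    pool_variance_by_distance: bool = True,
) -> ComparisonResult:
    """Distance-banded chi-square agreement between two contact maps.

    ``variance_mode``:

    * ``"replicates"`` — sigma2 from the sample variance of entries
      across per-replicate maps, divided by the replicate count
      (variance of the replicate mean); requires ``replicates``.  Pass
      replicate maps of either side; for a parameter-grid scan use the
      *reference's* replicates so the weights are fixed across cells
      (weighting each candidate by its own variance favors noisy cells).
    * ``"poisson"`` — sigma2_ij = ref_ij / ref.n_snapshots, the binomial
      /Poisson variance of a probability estimated from n snapshots.
    * ``"fixed"`` — sigma2 passed explicitly (scalar or matrix).

    With ``pool_variance_by_distance`` (default) the replicate/poisson
    variance estimates are pooled over all bin pairs at the same genomic
    separation: contact-map noise is close to stationary per distance,
    and pooling removes the heavy-tailed per-pixel estimates a handful
    of replicates (or a near-empty reference pixel) would give.
    Zero-variance pairs are excluded and their count reported.
    """
    if model.bin_size_kb != reference.bin_size_kb:
        raise ConfigError(
            f"bin size mismatch: model {model.bin_size_kb} kb vs reference "
            f"{reference.bin_size_kb} kb — rebin the reference first "
            "(compare.rebin)"
        )
    if model.n_bins != reference.n_bins:
        raise ConfigError(
            f"span mismatch: {model.n_bins} vs {reference.n_bins} bins — "
            "rebin/crop the reference first"
        )
    if variance_mode not in VARIANCE_MODES:
        raise ConfigError(f"variance_mode must be one of {VARIANCE_MODES}")
    band_kb, offsets = _band_offsets(model, band_kb)

    # scale: least-squares alignment of the mean P(s) curves on the band
    _, pm = ps_curve(model)
    _, pr = ps_curve(reference)
    pm_band = pm[offsets]
    pr_band = pr[offsets]
    denom = float(np.sum(pm_band**2))
    scale = float(np.sum(pm_band * pr_band) / denom) if denom > 0 else 1.0

    rows, cols, offset_of = [], [], []
    for k in offsets:
        idx = np.arange(model.n_bins - k)
        rows.append(idx)
        cols.append(idx + k)
        offset_of.append(np.full(idx.shape, k))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    offset_of = np.concatenate(offset_of)
    m_vals = model.matrix[rows, cols]
    r_vals = reference.matrix[rows, cols]

    if variance_mode == "replicates":
        if not replicates:
            raise ConfigError("variance_mode=replicates requires replicate maps")
        stack = np.stack([r.matrix[rows, cols] for r in replicates])
        if stack.shape[0] < 2:
            raise ConfigError("need at least 2 replicate maps for a variance")
        var = stack.var(axis=0, ddof=1) / stack.shape[0]
    elif variance_mode == "poisson":
        var = r_vals / max(reference.n_snapshots, 1)
    else:
        if sigma2 is None:
            raise ConfigError("variance_mode=fixed requires sigma2")
        sig = np.asarray(sigma2, dtype=float)
        var = np.full(m_vals.shape, float(sig)) if sig.ndim == 0 else sig[rows, cols]

    if pool_variance_by_distance and variance_mode in ("replicates", "poisson"):
        pooled = np.empty_like(var)
        for k in offsets:
            sel = offset_of == k
            pooled[sel] = var[sel].mean()
        var = pooled

    good = var > 0
    n_excluded = int(np.sum(~good))
    if not np.any(good):
        raise ConfigError("all bin pairs in the band have zero variance")
    resid = scale * m_vals[good] - r_vals[good]
    chi2 = float(np.mean(resid**2 / var[good]))
    return ComparisonResult(
        chi2=chi2,
        n_pairs_used=int(np.sum(good)),
        distance_range_kb=(float(band_kb[0]), float(band_kb[1])),
        scale_factor=scale,
        n_zero_variance_excluded=n_excluded,
        variance_mode=variance_mode,
    )


def rebin(cmap: ContactMap, new_bin_kb: int) -> ContactMap:
    """Block-average a map to a coarser bin size (integer multiple)."""
    if new_bin_kb == cmap.bin_size_kb:
        return cmap
    if new_bin_kb % cmap.bin_size_kb != 0:
        raise ConfigError(
            f"new bin size {new_bin_kb} is not a multiple of {cmap.bin_size_kb}"
        )
    f = new_bin_kb // cmap.bin_size_kb
    n_new = cmap.n_bins // f
    trimmed = cmap.matrix[: n_new * f, : n_new * f]
    coarse = trimmed.reshape(n_new, f, n_new, f).mean(axis=(1, 3))
    np.fill_diagonal(coarse, 1.0)
    return ContactMap(coarse, new_bin_kb, cmap.n_snapshots, cmap.chrom_label)


def read_reference(path, bin_size_kb: int | None = None) -> ContactMap:
    """Read a reference map: cooler-schema HDF5 or whitespace dense matrix text."""
    if h5py.is_hdf5(path):
        return read_cooler(path)
    matrix = np.loadtxt(path)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ConfigError(f"dense reference in {path} is not a square matrix")
    if bin_size_kb is None:
        raise ConfigError("dense text references need an explicit bin_size_kb")
    return ContactMap(matrix, bin_size_kb, 1)


# ---------------------------------------------------------------------------
# Parameter-grid summaries
# ---------------------------------------------------------------------------


@dataclass
class GridSummary:
    """Dense chi2 score array over a declared parameter grid (NaN = absent)."""

    axes: dict[str, list] = field(default_factory=dict)
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    best_cell: tuple[int, ...] = ()

    def best_parameters(self) -> dict:
        return {
            name: values[i]
            for (name, values), i in zip(self.axes.items(), self.best_cell)
        }


def grid_summarize(
    results: Sequence[tuple[tuple, ComparisonResult]],
    axes: dict[str, Sequence],
) -> GridSummary:
    """Assemble per-cell comparison results into a dense score grid.

    ``results`` pairs each cell's parameter-value coordinates (in axis
    order) with its ComparisonResult; cells may be missing (sparse
    grid).  Input order does not matter; duplicate cells are rejected.
    """
    axes = {name: list(values) for name, values in axes.items()}
    shape = tuple(len(v) for v in axes.values())
    scores = np.full(shape, np.nan)
    for coords, result in results:
        if len(coords) != len(axes):
            raise ConfigError(
                f"coordinates {coords} do not match the {len(axes)} grid axes"
            )
        idx = []
        for value, (name, values) in zip(coords, axes.items()):
            if value not in values:
                raise ConfigError(f"value {value!r} not on declared axis {name!r}")
            idx.append(values.index(value))
        idx = tuple(idx)
        if not np.isnan(scores[idx]):
            raise ConfigError(f"duplicate grid cell {coords}")
        scores[idx] = result.chi2
    if np.all(np.isnan(scores)):
        raise ConfigError("no grid cells populated")
    best = np.unravel_index(np.nanargmin(scores), shape)
    return GridSummary(axes=axes, scores=scores, best_cell=tuple(int(i) for i in best))


def write_grid_tsv(summary: GridSummary, path) -> None:
    names = list(summary.axes)
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\tchi2\n")
        it = np.nditer(summary.scores, flags=["multi_index"])
        for value in it:
            coords = [
                summary.axes[name][i]
                for name, i in zip(names, it.multi_index)
            ]
            score = "NA" if np.isnan(value) else f"{float(value):.6g}"
            fh.write("\t".join(str(c) for c in coords) + f"\t{score}\n")


def plot_grid_heatmap(summary: GridSummary, path) -> None:
    """Render a 2D grid summary as a heat map (chi2 per cell)."""
    if summary.scores.ndim != 2:
        raise ConfigError("heat-map rendering requires a 2D grid")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(summary.axes)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.imshow(summary.scores, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(summary.axes[names[1]])))
    ax.set_xticklabels(summary.axes[names[1]])
    ax.set_yticks(range(len(summary.axes[names[0]])))
    ax.set_yticklabels(summary.axes[names[0]])
    ax.set_xlabel(names[1])
    ax.set_ylabel(names[0])
    ax.plot(summary.best_cell[1], summary.best_cell[0], "r*", markersize=14)
    fig.colorbar(im, ax=ax, label="chi2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
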