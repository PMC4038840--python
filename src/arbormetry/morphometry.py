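"""Per-neuron arbor metrics.

Implements the standard single-arbor measurements for sparse-labeled
reconstructions: cable length, branch-point counts and density, the
per-section convex-polygon ("polygon method") territory volume, arbor
density (cable length per territory volume), mediolateral extent, and
the soma-vs-arbor topographic rank correlation.

The polygon method encloses the axon trace of each virtual 300 µm
section with the smallest convex polygon (projected onto the section
plane); polygon area x section thickness, summed over all populated,
non-excluded sections, gives an upper estimate of the territory the
arbor influences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import spearmanr

from .reconstruction import (
    NeuronReconstruction,
    SlabDecomposition,
    _type_mask,
    assign_sections,
)
from .units import MM_PER_UM, UM3_PER_MM3

__all__ = [
    "ArborMetrics",
    "total_length",
    "count_branch_points",
    "branch_density",
    "branch_density_subsample",
    "convex_polygon_area",
    "territory_volume",
    "arbor_density",
    "MediolateralSummary",
    "mediolateral_summary",
    "topographic_correlation",
    "compute_metrics",
]


def total_length(rec: NeuronReconstruction, type_filter: str = "axon") -> float:
    """Total cable length (µm): sum of Euclidean parent-child distances
    over edges whose *child* node passes the type filter.

    An empty selection returns 0 with a warning rather than erroring, so
    that e.g. dendrite length of an axon-only trace is simply 0.
    """
    mask = _type_mask(rec.type_codes, type_filter)
    e = rec.edges()
    e = e[mask[e]]
    if e.size == 0:
        warnings.warn(f"no edges match type filter {type_filter!r}", stacklevel=2)
        return 0.0
    return float(np.linalg.norm(rec.xyz[e] - rec.xyz[rec.parent_index[e]], axis=1).sum())


def count_branch_points(rec: NeuronReconstruction, type_filter: str = "axon") -> int:
    """Number of branch points: nodes of the filtered type with >= 2
    children of that type.  A node with k >= 2 children counts once
    (trifurcations are not double counted) and the soma never counts.
    """
    counts = rec.child_counts(type_filter)
    mask = _type_mask(rec.type_codes, type_filter)
    mask &= rec.type_codes != 1  # soma node never counts
    return int(np.sum((counts >= 2) & mask))


def branch_density(rec: NeuronReconstruction, type_filter: str = "axon") -> float:
    """Branch points per mm of cable length."""
    length_mm = total_length(rec, type_filter) * MM_PER_UM
    if length_mm <= 0:
        raise ValueError("branch density undefined for zero cable length")
    return count_branch_points(rec, type_filter) / length_mm


def branch_density_subsample(
    rec: NeuronReconstruction,
    decomp: SlabDecomposition,
    n_sections: int = 2,
    type_filter: str = "axon",
) -> float:
    """Branch density estimated from the ``n_sections`` fullest sections.

    Mirrors measuring total length and branch points within two 300 µm
    sections per arbor instead of the whole reconstruction.  Sections are
    ranked by their cable content; branch points are counted among nodes
    whose coordinate falls inside the selected slabs.
    """
    ranked = sorted(
        ((s.length(type_filter), i) for i, s in decomp.slabs.items()), reverse=True
    )
    chosen = [i for _, i in ranked[:n_sections]]
    if not chosen:
        raise ValueError("decomposition has no content of the requested type")
    length_um = sum(decomp.slabs[i].length(type_filter) for i in chosen)
    if length_um <= 0:
        raise ValueError("selected sections contain no cable")
    counts = rec.child_counts(type_filter)
    mask = _type_mask(rec.type_codes, type_filter) & (rec.type_codes != 1)
    a = rec.xyz[:, decomp.axis]
    slab_idx = np.floor((a - decomp.origin) / decomp.thickness).astype(int)
    in_chosen = np.isin(slab_idx, chosen)
    n_bp = int(np.sum((counts >= 2) & mask & in_chosen))
    return n_bp / (length_um * MM_PER_UM)


def convex_polygon_area(points: np.ndarray) -> float:
    """Area (µm²) of the smallest convex polygon enclosing 2-D points.

    Degenerate inputs (fewer than 3 points, or all collinear) have zero
    area; an empty input is an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("convex_polygon_area requires at least one point")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0  # collinear / coincident points enclose no area
    return float(hull.volume)  # in 2-D, ConvexHull.volume is the area


def territory_volume(decomp: SlabDecomposition, type_filter: str = "axon") -> float:
    """Territory volume (mm³) by the polygon method.

    For every populated, non-excluded slab, the sub-segment vertices are
    projected onto the section plane, enclosed with the smallest convex
    polygon, and the polygon area is multiplied by the section thickness;
    slab volumes are summed.  Hulls of polylines equal hulls of their
    vertices, so projecting vertices (including boundary-split points)
    suffices.  Degenerate slabs contribute zero volume.
    """
    planar = [i for i in range(3) if i != decomp.axis]
    total_um3 = 0.0
    for _, slab in sorted(decomp.slabs.items()):
        if slab.excluded:
            continue
        pts = slab.points(type_filter)
        if pts.shape[0] == 0:
            continue
        area = convex_polygon_area(pts[:, planar])
        total_um3 += area * decomp.thickness
    return total_um3 / UM3_PER_MM3


def arbor_density(total_length_um: float, territory_volume_mm3: float) -> float:
    """Arbor density: mm of cable per mm³ of territory volume."""
    if territory_volume_mm3 <= 0:
        raise ValueError("arbor density undefined for zero territory volume")
    return (total_length_um * MM_PER_UM) / territory_volume_mm3


@dataclass(frozen=True)
class MediolateralSummary:
    """Arbor position along the sectioning (mediolateral) axis, in mm.

    ``extent_mm`` counts occupied sections x thickness, matching how
    extents are measured across physical serial sections;
    ``span_mm`` is the raw coordinate span, reported alongside.
    """

    extent_mm: float
    soma_position_mm: float
    interval_mm: tuple[float, float]
    span_mm: float


def mediolateral_summary(
    decomp: SlabDecomposition,
    soma_position: np.ndarray,
    type_filter: str = "axon",
) -> MediolateralSummary:
    """Mediolateral extent and position of an arbor.

    Extent = (max occupied slab index - min + 1) x thickness over slabs
    containing content of the given type (exclusion flags do not apply
    here: a section that is excluded from territory estimation still
    witnesses the arbor's extent).  The interval endpoints sit at slab
    faces.  Soma position is the soma coordinate on the sectioning axis.
    """
    occupied = decomp.occupied_indices(type_filter)
    if not occupied:
        raise ValueError("no content of the requested type in any slab")
    i0, i1 = min(occupied), max(occupied)
    t = decomp.thickness
    extent_um = (i1 - i0 + 1) * t
    interval = (
        (decomp.origin + i0 * t) * MM_PER_UM,
        (decomp.origin + (i1 + 1) * t) * MM_PER_UM,
    )
    coords: list[float] = []
    for i in occupied:
        pts = decomp.slabs[i].points(type_filter)
        if pts.size:
            coords.extend(pts[:, decomp.axis].tolist())
    span_um = float(np.max(coords) - np.min(coords)) if coords else 0.0
    soma = float(np.asarray(soma_position, float)[decomp.axis])
    return MediolateralSummary(
        extent_mm=extent_um * MM_PER_UM,
        soma_position_mm=soma * MM_PER_UM,
        interval_mm=interval,
        span_mm=span_um * MM_PER_UM,
    )


def topographic_correlation(soma_positions, arbor_midpoints) -> float:
    """Spearman rank correlation between soma positions and arbor
    midpoints along the mediolateral axis (both in consistent units).

    A positive value supports a topographic map: more lateral somata
    project to more lateral territories.
    """
    somas = np.asarray(soma_positions, float)
    arbors = np.asarray(arbor_midpoints, float)
    if somas.shape != arbors.shape:
        raise ValueError("soma and arbor lists must have equal length")
    if somas.size < 3:
        raise ValueError("need at least 3 pairs")
    return float(spearmanr(somas, arbors).statistic)


@dataclass(frozen=True)
class ArborMetrics:
    """Per-neuron morphometric report."""

    total_axon_length_um: float
    total_dendrite_length_um: float
    n_branch_points: int
    branch_density_per_mm: float
    territory_volume_mm3: float
    arbor_density_mm_per_mm3: float
    mediolateral_extent_mm: float
    soma_ml_position_mm: float
    arbor_ml_interval_mm: tuple[float, float]


def compute_metrics(
    rec: NeuronReconstruction,
    axis: str | int = "x",
    thickness: float = 300.0,
    origin: float = 0.0,
    branch_mode: str = "whole",
) -> ArborMetrics:
    """Assemble the full per-neuron report.

    ``branch_mode`` is ``"whole"`` (whole-arbor branch density) or
    ``"two_sections"`` (density from the two fullest virtual sections,
    emulating measurement on two physical sections per arbor).
    """
    decomp = assign_sections(rec, axis=axis, thickness=thickness, origin=origin)
    axon_len = total_length(rec, "axon")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dend_len = total_length(rec, "dendrite")
    if branch_mode == "whole":
        bdens = branch_density(rec, "axon")
    elif branch_mode == "two_sections":
        bdens = branch_density_subsample(rec, decomp, n_sections=2)
    else:
        raise ValueError(f"unknown branch_mode {branch_mode!r}")
    terr = territory_volume(decomp, "axon")
    dens = arbor_density(axon_len, terr) if terr > 0 else float("nan")
    ml = mediolateral_summary(decomp, rec.soma_position(), "axon")
    return ArborMetrics(
        total_axon_length_um=axon_len,
        total_dendrite_length_um=dend_len,
        n_branch_points=count_branch_points(rec, "axon"),
        branch_density_per_mm=bdens,
        territory_volume_mm3=terr,
        arbor_density_mm_per_mm3=dens,
        mediolateral_extent_mm=ml.extent_mm,
        soma_ml_position_mm=ml.soma_position_mm,
        arbor_ml_interval_mm=ml.interval_mm,
    )
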