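"""Synthetic data with known ground truth.

Three generators make every downstream stage testable without any
external data:

* :func:`generate_arbor` — axon arbors grown as a persistent random walk
  with memoryless branching inside a bounding box, emulating basal
  forebrain cholinergic arbors (tens of cm of cable, 4–5 branch points
  per mm, ~2 mm mediolateral extent when sectioned into 300 µm slabs).
* :func:`generate_puncta_image` — 620 x 620 px fields (400 µm x 400 µm)
  with disc-shaped bright deposits over a dim fiber background, plus a
  truth table of centers and diameters.
* :func:`generate_zstack_field` — per-stack traced axon lengths for
  adjacent confocal Z-stacks with out-of-plane "bleed": segments near a
  shared stack face are credited to both stacks, reproducing the
  double-counting artifact that the overlap correction removes.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk, line

from .reconstruction import NeuronReconstruction

__all__ = [
    "ArborSimParams",
    "PunctaSimParams",
    "ZStackSimParams",
    "generate_arbor",
    "generate_puncta_image",
    "generate_zstack_field",
    "ZStackSimResult",
    "save_image",
]

_SOMA_RADIUS_UM = 15.0  # soma diameter ~30 µm
_AXON_RADIUS_UM = 0.15  # axon diameter ~0.3 µm


@dataclass(frozen=True)
class ArborSimParams:
    """Parameters of the random-walk arbor generator.

    Defaults state the adult (P30) regime: 31 cm of axon, 4.5 branch
    points per mm, and a 2 mm bounding box so that sectioned arbors span
    ~2 mm mediolaterally.
    """

    target_length: float = 310_000.0  # µm (31 cm)
    branch_rate: float = 4.5  # branch points per mm of axon
    bounding_box: tuple[float, float, float] = (2000.0, 2000.0, 2000.0)  # µm extents
    step_length: float = 10.0  # µm
    direction_persistence: float = 0.8  # in [0, 1]
    soma_position: tuple[float, float, float] | None = None  # default: box center
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_length > 0:
            raise ValueError("target_length must be > 0")
        if not self.step_length > 0:
            raise ValueError("step_length must be > 0")
        if self.branch_rate < 0:
            raise ValueError("branch_rate must be >= 0")
        if any(e <= 0 for e in self.bounding_box):
            raise ValueError("bounding_box extents must be > 0")
        if not 0.0 <= self.direction_persistence <= 1.0:
            raise ValueError("direction_persistence must be in [0, 1]")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - measure-zero event
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def generate_arbor(params: ArborSimParams) -> NeuronReconstruction:
    """Grow a synthetic axon arbor.

    Growth: each active tip takes steps of fixed length; the direction is
    ``normalize(persistence * previous + (1 - persistence) * isotropic)``,
    specularly reflected at bounding-box faces so arbors stay compact.
    Branching: each step spawns a new tip with probability
    ``branch_rate x step_length`` (memoryless, so branch counts are
    binomial with mean rate x cable length); new branch directions are
    drawn fresh, and trifurcations are never generated.  On a branch
    event both child tips are scheduled next, so branch nodes acquire
    their two children before the length budget can run out under them.

    The realized total axon length is within one ``step_length`` of
    ``target_length`` by construction (every edge has exactly the step
    length).  Identical parameters and seed give identical output.
    """
    rng = np.random.default_rng(params.seed)
    box = np.asarray(params.bounding_box, float)
    step = params.step_length
    rho = params.direction_persistence
    p_branch = params.branch_rate * 1e-3 * step  # rate per µm x step
    if p_branch >= 1.0:
        raise ValueError("branch_rate x step_length must be < 1 branch per step")
    soma = (
        box / 2.0
        if params.soma_position is None
        else np.asarray(params.soma_position, float)
    )
    if np.any(soma < 0) or np.any(soma > box):
        raise ValueError("soma_position must lie inside the bounding box")

    positions = [soma]
    codes = [1]
    radii = [_SOMA_RADIUS_UM]
    parents = [-1]

    # (parent node index, current direction); branch events push to the front
    tips: deque[tuple[int, np.ndarray]] = deque()
    tips.append((0, _random_unit(rng)))
    used = 0.0

    while tips and params.target_length - used >= step:
        parent_idx, d = tips.popleft()
        d_new = rho * d + (1.0 - rho) * _random_unit(rng)
        n = np.linalg.norm(d_new)
        d_new = _random_unit(rng) if n < 1e-12 else d_new / n
        pos = positions[parent_idx] + step * d_new
        for ax in range(3):
            if pos[ax] < 0.0 or pos[ax] > box[ax]:
                d_new = d_new.copy()
                d_new[ax] = -d_new[ax]
        pos = positions[parent_idx] + step * d_new
        positions.append(pos)
        codes.append(2)
        radii.append(_AXON_RADIUS_UM)
        parents.append(parent_idx)
        new_idx = len(positions) - 1
        used += step
        if rng.random() < p_branch:
            tips.appendleft((new_idx, d_new))  # continuation
            tips.appendleft((new_idx, _random_unit(rng)))  # new branch steps first
        else:
            tips.append((new_idx, d_new))

    n = len(positions)
    return NeuronReconstruction(
        ids=np.arange(1, n + 1),
        type_codes=np.array(codes),
        xyz=np.vstack(positions),
        radius=np.array(radii),
        parent_ids=np.array([-1] + [p + 1 for p in parents[1:]]),
    )


# -- puncta images ------------------------------------------------------


@dataclass(frozen=True)
class PunctaSimParams:
    """Parameters of the puncta-field generator.

    The default field emulates acquisition of 400 µm x 400 µm images at
    620 x 620 px.  Deposits are bright discs; the fiber background is a
    set of dim straight lines; diameters are drawn uniformly (integers)
    from ``puncta_diameter_range``.
    """

    field_size: float = 400.0  # µm, square side
    image_size: int = 620  # px, square side
    n_puncta: int = 40
    puncta_diameter_range: tuple[int, int] = (4, 12)  # px
    n_background_fibers: int = 30
    noise_sd: float = 0.02  # intensity units on a [0, 1] scale
    seed: int = 0
    background_intensity: float = 0.05
    fiber_intensity: float = 0.15
    puncta_intensity: float = 1.0
    max_place_retries: int = 1000

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be > 0")
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        if self.puncta_diameter_range[0] < 1:
            raise ValueError("puncta diameters must be >= 1 px")

    @property
    def pixel_size_um(self) -> float:
        return self.field_size / self.image_size


def generate_puncta_image(
    params: PunctaSimParams,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a synthetic puncta field.

    Returns ``(image, truth)`` where ``image`` is a float array in
    [0, 1] and ``truth`` is a DataFrame with one row per disc
    (``row``, ``col`` center in px; ``diameter_px``).  Discs are placed
    without touching each other (rejection sampling); if a non-touching
    placement cannot be found within ``max_place_retries`` attempts the
    field is over-packed and a ``RuntimeError`` is raised.
    """
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    img = np.full((size, size), params.background_intensity, dtype=float)

    for _ in range(params.n_background_fibers):
        # random chord across the field
        r0, c0 = rng.integers(0, size, size=2)
        r1, c1 = rng.integers(0, size, size=2)
        rr, cc = line(int(r0), int(c0), int(r1), int(c1))
        img[rr, cc] = np.maximum(img[rr, cc], params.fiber_intensity)

    d_lo, d_hi = params.puncta_diameter_range
    placed: list[tuple[float, float, int]] = []
    for _ in range(params.n_puncta):
        d = int(rng.integers(d_lo, d_hi + 1))
        radius = d / 2.0
        ok = False
        for _attempt in range(params.max_place_retries):
            margin = radius + 2.0
            r = rng.uniform(margin, size - margin)
            c = rng.uniform(margin, size - margin)
            if all(
                np.hypot(r - rp, c - cp) >= radius + dp / 2.0 + 3.0
                for rp, cp, dp in placed
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place puncta without overlap; packing limit exceeded"
            )
        placed.append((r, c, d))
        rr, cc = disk((r, c), radius, shape=img.shape)
        img[rr, cc] = params.puncta_intensity

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 1.0)

    truth = pd.DataFrame(placed, columns=["row", "col", "diameter_px"])
    truth["diameter_px"] = truth["diameter_px"].astype(int)
    return img, truth


def save_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit grayscale TIFF."""
    import tifffile

    tifffile.imwrite(path, (np.clip(image, 0, 1) * 65535).astype(np.uint16))


# -- confocal Z-stack fields --------------------------------------------


@dataclass(frozen=True)
class ZStackSimParams:
    """Parameters of the Z-stack trace-length generator.

    Defaults state the motor-cortex measurement geometry: two adjacent
    Z-stacks of four 2 µm confocal planes (8 µm per stack) and a true
    axon density of 0.044 µm/µm³.  ``bleed_depth`` is the distance beyond
    a stack face within which a segment is still traced in the adjacent
    stack; the default 1.362 µm is the depth implied by a duplicated
    fraction of 25.4% at 8 µm stacks (2b / (T + 2b) = 0.254).
    """

    true_density: float = 0.044  # µm axon per µm³
    field_area: float = 40_000.0  # µm² (200 µm x 200 µm confocal frame)
    stack_thickness: float = 8.0  # µm (4 planes at 2 µm)
    n_stacks: int = 2
    bleed_depth: float = 1.362  # µm
    segment_length: float = 2.0  # µm per traced segment
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_density < 0:
            raise ValueError("true_density must be >= 0")
        if not self.stack_thickness > 0:
            raise ValueError("stack_thickness must be > 0")
        if self.bleed_depth < 0:
            raise ValueError("bleed_depth must be >= 0")
        if self.n_stacks < 1:
            raise ValueError("n_stacks must be >= 1")


@dataclass(frozen=True)
class ZStackSimResult:
    """Ground truth and per-stack bookkeeping of a simulated field."""

    per_stack_raw_length: np.ndarray  # µm traced per stack (with bleed-in)
    per_pair_duplicated_length: np.ndarray  # µm traced in both stacks of each pair
    true_total_length: float  # µm of axon actually inside the stacks
    true_density: float  # realized in-stack density, µm/µm³


def generate_zstack_field(params: ZStackSimParams) -> ZStackSimResult:
    """Simulate traced axon lengths for adjacent confocal Z-stacks.

    Short segments are placed uniformly across the imaged depth *plus* a
    ``bleed_depth`` margin beyond the two outer faces (tissue continues
    past the imaged volume, so every face is statistically equivalent).
    Each segment is credited to the stack containing it, and additionally
    to any adjacent stack whose shared face lies within ``bleed_depth``
    — those doubly-traced segments form the per-pair duplicated lengths.
    Margin segments bleed into edge stacks but belong to no stack, and
    are excluded from the true total.
    """
    rng = np.random.default_rng(params.seed)
    T, b, n = params.stack_thickness, params.bleed_depth, params.n_stacks
    span = n * T
    ell = params.segment_length
    n_segments = int(round(params.true_density * params.field_area * (span + 2 * b) / ell))
    z = rng.uniform(-b, span + b, size=n_segments)

    raw = np.zeros(n)
    for i in range(n):
        lo, hi = i * T - b, (i + 1) * T + b
        raw[i] = np.count_nonzero((z >= lo) & (z < hi)) * ell
    dup = np.zeros(max(n - 1, 0))
    for j in range(n - 1):
        face = (j + 1) * T
        dup[j] = np.count_nonzero((z >= face - b) & (z < face + b)) * ell

    in_stacks = np.count_nonzero((z >= 0.0) & (z < span)) * ell
    return ZStackSimResult(
        per_stack_raw_length=raw,
        per_pair_duplicated_length=dup,
        true_total_length=float(in_stacks),
        true_density=float(in_stacks / (params.field_area * span)),
    )
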