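"""Reference phantoms and simulated multi-observer delineation cohorts.

The simulator stands in for real delineation data: a star-convex reference
structure is perturbed per observer by a global radial offset (systematic
error, a volume bias) plus a smooth band-limited random field on the unit
sphere (random surface error with a controllable angular correlation
scale). Because the perturbation is radial, the noise SD maps directly
onto the surface-distance SD the analysis pipeline measures, which is what
makes parameter-recovery tests possible.

The random field is a flat-spectrum spherical-harmonic expansion up to a
cutoff degree of about pi * mean_radius / correlation_length, with i.i.d.
standard-normal coefficients, renormalised so its pointwise variance is
exactly one before scaling by sigma_random (the spherical addition theorem
makes the sum of squared orthonormal harmonics direction-independent, so
the normalisation is exact, not asymptotic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.special import sph_harm_y

from .grid import BinaryMask, ObserverCohort, VolumeGrid

__all__ = [
    "PhantomSpec",
    "PhantomMask",
    "ObserverErrorModel",
    "PhantomSpecError",
    "GeometryError",
    "make_phantom",
    "simulate_cohort",
    "decimate_slices",
]


class PhantomSpecError(ValueError):
    """Phantom does not fit its grid with the required margin, or is degenerate."""


class GeometryError(ValueError):
    """Reference structure violates the star-convexity requirement."""


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic star-convex phantom on a voxel grid.

    kind:
      - ``sphere``: ``radius_mm``
      - ``tube``: ``radius_mm`` (transverse) and ``length_mm`` (along z) —
        the low-variation regime analogue (a spinal-canal-like structure)
      - ``blob``: ``axes_mm`` ellipsoid semi-axes, optionally roughened by
        smooth radial bumps of relative amplitude ``bump_rel`` — the
        high-variation regime analogue (a target-volume-like structure)

    ``margin_mm`` is the clearance the phantom must keep to every grid
    face so that distance clipping and surface perturbation never interact
    with the volume boundary (default 20 mm, the distance clip limit).
    """

    kind: str
    grid: VolumeGrid
    center_mm: tuple[float, float, float]
    radius_mm: float = 0.0
    length_mm: float = 0.0
    axes_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bump_rel: float = 0.0
    bump_seed: int = 0
    margin_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "tube", "blob"):
            raise PhantomSpecError(f"unknown phantom kind {self.kind!r}")
        if self.kind == "sphere" and self.radius_mm <= 0:
            raise PhantomSpecError("sphere needs radius_mm > 0")
        if self.kind == "tube" and (self.radius_mm <= 0 or self.length_mm <= 0):
            raise PhantomSpecError("tube needs radius_mm > 0 and length_mm > 0")
        if self.kind == "blob" and (
            min(self.axes_mm) <= 0 or not 0 <= self.bump_rel < 1
        ):
            raise PhantomSpecError("blob needs positive axes_mm and 0 <= bump_rel < 1")

    def axis_extents_mm(self) -> np.ndarray:
        """Support of the shape along each axis (half-extent from center)."""
        if self.kind == "sphere":
            return np.full(3, self.radius_mm)
        if self.kind == "tube":
            return np.array([self.radius_mm, self.radius_mm, self.length_mm / 2.0])
        return np.asarray(self.axes_mm) * (1.0 + self.bump_rel)


class PhantomMask(BinaryMask):
    """A voxelised phantom that remembers its analytic radial profile."""

    def __init__(self, grid, voxels, label, center_mm, radial_fn):
        super().__init__(grid=grid, voxels=voxels, label=label)
        self.center_mm = np.asarray(center_mm, dtype=float)
        self.radial_fn = radial_fn  # unit directions (n, 3) -> radii mm


@dataclass(frozen=True)
class ObserverErrorModel:
    """Per-observer delineation error model.

    sigma_systematic : mm, SD of each observer's global radial offset
        (volume bias; constant over the surface of one observer).
    sigma_random : mm, pointwise SD of the spatially correlated random
        surface error.
    correlation_length_mm : angular smoothing scale of the random field,
        expressed as an arc length on the structure surface.
    seed : master seed; per-observer substreams are derived from
        (seed, observer_index) so adding observers never changes earlier
        observers' masks.
    """

    sigma_systematic: float = 0.0
    sigma_random: float = 0.0
    correlation_length_mm: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_systematic < 0 or self.sigma_random < 0:
            raise ValueError("error SDs must be >= 0")
        if self.correlation_length_mm <= 0:
            raise ValueError("correlation_length_mm must be > 0")


def _unit_dirs_and_radii(
    grid: VolumeGrid, center_mm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel unit direction from center and distance rho (flattened)."""
    xs, ys, zs = grid.voxel_centers()
    gx, gy, gz = np.meshgrid(
        xs - center_mm[0], ys - center_mm[1], zs - center_mm[2], indexing="ij"
    )
    vec = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    rho = np.linalg.norm(vec, axis=1)
    unit = np.divide(vec, rho[:, None], out=np.zeros_like(vec), where=rho[:, None] > 0)
    return unit, rho


def _sphere_radial(radius: float):
    def fn(dirs: np.ndarray) -> np.ndarray:
        return np.full(len(dirs), radius)

    return fn


def _tube_radial(radius: float, length: float):
    half = length / 2.0

    def fn(dirs: np.ndarray) -> np.ndarray:
        ut = np.hypot(dirs[:, 0], dirs[:, 1])
        uz = np.abs(dirs[:, 2])
        with np.errstate(divide="ignore"):
            side = np.where(ut > 0, radius / np.where(ut > 0, ut, 1.0), np.inf)
            cap = np.where(uz > 0, half / np.where(uz > 0, uz, 1.0), np.inf)
        return np.minimum(side, cap)

    return fn


def _blob_radial(axes: np.ndarray, bump_rel: float, bump_seed: int):
    inv2 = 1.0 / axes**2

    if bump_rel > 0:
        rng = np.random.default_rng(bump_seed)
        coeffs = rng.standard_normal(_n_harmonics(3))

    def fn(dirs: np.ndarray) -> np.ndarray:
        r = 1.0 / np.sqrt((dirs**2 * inv2).sum(axis=1))
        if bump_rel > 0:
            field = _unit_variance_field(dirs, coeffs, lmax=3)
            # tanh keeps |relative bump| < bump_rel, preserving positivity
            r = r * (1.0 + bump_rel * np.tanh(field))
        return r

    return fn


def make_phantom(spec: PhantomSpec) -> PhantomMask:
    """Voxelise the analytic phantom: centre-inclusion against r(theta, phi)."""
    center = np.asarray(spec.center_mm, dtype=float)
    extents = spec.axis_extents_mm()
    lo = np.asarray(spec.grid.origin) - 0.5 * np.asarray(spec.grid.spacing)
    hi = lo + np.asarray(spec.grid.shape) * np.asarray(spec.grid.spacing)
    clearance = np.minimum(center - extents - lo, hi - center - extents)
    if clearance.min() < spec.margin_mm:
        raise PhantomSpecError(
            f"phantom clearance {clearance.min():.1f} mm to the nearest grid "
            f"face is below the required margin {spec.margin_mm:g} mm"
        )
    if extents.min() < max(spec.grid.spacing):
        raise PhantomSpecError(
            f"phantom extent {extents.min():.2f} mm is sub-voxel for spacing "
            f"{spec.grid.spacing}; structure would not be resolved"
        )
    if spec.kind == "sphere":
        radial = _sphere_radial(spec.radius_mm)
    elif spec.kind == "tube":
        radial = _tube_radial(spec.radius_mm, spec.length_mm)
    else:
        radial = _blob_radial(np.asarray(spec.axes_mm, float), spec.bump_rel, spec.bump_seed)
    unit, rho = _unit_dirs_and_radii(spec.grid, center)
    inside = rho <= radial(unit)
    vox = inside.reshape(spec.grid.shape)
    if not vox.any():
        raise PhantomSpecError("phantom voxelised to an empty mask")
    return PhantomMask(
        grid=spec.grid,
        voxels=vox,
        label=f"{spec.kind}-reference",
        center_mm=center,
        radial_fn=radial,
    )


# --- band-limited unit-variance random fields on the sphere ---------------


def _n_harmonics(lmax: int) -> int:
    # degrees 1..lmax (the constant l=0 term is excluded: a constant offset
    # is the systematic error's job)
    return (lmax + 1) ** 2 - 1


def _real_sph_harm_basis(dirs: np.ndarray, lmax: int) -> np.ndarray:
    """Orthonormal real spherical harmonics, degrees 1..lmax, at unit dirs."""
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    cols = []
    sqrt2 = np.sqrt(2.0)
    for ell in range(1, lmax + 1):
        for m in range(-ell, ell + 1):
            y = sph_harm_y(ell, abs(m), theta, phi)
            if m == 0:
                cols.append(y.real)
            elif m > 0:
                cols.append(sqrt2 * (-1.0) ** m * y.real)
            else:
                cols.append(sqrt2 * (-1.0) ** m * y.imag)
    return np.column_stack(cols)


def _unit_variance_field(
    dirs: np.ndarray, coeffs: np.ndarray, lmax: int, basis: np.ndarray | None = None
) -> np.ndarray:
    """Evaluate sum_lm c_lm Y_lm / norm with exact pointwise unit variance."""
    if basis is None:
        basis = _real_sph_harm_basis(dirs, lmax)
    # addition theorem: sum_m Y_lm^2 = (2l+1)/(4pi), independent of direction
    var = sum(2 * ell + 1 for ell in range(1, lmax + 1)) / (4.0 * np.pi)
    return (basis @ coeffs) / np.sqrt(var)


def _cutoff_degree(mean_radius_mm: float, correlation_length_mm: float) -> int:
    return max(1, int(round(np.pi * mean_radius_mm / correlation_length_mm)))


# --- radial profile recovery for non-phantom references -------------------


def _radial_fn_from_mask(
    mask: BinaryMask, center: np.ndarray, n_iter: int = 35
):
    """Radial profile r(u) of a star-convex mask by bisection on the
    trilinearly interpolated indicator (0.5 crossing along each ray)."""
    vox = mask.voxels.astype(np.float32)
    grid = mask.grid
    r_max = float(
        np.linalg.norm(np.asarray(grid.shape) * np.asarray(grid.spacing))
    )

    def fn(dirs: np.ndarray) -> np.ndarray:
        lo = np.zeros(len(dirs))
        hi = np.full(len(dirs), r_max)
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            pts = center[None, :] + mid[:, None] * dirs
            val = map_coordinates(
                vox, grid.index_coordinates(pts).T, order=1, mode="constant", cval=0.0
            )
            inside = val >= 0.5
            lo = np.where(inside, mid, lo)
            hi = np.where(inside, hi, mid)
        return 0.5 * (lo + hi)

    return fn


def _check_star_convex(
    mask: BinaryMask, rho: np.ndarray, r_ref: np.ndarray
) -> None:
    """The radial criterion must reproduce the mask up to boundary voxels."""
    predicted = rho <= r_ref
    actual = mask.voxels.ravel()
    disagreement = int(np.count_nonzero(predicted != actual))
    # radial recovery is exact for clean star-convex masks; allow a modest
    # straddle of boundary voxels before declaring the shape non-radial
    surface_budget = max(100, _surface_voxel_count(mask) // 2)
    if disagreement > surface_budget:
        raise GeometryError(
            f"mask {mask.label!r} is not star-convex about its centroid: "
            f"{disagreement} voxels violate the radial representation"
        )


def _surface_voxel_count(mask: BinaryMask) -> int:
    v = mask.voxels
    interior = v.copy()
    interior[1:-1, 1:-1, 1:-1] &= (
        v[:-2, 1:-1, 1:-1] & v[2:, 1:-1, 1:-1]
        & v[1:-1, :-2, 1:-1] & v[1:-1, 2:, 1:-1]
        & v[1:-1, 1:-1, :-2] & v[1:-1, 1:-1, 2:]
    )
    return int(v.sum() - interior.sum())


def simulate_cohort(
    reference: BinaryMask,
    model: ObserverErrorModel,
    n_observers: int,
) -> ObserverCohort:
    """Simulate ``n_observers`` delineations of a star-convex reference.

    Observer ``o`` delineates the body ``rho <= r(u) + s_o + eps_o(u)``
    where ``s_o ~ N(0, sigma_systematic^2)`` is a global radial offset and
    ``eps_o`` is a smooth zero-mean random field with pointwise SD
    ``sigma_random``; masks are voxelised by centre inclusion. The result
    is deterministic given (seed, model, reference, n_observers), and with
    both SDs zero every observer equals the reference exactly.

    A perturbation driving the radius non-positive anywhere is resampled
    with a warning (error after 10 attempts per observer).
    """
    if n_observers < 2:
        raise ValueError("need at least 2 observers")
    if reference.count == 0:
        raise ValueError("reference mask is empty")
    grid = reference.grid

    if isinstance(reference, PhantomMask):
        center = reference.center_mm
        radial_fn = reference.radial_fn
        check_star = False
    else:
        center = reference.centroid_mm()
        radial_fn = _radial_fn_from_mask(reference, center)
        check_star = True

    unit, rho = _unit_dirs_and_radii(grid, center)
    r_ref = radial_fn(unit)
    if check_star:
        _check_star_convex(reference, rho, r_ref)
    inside_ref = rho <= r_ref

    mean_radius = float((3.0 * reference.count * grid.voxel_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))
    lmax = _cutoff_degree(mean_radius, model.correlation_length_mm)

    # offsets are drawn first (one substream per observer) so the band of
    # voxels that can change side is known before fields are evaluated
    rngs = [
        np.random.default_rng(np.random.SeedSequence([int(model.seed), o]))
        for o in range(n_observers)
    ]
    offsets = np.array([rng.normal(0.0, model.sigma_systematic) for rng in rngs])
    half_band = float(np.max(np.abs(offsets))) + 6.0 * model.sigma_random + 1e-9
    band = np.abs(rho - r_ref) <= half_band
    basis = (
        _real_sph_harm_basis(unit[band], lmax) if model.sigma_random > 0 else None
    )

    masks = []
    zero_model = model.sigma_systematic == 0.0 and model.sigma_random == 0.0
    for o, rng in enumerate(rngs):
        label = f"obs{o + 1:02d}"
        if zero_model:
            masks.append(BinaryMask(grid=grid, voxels=reference.voxels.copy(), label=label))
            continue
        s_o = offsets[o]
        for attempt in range(10):
            delta = np.full(int(band.sum()), s_o)
            if model.sigma_random > 0:
                coeffs = rng.standard_normal(_n_harmonics(lmax))
                delta = delta + model.sigma_random * _unit_variance_field(
                    unit[band], coeffs, lmax, basis=basis
                )
            if (r_ref[band] + delta).min() > 0 and (r_ref.min() + s_o) > 0:
                break
            warnings.warn(
                f"observer {label}: perturbation drove the radius non-positive; "
                "resampling",
                stacklevel=2,
            )
            if model.sigma_random == 0:
                s_o = rng.normal(0.0, model.sigma_systematic)
        else:
            raise ValueError(
                f"observer {label}: 10 resampling attempts all produced a "
                "non-positive radius; reduce the error SDs"
            )
        inside = inside_ref.copy()
        inside[band] = rho[band] <= r_ref[band] + delta
        masks.append(
            BinaryMask(grid=grid, voxels=inside.reshape(grid.shape), label=label)
        )
    return ObserverCohort(grid=grid, masks=masks)


def decimate_slices(cohort: ObserverCohort, keep: str = "even") -> ObserverCohort:
    """Drop every other axial slice, doubling the z spacing.

    Emulates halving the slice count of a scan (e.g. 1.5 mm slices thinned
    to 3 mm) to reduce delineation workload. ``keep`` selects whether the
    even- or odd-indexed slices are retained.
    """
    if keep not in ("even", "odd"):
        raise ValueError("keep must be 'even' or 'odd'")
    nx, ny, nz = cohort.grid.shape
    if nz < 2:
        raise ValueError("cannot decimate a single-slice grid")
    start = 0 if keep == "even" else 1
    sx, sy, sz = cohort.grid.spacing
    ox, oy, oz = cohort.grid.origin
    new_grid = VolumeGrid(
        shape=(nx, ny, len(range(start, nz, 2))),
        spacing=(sx, sy, 2.0 * sz),
        origin=(ox, oy, oz + start * sz),
    )
    new_masks = [
        BinaryMask(grid=new_grid, voxels=m.voxels[:, :, start::2], label=m.label)
        for m in cohort.masks
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-mask warnings already raised upstream
        return ObserverCohort(grid=new_grid, masks=new_masks)
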