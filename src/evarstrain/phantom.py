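"""Synthetic CTA-like phantom pairs with known ground truth.

A phantom case emulates two post-operative CTA scans of the same patient:
high-intensity bone rods (vertebra, hips), a contrasted aortic lumen that
bifurcates into two iliac branches, a thrombus sheath around the aneurysmal
trunk segment, anisotropic voxel spacing, a between-timepoint rigid body
motion, and a smooth aneurysm deformation with a closed-form displacement
field and Jacobian.

The deformation is prescribed kinematically, not simulated mechanically.  An
"unfavorable" case carries an outward radial bulge whose radial profile peaks
at the lumen surface and decays slowly across the thrombus wall, so that (as
for a pressurized cylinder) the circumferential stretch is tensile and the
radial stretch compressive throughout the wall.  A "favorable" case carries a
mild isotropic contraction of the sac plus a sum of random-phase smooth
plane-wave harmonics, producing strain vectors with no dominant orientation.

The second timepoint is rendered analytically: for every t2 lattice point the
material pre-image under (rigid o (id + U)) is found by vectorized Newton
iteration using the closed-form Jacobian, and the analytic scene is evaluated
there.  This makes t2 exactly consistent with the stored ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Callable, Sequence

import numpy as np

from .core import BinaryMask, ImageVolume, RigidTransform3D, VectorField

__all__ = [
    "PhantomSpec", "GroundTruth", "DeformationModel",
    "RadialProfileField", "IsotropicContractionField", "GaussianBumpField",
    "PlaneWaveField", "SumField", "EnvelopedField",
    "analytic_affine_field", "analytic_bulge_field",
    "generate_case", "generate_cohort", "generate_straightened_pair",
]


# ---------------------------------------------------------------------------
# Closed-form deformation fields
# ---------------------------------------------------------------------------

class DeformationModel:
    """Interface: closed-form displacement U(x) and Jacobian dU/dx."""

    def displacement(self, points: np.ndarray) -> np.ndarray:  # (N,3)->(N,3)
        raise NotImplementedError

    def jacobian(self, points: np.ndarray) -> np.ndarray:  # (N,3)->(N,3,3)
        raise NotImplementedError


class ZeroField(DeformationModel):
    def displacement(self, points):
        return np.zeros_like(np.asarray(points, dtype=float))

    def jacobian(self, points):
        return np.zeros((len(points), 3, 3))


def _cos2_bump(s: np.ndarray, center: float, half: float):
    """C1 bump: cos^2(pi (s-center) / (2 half)) on |s-center| < half, else 0.

    Returns (value, derivative)."""
    u = np.pi * (s - center) / (2.0 * half)
    inside = np.abs(s - center) < half
    val = np.where(inside, np.cos(u) ** 2, 0.0)
    der = np.where(inside, -np.pi / (2.0 * half) * np.sin(2.0 * u), 0.0)
    return val, der


class RadialProfileField(DeformationModel):
    """Axisymmetric radial field ``U = a g(z) h(r) r_hat`` about a z-parallel axis.

    ``h(r) = 2q / (1 + q^2)`` with ``q = r/rp`` rises linearly from 0 at the
    axis to a smooth unit peak at the peak radius rp (h = 1, h' = 0) and
    decays slowly outward, so d(h)/dr < 0 across the thrombus wall (radial
    compression under an outward bulge) while ``r h(r)`` stays monotonically
    increasing (an outward bulge strictly grows the sheath volume); ``g`` is
    a compactly supported cos^2 axial bump.  Positive amplitude = outward
    bulge, negative = shrink.
    """

    def __init__(self, amplitude: float, axis_xy: Sequence[float],
                 z_center: float, half_length: float, peak_radius: float):
        self.amplitude = float(amplitude)
        self.axis_xy = np.asarray(axis_xy, dtype=float)
        self.z_center = float(z_center)
        self.half_length = float(half_length)
        self.peak_radius = float(peak_radius)

    def _radial(self, r: np.ndarray):
        q = r / self.peak_radius
        d = 1.0 + q * q
        h = 2.0 * q / d
        dh = 2.0 * (1.0 - q * q) / (d * d * self.peak_radius)
        h_over_r = 2.0 / (d * self.peak_radius)  # limit of h/r, finite at the axis
        return h, dh, h_over_r

    def displacement(self, points):
        p = np.asarray(points, dtype=float)
        dx = p[:, 0] - self.axis_xy[0]
        dy = p[:, 1] - self.axis_xy[1]
        r = np.hypot(dx, dy)
        h, _, h_over_r = self._radial(r)
        g, _ = _cos2_bump(p[:, 2], self.z_center, self.half_length)
        # a g h(r) * (dx, dy)/r, written with h/r which is finite at r=0
        fac = self.amplitude * g * h_over_r
        out = np.zeros_like(p)
        out[:, 0] = fac * dx
        out[:, 1] = fac * dy
        return out

    def jacobian(self, points):
        p = np.asarray(points, dtype=float)
        dx = p[:, 0] - self.axis_xy[0]
        dy = p[:, 1] - self.axis_xy[1]
        r = np.hypot(dx, dy)
        h, dh, h_over_r = self._radial(r)
        g, dg = _cos2_bump(p[:, 2], self.z_center, self.half_length)
        a = self.amplitude
        rsafe = np.where(r > 1e-12, r, 1.0)
        nx = np.where(r > 1e-12, dx / rsafe, 0.0)
        ny = np.where(r > 1e-12, dy / rsafe, 0.0)
        J = np.zeros((len(p), 3, 3))
        # in-plane block: a g [ h' n n^T + (h/r)(I - n n^T) ]; at r=0 both
        # coefficients equal e/rp so the block is a g (e/rp) I and the n-terms
        # cancel by construction.
        coef_n = a * g * (dh - h_over_r)
        coef_i = a * g * h_over_r
        J[:, 0, 0] = coef_n * nx * nx + coef_i
        J[:, 0, 1] = coef_n * nx * ny
        J[:, 1, 0] = coef_n * ny * nx
        J[:, 1, 1] = coef_n * ny * ny + coef_i
        # d/dz: a g'(z) h(r) n
        J[:, 0, 2] = a * dg * h * nx
        J[:, 1, 2] = a * dg * h * ny
        return J


class IsotropicContractionField(DeformationModel):
    """Uniform contraction toward a point: ``U = -(a / r_ref) (p - center)``.

    The strain of this field is the isotropic tensor ``-(a / r_ref) I``; it
    shrinks the sac without preferring any direction, so the *orientation* of
    the principal strain vectors of a favorable case is selected entirely by
    the random perturbation bumps added on top.  ``amplitude`` is the inward
    displacement at distance ``r_ref`` from the center.
    """

    def __init__(self, amplitude: float, center: Sequence[float], r_ref: float):
        self.amplitude = float(amplitude)
        self.center = np.asarray(center, dtype=float)
        self.r_ref = float(r_ref)
        if self.r_ref <= 0:
            raise ValueError("r_ref must be positive")

    @property
    def _scale(self) -> float:
        return -self.amplitude / self.r_ref

    def displacement(self, points):
        p = np.asarray(points, dtype=float)
        return self._scale * (p - self.center)

    def jacobian(self, points):
        p = np.asarray(points, dtype=float)
        return np.broadcast_to(self._scale * np.eye(3), (len(p), 3, 3)).copy()


class GaussianBumpField(DeformationModel):
    """Sum of smooth random-direction Gaussian displacement bumps."""

    def __init__(self, centers: np.ndarray, sigmas: np.ndarray,
                 amplitudes: np.ndarray, directions: np.ndarray):
        self.centers = np.asarray(centers, dtype=float)
        self.sigmas = np.asarray(sigmas, dtype=float)
        self.amplitudes = np.asarray(amplitudes, dtype=float)
        self.directions = np.asarray(directions, dtype=float)

    def displacement(self, points):
        p = np.asarray(points, dtype=float)
        out = np.zeros_like(p)
        for c, s, a, d in zip(self.centers, self.sigmas, self.amplitudes, self.directions):
            w = a * np.exp(-np.sum((p - c) ** 2, axis=1) / (2.0 * s * s))
            out += w[:, None] * d
        return out

    def jacobian(self, points):
        p = np.asarray(points, dtype=float)
        J = np.zeros((len(p), 3, 3))
        for c, s, a, d in zip(self.centers, self.sigmas, self.amplitudes, self.directions):
            diff = p - c
            w = a * np.exp(-np.sum(diff ** 2, axis=1) / (2.0 * s * s))
            # dU_i/dx_j = -w (x_j - c_j)/s^2 d_i
            J += (-w / (s * s))[:, None, None] * d[None, :, None] * diff[:, None, :]
        return J

    def rescaled(self, factor: float) -> "GaussianBumpField":
        return GaussianBumpField(self.centers, self.sigmas,
                                 self.amplitudes * factor, self.directions)


class PlaneWaveField(DeformationModel):
    """Sum of sinusoidal displacement harmonics ``a_i d_i cos(k_i . p + phi_i)``.

    With wavevector and displacement directions drawn independently and
    uniformly on the sphere, the strain of each harmonic is proportional to
    ``sym(d k^T)``, whose principal axes bisect two isotropically random
    directions — so the orientation statistics of the summed strain field are
    isotropic, with no preferred axis anywhere in the domain.
    """

    def __init__(self, wavevectors: np.ndarray, directions: np.ndarray,
                 amplitudes: np.ndarray, phases: np.ndarray):
        self.wavevectors = np.asarray(wavevectors, dtype=float)   # (k, 3) rad/mm
        self.directions = np.asarray(directions, dtype=float)     # (k, 3) unit
        self.amplitudes = np.asarray(amplitudes, dtype=float)     # (k,) mm
        self.phases = np.asarray(phases, dtype=float)             # (k,) rad

    def displacement(self, points):
        p = np.asarray(points, dtype=float)
        phase = p @ self.wavevectors.T + self.phases          # (N, k)
        return (self.amplitudes * np.cos(phase)) @ self.directions

    def jacobian(self, points):
        p = np.asarray(points, dtype=float)
        phase = p @ self.wavevectors.T + self.phases          # (N, k)
        w = -self.amplitudes * np.sin(phase)                  # (N, k)
        # dU_i/dx_j = sum_k w_k d_i k_j
        return np.einsum("nk,ki,kj->nij", w, self.directions, self.wavevectors)

    def rescaled(self, factor: float) -> "PlaneWaveField":
        return PlaneWaveField(self.wavevectors, self.directions,
                              self.amplitudes * factor, self.phases)


class SumField(DeformationModel):
    def __init__(self, components: Sequence[DeformationModel]):
        self.components = list(components)

    def displacement(self, points):
        p = np.asarray(points, dtype=float)
        out = np.zeros_like(p)
        for c in self.components:
            out += c.displacement(p)
        return out

    def jacobian(self, points):
        p = np.asarray(points, dtype=float)
        J = np.zeros((len(p), 3, 3))
        for c in self.components:
            J += c.jacobian(p)
        return J


class EnvelopedField(DeformationModel):
    """Multiply a field by a separable C1 envelope E(x) = c_r(r) c_z(z).

    The envelope is 1 inside a cylindrical core and ramps smoothly to 0,
    guaranteeing that the deformation vanishes exactly at the bony anatomy
    (which the rigid-registration stage assumes static).
    """

    def __init__(self, inner: DeformationModel, axis_xy: Sequence[float],
                 r_flat: float, r_zero: float,
                 z_center: float, z_flat_half: float, z_zero_half: float):
        self.inner = inner
        self.axis_xy = np.asarray(axis_xy, dtype=float)
        self.r_flat, self.r_zero = float(r_flat), float(r_zero)
        self.z_center = float(z_center)
        self.z_flat_half, self.z_zero_half = float(z_flat_half), float(z_zero_half)

    def _ramp(self, s, flat, zero):
        """1 for s <= flat, cos^2 ramp to 0 at s = zero. Returns (val, d/ds)."""
        width = zero - flat
        u = np.pi * (s - flat) / (2.0 * width)
        val = np.where(s <= flat, 1.0, np.where(s >= zero, 0.0, np.cos(u) ** 2))
        der = np.where((s > flat) & (s < zero),
                       -np.pi / (2.0 * width) * np.sin(2.0 * u), 0.0)
        return val, der

    def _envelope(self, p):
        dx = p[:, 0] - self.axis_xy[0]
        dy = p[:, 1] - self.axis_xy[1]
        r = np.hypot(dx, dy)
        cr, dcr = self._ramp(r, self.r_flat, self.r_zero)
        s = np.abs(p[:, 2] - self.z_center)
        cz, dcz = self._ramp(s, self.z_flat_half, self.z_zero_half)
        E = cr * cz
        rsafe = np.where(r > 1e-12, r, 1.0)
        gE = np.zeros_like(p)
        gE[:, 0] = dcr * cz * dx / rsafe
        gE[:, 1] = dcr * cz * dy / rsafe
        gE[:, 2] = cr * dcz * np.sign(p[:, 2] - self.z_center)
        return E, gE

    def displacement(self, points):
        p = np.asarray(points, dtype=float)
        E, _ = self._envelope(p)
        return E[:, None] * self.inner.displacement(p)

    def jacobian(self, points):
        p = np.asarray(points, dtype=float)
        E, gE = self._envelope(p)
        U = self.inner.displacement(p)
        J = E[:, None, None] * self.inner.jacobian(p)
        J += U[:, :, None] * gE[:, None, :]
        return J


# ---------------------------------------------------------------------------
# Analytic field constructors (spec'd oracles)
# ---------------------------------------------------------------------------

class AffineField(DeformationModel):
    """U(x) = (A - I) x: the exact deformation gradient is A everywhere."""

    def __init__(self, A: np.ndarray):
        self.A = np.asarray(A, dtype=float)

    def displacement(self, points):
        p = np.asarray(points, dtype=float)
        return p @ (self.A - np.eye(3)).T

    def jacobian(self, points):
        return np.broadcast_to(self.A - np.eye(3), (len(points), 3, 3)).copy()


def _sample_on_lattice(model: DeformationModel, reference: ImageVolume,
                       domain: np.ndarray | None = None) -> VectorField:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in reference.shape],
                        indexing="ij")
    pts = (np.stack(grids, axis=-1) * np.asarray(reference.spacing)
           + np.asarray(reference.origin))
    U = model.displacement(pts.reshape(-1, 3)).reshape(*reference.shape, 3)
    return VectorField(U, reference.spacing, reference.origin, domain)


def analytic_affine_field(A: np.ndarray, reference: ImageVolume) -> VectorField:
    """Sample ``U(x) = (A - I) x`` on the reference lattice (world mm)."""
    A = np.asarray(A, dtype=float)
    if A.shape != (3, 3) or not np.all(np.isfinite(A)):
        raise ValueError("A must be a finite 3x3 matrix")
    return _sample_on_lattice(AffineField(A), reference)


def analytic_bulge_field(reference: ImageVolume, amplitude: float,
                         axis_xy: Sequence[float] | None = None,
                         z_center: float | None = None,
                         half_length: float | None = None,
                         peak_radius: float = 8.0,
                         ) -> tuple[VectorField, Callable[[np.ndarray], np.ndarray]]:
    """Outward radial bulge field on a lattice plus its closed-form Jacobian.

    Returns the sampled field and an evaluator ``jac(points (N,3)) -> (N,3,3)``
    giving the exact dU/dx at arbitrary world positions.  On the bulge
    equator (axial bump maximum, radial profile peak) the exact
    circumferential stretch is ``1 + amplitude / r``.
    """
    if amplitude < 0:
        raise ValueError("bulge amplitude must be >= 0")
    shape = np.asarray(reference.shape)
    spacing = np.asarray(reference.spacing)
    origin = np.asarray(reference.origin)
    extent = (shape - 1) * spacing
    if axis_xy is None:
        axis_xy = (origin[:2] + extent[:2] / 2.0)
    if z_center is None:
        z_center = float(origin[2] + extent[2] / 2.0)
    if half_length is None:
        half_length = float(extent[2] / 3.0)
    model = RadialProfileField(amplitude, axis_xy, z_center, half_length, peak_radius)
    return _sample_on_lattice(model, reference), model.jacobian


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of one synthetic CTA pair.

    Intensities are HU-like; geometry in mm.  ``None`` amplitude fields are
    sampled per-case from the documented default ranges using ``seed``.
    """

    shape: tuple[int, int, int] = (88, 88, 112)
    spacing: tuple[float, float, float] = (0.8, 0.8, 1.0)
    # vessel geometry
    lumen_radius: float = 6.0
    thrombus_outer_radius: float = 16.0
    thrombus_half_length: float = 26.0
    aneurysm_center_frac: float = 0.55      # z of aneurysm center / z extent
    bifurcation_fraction: float = 0.25      # z of bifurcation / z extent
    branch_angle_deg: float = 20.0
    curve_amplitude: float = 2.0            # gentle trunk curve in x, mm
    # intensities (HU-like)
    intensity_background: float = 40.0
    intensity_thrombus: float = 60.0
    intensity_lumen: float = 400.0
    intensity_bone: float = 1200.0
    noise_sd: float = 5.0
    # between-timepoint rigid motion (sampled unless `rigid` is set)
    rotation_max_deg: float = 5.0
    translation_max_mm: float = 20.0
    rigid: RigidTransform3D | None = None
    # aneurysm deformation
    label: str = "unfavorable"
    bulge_amplitude: float | None = None    # mm; None -> U(3, 6)
    bulge_half_length: float = 18.0
    bulge_peak_radius: float | None = None  # None -> lumen_radius + 2
    shrink_amplitude: float | None = None   # mm; None -> U(1, 2)
    n_harmonics: int = 10
    harmonic_mean_disp: float | None = None  # mm; None -> 4.5 / 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("favorable", "unfavorable"):
            raise ValueError(f"label must be favorable/unfavorable, got {self.label!r}")
        if self.lumen_radius >= self.thrombus_outer_radius:
            raise ValueError("lumen radius must be smaller than thrombus outer radius")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for name in ("bulge_amplitude", "shrink_amplitude"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    # derived geometry -----------------------------------------------------
    @property
    def extent(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    @property
    def axis_xy(self) -> np.ndarray:
        """Nominal aorta axis position in the xy-plane (mm)."""
        ex, ey = self.extent[:2]
        return np.array([0.45 * ex, 0.40 * ey])

    @property
    def z_bif(self) -> float:
        return float(self.bifurcation_fraction * self.extent[2])

    @property
    def z_top(self) -> float:
        return float(self.extent[2] - 8.0)

    @property
    def z_bottom(self) -> float:
        return 8.0

    @property
    def z_aneurysm(self) -> float:
        return float(self.aneurysm_center_frac * self.extent[2])

    @property
    def z_landmark(self) -> float:
        return min(self.z_aneurysm + self.thrombus_half_length + 6.0, self.z_top - 4.0)


@dataclass
class GroundTruth:
    """Everything a test oracle needs about one phantom case."""

    rigid: RigidTransform3D            # maps t1-space points into t2 space
    aneurysm_field: VectorField        # forward (Lagrangian) U on the t1 lattice
    masks_t1: dict                     # keys: bone, lumen, thrombus
    masks_t2: dict
    centerline_t1: np.ndarray          # (N, 3) trunk+merged path, proximal last
    centerline_t2: np.ndarray
    landmark_t1: np.ndarray            # lowest-renal landmark, mm
    landmark_t2: np.ndarray
    label: str
    model: DeformationModel = dc_field(repr=False, default=None)  # type: ignore


# ---------------------------------------------------------------------------
# Analytic scene
# ---------------------------------------------------------------------------

class _Scene:
    """Analytic t1 geometry: intensity and structure indicators at any point."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        ax = spec.axis_xy
        self.cx, self.cy = float(ax[0]), float(ax[1])
        # bone geometry: vertebra rod behind the aorta, two hip rods low
        self.vertebra_xy = (self.cx, self.cy + 30.0)
        self.vertebra_r = 8.0
        self.hip_xy = [(self.cx - 26.0, self.cy + 14.0), (self.cx + 26.0, self.cy + 14.0)]
        self.hip_r = 6.0
        self.hip_zmax = 45.0

    def trunk_x(self, z: np.ndarray) -> np.ndarray:
        """Trunk centerline x-offset (gentle sinusoidal curve)."""
        s = self.spec
        zz = np.clip(z, s.z_bif, s.z_top)
        return self.cx + s.curve_amplitude * np.sin(
            np.pi * (zz - s.z_bif) / (s.z_top - s.z_bif))

    def r_outer(self, z: np.ndarray) -> np.ndarray:
        """Thrombus sheath outer radius (ellipsoidal profile)."""
        s = self.spec
        t = (z - s.z_aneurysm) / s.thrombus_half_length
        prof = np.sqrt(np.clip(1.0 - t * t, 0.0, None))
        return s.lumen_radius + (s.thrombus_outer_radius - s.lumen_radius) * prof

    def bone(self, p: np.ndarray) -> np.ndarray:
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        m = (x - self.vertebra_xy[0]) ** 2 + (y - self.vertebra_xy[1]) ** 2 <= self.vertebra_r ** 2
        for hx, hy in self.hip_xy:
            r2 = (x - hx) ** 2 + (y - hy) ** 2
            # rod with a hemispherical end cap: a flat lattice-aligned end
            # plane would voxelize coherently and quantize the apparent bone
            # edge by up to half a voxel, making the rigid ground truth
            # unrecoverable along z
            m |= (r2 <= self.hip_r ** 2) & (z <= self.hip_zmax)
            m |= r2 + (z - self.hip_zmax) ** 2 <= self.hip_r ** 2
        return m

    def lumen(self, p: np.ndarray) -> np.ndarray:
        s = self.spec
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        cxz = self.trunk_x(z)
        trunk = ((z >= s.z_bif) & (z <= s.z_top)
                 & ((x - cxz) ** 2 + (y - self.cy) ** 2 <= s.lumen_radius ** 2))
        d = (s.z_bif - z) * np.tan(np.radians(s.branch_angle_deg))
        rb = 0.8 * s.lumen_radius
        x0 = self.trunk_x(np.full_like(z, s.z_bif))
        limbs = ((z >= s.z_bottom) & (z < s.z_bif)
                 & (((x - (x0 + d)) ** 2 + (y - self.cy) ** 2 <= rb ** 2)
                    | ((x - (x0 - d)) ** 2 + (y - self.cy) ** 2 <= rb ** 2)))
        return trunk | limbs

    def thrombus(self, p: np.ndarray) -> np.ndarray:
        s = self.spec
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        inside_z = np.abs(z - s.z_aneurysm) <= s.thrombus_half_length
        cxz = self.trunk_x(z)
        r2 = (x - cxz) ** 2 + (y - self.cy) ** 2
        return inside_z & (r2 <= self.r_outer(z) ** 2) & (r2 > s.lumen_radius ** 2)

    def intensity(self, p: np.ndarray) -> np.ndarray:
        s = self.spec
        out = np.full(len(p), s.intensity_background, dtype=float)
        out[self.thrombus(p)] = s.intensity_thrombus
        out[self.lumen(p)] = s.intensity_lumen
        out[self.bone(p)] = s.intensity_bone
        return out

    def centerline(self, step: float = 1.0) -> np.ndarray:
        """Ground-truth combined centerline, distal (low z) to proximal."""
        s = self.spec
        z = np.arange(s.z_bottom, s.z_top + step / 2, step)
        x = np.where(z >= s.z_bif, self.trunk_x(z), self.trunk_x(np.full_like(z, s.z_bif)))
        return np.stack([x, np.full_like(z, self.cy), z], axis=1)

    def landmark(self) -> np.ndarray:
        s = self.spec
        zl = s.z_landmark
        return np.array([float(self.trunk_x(np.array([zl]))[0]), self.cy, zl])


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------

def _build_deformation(spec: PhantomSpec, scene: _Scene,
                       rng: np.random.Generator) -> DeformationModel:
    s = spec
    z_an = s.z_aneurysm
    axis = np.array([float(scene.trunk_x(np.array([z_an]))[0]), scene.cy])
    # peak at the lumen radius: the thrombus sheath lies entirely at r >= the
    # peak, where dh/dr <= 0, so an outward bulge is radially compressive
    # (and circumferentially tensile) over the whole strain domain
    peak = s.bulge_peak_radius if s.bulge_peak_radius is not None else s.lumen_radius
    components: list[DeformationModel] = []
    if s.label == "unfavorable":
        amp = s.bulge_amplitude
        if amp is None:
            amp = float(rng.uniform(3.0, 6.0))
        components.append(RadialProfileField(amp, axis, z_an, s.bulge_half_length, peak))
    else:
        amp = s.shrink_amplitude
        if amp is None:
            amp = float(rng.uniform(1.0, 2.0))
        # an isotropic contraction has strain -(amp/r_ref) I: it shrinks the
        # sac but carries no directional preference, so the favorable-case
        # strain orientations are set by the random bumps below.  (A radial
        # shrink profile would coherently bias the compressive vectors into
        # the cross-sectional plane, which is the unfavorable signature.)
        components.append(IsotropicContractionField(
            amp, np.array([axis[0], axis[1], z_an]), s.thrombus_outer_radius))
        # smooth random-phase harmonics with no dominant orientation: both
        # the wavevector and the displacement direction of every harmonic
        # are uniform on the sphere, so the perturbation strain orientation
        # statistics are isotropic (a domain-bound bump model would inherit
        # the elongated thrombus geometry and bias the axes toward z)
        k = s.n_harmonics
        if k > 0:
            kdir = rng.normal(size=(k, 3))
            kdir /= np.linalg.norm(kdir, axis=1, keepdims=True)
            wavelength = rng.uniform(15.0, 30.0, k)           # mm, smooth
            wavevectors = kdir * (2.0 * np.pi / wavelength)[:, None]
            dirs = rng.normal(size=(k, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            amps = rng.normal(0.0, 1.0, k)
            phases = rng.uniform(0.0, 2 * np.pi, k)
            bumps = PlaneWaveField(wavevectors, dirs, amps, phases)
            # calibrate so the mean |U| over the thrombus is ~1/4 of the
            # nominal unfavorable bulge amplitude
            target = s.harmonic_mean_disp if s.harmonic_mean_disp is not None else 4.5 / 4.0
            probe_z = rng.uniform(z_an - s.thrombus_half_length,
                                  z_an + s.thrombus_half_length, 500)
            probe_r = rng.uniform(s.lumen_radius, s.thrombus_outer_radius, 500)
            probe_t = rng.uniform(0, 2 * np.pi, 500)
            probe = np.stack([axis[0] + probe_r * np.cos(probe_t),
                              axis[1] + probe_r * np.sin(probe_t), probe_z], axis=1)
            mean_disp = float(np.mean(np.linalg.norm(bumps.displacement(probe), axis=1)))
            if mean_disp > 1e-12:
                bumps = bumps.rescaled(target / mean_disp)
            components.append(bumps)
    inner = SumField(components) if len(components) > 1 else components[0]
    return EnvelopedField(
        inner, axis,
        r_flat=s.thrombus_outer_radius + 1.0, r_zero=s.thrombus_outer_radius + 6.0,
        z_center=z_an, z_flat_half=s.thrombus_half_length,
        z_zero_half=s.thrombus_half_length + 8.0)


def _sample_rigid(spec: PhantomSpec, rng: np.random.Generator) -> RigidTransform3D:
    if spec.rigid is not None:
        return spec.rigid
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.2, 1.0) * spec.rotation_max_deg)
    tdir = rng.normal(size=3)
    tdir /= np.linalg.norm(tdir)
    tmag = rng.uniform(0.25, 1.0) * spec.translation_max_mm
    center = spec.extent / 2.0
    return RigidTransform3D.from_rotvec(axis * angle, tdir * tmag, center=center)


def _invert_forward_map(model: DeformationModel, targets: np.ndarray,
                        iterations: int = 8) -> np.ndarray:
    """Solve ``x + U(x) = z`` for each target z by Newton iteration."""
    z = np.asarray(targets, dtype=float)
    x = z - model.displacement(z)  # first-order guess
    for _ in range(iterations):
        res = x + model.displacement(x) - z
        J = model.jacobian(x)
        J[:, 0, 0] += 1.0
        J[:, 1, 1] += 1.0
        J[:, 2, 2] += 1.0
        x = x - np.linalg.solve(J, res[..., None])[..., 0]
    return x


def generate_case(spec: PhantomSpec) -> tuple[ImageVolume, ImageVolume, GroundTruth]:
    """Generate one CTA-like pair (t1, t2) with full ground truth.

    t2 is the rigid motion of t1 deformed by the case's closed-form aneurysm
    field, with independent additive Gaussian noise on both volumes.
    """
    rng = np.random.default_rng(spec.seed)
    scene = _Scene(spec)
    model = _build_deformation(spec, scene, rng)
    rigid = _sample_rigid(spec, rng)

    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in spec.shape], indexing="ij")
    pts = (np.stack(grids, axis=-1) * np.asarray(spec.spacing)).reshape(-1, 3)

    vox_t1 = scene.intensity(pts)
    masks_t1 = {
        "bone": scene.bone(pts), "lumen": scene.lumen(pts), "thrombus": scene.thrombus(pts),
    }

    # material pre-image of each t2 lattice point under rigid o (id + U)
    z_pts = rigid.inverse().apply(pts)
    # restrict the Newton solve to points near the deformation support
    ax = np.array([*model.axis_xy]) if isinstance(model, EnvelopedField) else spec.axis_xy
    r = np.hypot(z_pts[:, 0] - ax[0], z_pts[:, 1] - ax[1])
    margin = 8.0
    near = ((r <= spec.thrombus_outer_radius + 6.0 + margin)
            & (np.abs(z_pts[:, 2] - spec.z_aneurysm)
               <= spec.thrombus_half_length + 8.0 + margin))
    pre = z_pts.copy()
    if np.any(near):
        pre[near] = _invert_forward_map(model, z_pts[near])

    vox_t2 = scene.intensity(pre)
    masks_t2 = {
        "bone": scene.bone(pre), "lumen": scene.lumen(pre), "thrombus": scene.thrombus(pre),
    }

    if spec.noise_sd > 0:
        vox_t1 = vox_t1 + rng.normal(0.0, spec.noise_sd, vox_t1.shape)
        vox_t2 = vox_t2 + rng.normal(0.0, spec.noise_sd, vox_t2.shape)

    shape = spec.shape
    t1 = ImageVolume(vox_t1.reshape(shape), spec.spacing)
    t2 = ImageVolume(vox_t2.reshape(shape), spec.spacing)

    def _mask(d):
        return {k: BinaryMask(v.reshape(shape).astype(np.uint8), spec.spacing)
                for k, v in d.items()}

    U = model.displacement(pts).reshape(*shape, 3)
    field = VectorField(U, spec.spacing, domain=masks_t1["thrombus"].reshape(shape))

    cl1 = scene.centerline()
    cl2 = rigid.apply(cl1 + model.displacement(cl1))
    lm1 = scene.landmark()
    lm2 = rigid.apply(lm1 + model.displacement(lm1[None])[0])

    gt = GroundTruth(rigid=rigid, aneurysm_field=field,
                     masks_t1=_mask(masks_t1), masks_t2=_mask(masks_t2),
                     centerline_t1=cl1, centerline_t2=cl2,
                     landmark_t1=lm1, landmark_t2=lm2,
                     label=spec.label, model=model)
    return t1, t2, gt


def generate_straightened_pair(spec: PhantomSpec | None = None, seed: int | None = None
                               ) -> tuple[ImageVolume, ImageVolume,
                                          BinaryMask, BinaryMask, VectorField]:
    """A straightened-thrombus pair: fixed/moving tube volumes plus masks.

    Emulates the deformable-registration input after curved planar
    reformation: a straight-axis lumen + thrombus tube at 1 mm isotropic
    sampling, deformed by the case's smooth outward bulge (amplitude drawn
    from the unfavorable default range when unspecified), with independent
    noise per timepoint and no rigid motion.  Returns
    ``(fixed, moving, fixed_mask, moving_mask, forward_field)`` where the
    forward field is the ground-truth Lagrangian displacement on the fixed
    lattice.
    """
    spec = spec or PhantomSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    amp = spec.bulge_amplitude
    if amp is None:
        amp = float(rng.uniform(3.0, 6.0))

    r_out = spec.thrombus_outer_radius
    half = spec.thrombus_half_length
    margin = 8.0
    n_in = int(2 * np.ceil(r_out + amp + margin)) + 1
    n_z = int(2 * np.ceil(half + margin)) + 1
    c = (n_in - 1) / 2.0
    zc = (n_z - 1) / 2.0
    spacing = (1.0, 1.0, 1.0)

    peak = spec.bulge_peak_radius if spec.bulge_peak_radius is not None \
        else spec.lumen_radius + 2.0
    inner = RadialProfileField(amp, (c, c), zc, spec.bulge_half_length, peak)
    model = EnvelopedField(inner, np.array([c, c]),
                           r_flat=r_out + 1.0, r_zero=r_out + 6.0,
                           z_center=zc, z_flat_half=half, z_zero_half=half + 6.0)

    g = np.meshgrid(*map(np.arange, (n_in, n_in, n_z)), indexing="ij")
    pts = np.stack([a.astype(float) for a in g], axis=-1).reshape(-1, 3)

    def tube(p):
        r = np.hypot(p[:, 0] - c, p[:, 1] - c)
        dz = np.abs(p[:, 2] - zc)
        lum = r < spec.lumen_radius
        thr = (r < r_out) & (dz <= half)
        vox = np.full(len(p), float(spec.intensity_background))
        vox[thr] = spec.intensity_thrombus
        vox[lum] = spec.intensity_lumen
        return vox, thr

    vox_f, thr_f = tube(pts)
    pre = _invert_forward_map(model, pts)
    vox_m, thr_m = tube(pre)
    shape = (n_in, n_in, n_z)
    if spec.noise_sd > 0:
        vox_f = vox_f + rng.normal(0.0, spec.noise_sd, vox_f.shape)
        vox_m = vox_m + rng.normal(0.0, spec.noise_sd, vox_m.shape)
    U = model.displacement(pts).reshape(*shape, 3)
    fixed_mask = BinaryMask(thr_f.reshape(shape).astype(np.uint8), spacing)
    return (ImageVolume(vox_f.reshape(shape), spacing),
            ImageVolume(vox_m.reshape(shape), spacing),
            fixed_mask,
            BinaryMask(thr_m.reshape(shape).astype(np.uint8), spacing),
            VectorField(U, spacing, domain=thr_f.reshape(shape)))


def generate_cohort(n_cases: int, n_unfavorable: int,
                    base_spec: PhantomSpec | None = None,
                    seed: int = 0) -> list[PhantomSpec]:
    """Per-case jittered specs with exactly ``n_unfavorable`` unfavorable labels.

    Returns lightweight specs; realize each with :func:`generate_case`.
    Deterministic given ``seed``.
    """
    if not (0 <= n_unfavorable <= n_cases):
        raise ValueError(f"need 0 <= n_unfavorable <= n_cases, got {n_unfavorable}/{n_cases}")
    if base_spec is None:
        base_spec = PhantomSpec()
    rng = np.random.default_rng(seed)
    labels = np.array(["unfavorable"] * n_unfavorable
                      + ["favorable"] * (n_cases - n_unfavorable))
    rng.shuffle(labels)
    specs = []
    for i, label in enumerate(labels):
        jitter = rng.uniform(0.9, 1.1, size=3)
        specs.append(replace(
            base_spec,
            label=str(label),
            lumen_radius=base_spec.lumen_radius * jitter[0],
            thrombus_outer_radius=base_spec.thrombus_outer_radius * jitter[1],
            thrombus_half_length=base_spec.thrombus_half_length * jitter[2],
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        ))
    return specs
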