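"""Voxel-wise finite-strain analysis of a displacement field.

From the Lagrangian displacement U (mm, on the reference lattice) the
deformation gradient is F = dU/dX + I (central differences against physical
coordinates), the right Cauchy-Green tensor C = F^T F, and its
eigen-decomposition gives the squared principal stretches.  Where the largest
principal stretch sqrt(lambda_1) exceeds 1 the corresponding eigenvector is
the maximum tensile strain direction with magnitude sqrt(lambda_1) - 1; where
the smallest stretch is below 1 its eigenvector is the maximum compressive
direction with magnitude 1 - sqrt(lambda_3).  Voxels whose maximum stretch is
<= 1 are triaxially compressed and contribute no tensile vector (and
symmetrically for triaxial tension).

Strain magnitude is defined as the principal-stretch deviation |stretch - 1|
(engineering-strain-like, zero exactly at the tensile/compressive threshold);
the Green-Lagrange tensor E = (C - I)/2 is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, VectorField

logger = logging.getLogger(__name__)


@dataclass
class StrainField:
    """Per-voxel strain quantities on the reference lattice.

    Tensor lattices are (nx, ny, nz, 3, 3); per-voxel quantities are defined
    only where ``valid``; tensile/compressive entries only where the
    respective presence mask holds.  Eigenvalues are sorted descending.
    """

    F: np.ndarray
    C: np.ndarray
    eigenvalues: np.ndarray            # (..., 3) descending
    stretches: np.ndarray              # sqrt(eigenvalues)
    tensile_unit: np.ndarray           # (..., 3), zeros where absent
    tensile_mag: np.ndarray
    tensile_present: np.ndarray
    compressive_unit: np.ndarray
    compressive_mag: np.ndarray
    compressive_present: np.ndarray
    valid: np.ndarray
    fold_count: int = 0                # voxels with det F <= 0 (excluded)
    spacing: tuple = (1.0, 1.0, 1.0)

    def tensile_vectors(self) -> np.ndarray:
        """The set of tensile unit vectors, shape (N, 3)."""
        return self.tensile_unit[self.tensile_present]

    def compressive_vectors(self) -> np.ndarray:
        return self.compressive_unit[self.compressive_present]


@dataclass
class StrainSummary:
    mean_tensile_mag: float
    mean_compressive_mag: float
    n_tensile: int
    n_compressive: int
    n_triaxial_tense: int
    n_triaxial_compressed: int
    n_valid: int

    def __post_init__(self) -> None:
        if self.mean_tensile_mag < 0 or self.mean_compressive_mag < 0:
            raise ValueError("mean magnitudes must be >= 0")


def canonical_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip each vector so its largest-|component| entry is positive.

    Ties are broken by the earliest axis.  Deterministic resolution of the
    inherent sign ambiguity of eigenvectors.
    """
    v = np.asarray(vectors, dtype=float)
    absv = np.abs(v)
    # earliest axis among maximal |components|
    lead = np.argmax(absv, axis=-1)
    sign = np.sign(np.take_along_axis(v, lead[..., None], axis=-1))[..., 0]
    sign = np.where(sign == 0, 1.0, sign)
    return v * sign[..., None]


def displacement_gradient(fieldv: VectorField,
                          domain: BinaryMask | np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient dU_a/dx_b with physical spacing.

    Returns ``(gradU, valid)`` where ``gradU[..., a, b]`` is the derivative of
    component a along axis b, and ``valid`` marks voxels whose +/-1
    neighbours along every axis lie inside the lattice and the domain.
    """
    U = fieldv.vectors
    spacing = fieldv.spacing
    if domain is None:
        dom = np.ones(U.shape[:3], dtype=bool)
    elif isinstance(domain, BinaryMask):
        if domain.shape != U.shape[:3]:
            raise ValueError("domain lattice does not match the field")
        dom = domain.as_bool()
    else:
        dom = np.asarray(domain).astype(bool)
        if dom.shape != U.shape[:3]:
            raise ValueError("domain lattice does not match the field")

    grad = np.empty((*U.shape[:3], 3, 3))
    for a in range(3):
        gx, gy, gz = np.gradient(U[..., a], *spacing)
        grad[..., a, 0] = gx
        grad[..., a, 1] = gy
        grad[..., a, 2] = gz
    # full central-difference support: 6-neighbourhood inside lattice & domain
    cross = ndimage.generate_binary_structure(3, 1)
    valid = ndimage.binary_erosion(dom, structure=cross, border_value=0)
    return grad, valid


def deformation_tensor(gradU: np.ndarray) -> np.ndarray:
    """F = gradU + I at every voxel."""
    return np.asarray(gradU) + np.eye(3)


def right_cauchy_green(F: np.ndarray) -> np.ndarray:
    """C = F^T F (symmetric positive semidefinite by construction)."""
    F = np.asarray(F)
    return np.einsum("...ba,...bc->...ac", F, F)


def green_lagrange(C: np.ndarray) -> np.ndarray:
    """Green-Lagrange finite-strain tensor E = (C - I)/2."""
    return (np.asarray(C) - np.eye(3)) / 2.0


def principal_strain_fields(C: np.ndarray,
                            valid: np.ndarray | None = None,
                            F: np.ndarray | None = None,
                            spacing=(1.0, 1.0, 1.0),
                            symmetry_tol: float = 1e-8) -> StrainField:
    """Eigen-analysis of C: principal stretches and tensile/compressive fields.

    Strict inequalities define presence: a tensile vector exists only where
    sqrt(lambda_1) > 1, a compressive one only where sqrt(lambda_3) < 1.
    Eigenvector signs are canonicalized (largest-|component| positive).  When
    ``F`` is given, voxels with det F <= 0 (folding) are excluded and counted.
    """
    C = np.asarray(C, dtype=float)
    shape = C.shape[:-2]
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    else:
        valid = np.asarray(valid).astype(bool)

    Cv = C[valid]
    asym = np.abs(Cv - np.swapaxes(Cv, -1, -2)).max() if len(Cv) else 0.0
    if asym > symmetry_tol:
        raise FloatingPointError(f"C not symmetric: max |C - C^T| = {asym:.3e}")

    fold = 0
    if F is not None and len(Cv):
        detF = np.linalg.det(np.asarray(F)[valid])
        folded = detF <= 0
        fold = int(folded.sum())
        if fold:
            logger.warning("%d voxel(s) with det F <= 0 excluded from strain analysis", fold)
            keep = np.zeros(shape, dtype=bool)
            keep[valid] = ~folded
            valid = keep
            Cv = C[valid]

    lam = np.zeros((*shape, 3))
    vecs = np.zeros((*shape, 3, 3))
    if len(Cv):
        w, v = np.linalg.eigh(0.5 * (Cv + np.swapaxes(Cv, -1, -2)))
        w = w[:, ::-1]                       # descending
        v = v[:, :, ::-1]
        lam[valid] = np.clip(w, 0.0, None)
        vecs[valid] = v

    stretches = np.sqrt(lam)
    tensile_present = valid & (stretches[..., 0] > 1.0)
    compressive_present = valid & (stretches[..., 2] < 1.0)

    tensile_unit = np.zeros((*shape, 3))
    tensile_unit[tensile_present] = canonical_sign(vecs[tensile_present][:, :, 0])
    compressive_unit = np.zeros((*shape, 3))
    compressive_unit[compressive_present] = canonical_sign(vecs[compressive_present][:, :, 2])

    tensile_mag = np.where(tensile_present, stretches[..., 0] - 1.0, 0.0)
    compressive_mag = np.where(compressive_present, 1.0 - stretches[..., 2], 0.0)

    Ffull = np.asarray(F) if F is not None else deformation_tensor(np.zeros((*shape, 3, 3)))
    return StrainField(F=Ffull, C=C, eigenvalues=lam, stretches=stretches,
                       tensile_unit=tensile_unit, tensile_mag=tensile_mag,
                       tensile_present=tensile_present,
                       compressive_unit=compressive_unit,
                       compressive_mag=compressive_mag,
                       compressive_present=compressive_present,
                       valid=valid, fold_count=fold, spacing=tuple(spacing))


def strain_from_displacement(fieldv: VectorField,
                             domain: BinaryMask | np.ndarray | None = None
                             ) -> StrainField:
    """Convenience chain: gradient -> F -> C -> principal strain fields."""
    gradU, valid = displacement_gradient(fieldv, domain)
    F = deformation_tensor(gradU)
    C = right_cauchy_green(F)
    return principal_strain_fields(C, valid, F=F, spacing=fieldv.spacing)


def strain_summary(sf: StrainField) -> StrainSummary:
    """Mean tensile/compressive magnitudes over voxels where each is present."""
    nt = int(sf.tensile_present.sum())
    nc = int(sf.compressive_present.sum())
    nv = int(sf.valid.sum())
    return StrainSummary(
        mean_tensile_mag=float(sf.tensile_mag[sf.tensile_present].mean()) if nt else 0.0,
        mean_compressive_mag=(float(sf.compressive_mag[sf.compressive_present].mean())
                              if nc else 0.0),
        n_tensile=nt, n_compressive=nc,
        n_triaxial_tense=nv - nc if nv else 0,
        n_triaxial_compressed=nv - nt if nv else 0,
        n_valid=nv)
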