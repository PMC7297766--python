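"""Procrustes superimposition and related geometry.

Covers ordinary (pairwise) and generalized Procrustes fits, the
reflect-and-relabel decomposition into symmetric and asymmetric shape
components for structures with object symmetry, thin-plate-spline
estimation of missing landmarks, and rigid merging of dorsal/ventral
digitizing views through their shared landmarks.

Shape variables are Procrustes coordinates relative to the consensus; no
explicit tangent-space projection is applied (negligible at small shape
variation scales).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .morphio import LandmarkTemplate, ShapeDataset, SpecimenRecord, TemplateError

__all__ = [
    "AlignedDataset",
    "OPAResult",
    "centroid_size",
    "opa_fit",
    "gpa_align",
    "reflect_relabel",
    "symmetric_decomposition",
    "estimate_missing_tps",
    "merge_views",
    "impute_dataset",
]

GPA_TOL = 1e-10
# scattered synthetic shapes need far more than 100 passes to reach 1e-10
GPA_MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    """GPA failed to converge within the iteration budget."""


@dataclass
class AlignedDataset:
    """Procrustes shape variables for a set of specimens.

    ``shapes`` holds the aligned configurations (unit centroid size when
    ``scaled``); ``centroid_sizes`` always keeps the original sizes in mm.
    ``component`` records which part of the symmetry decomposition these
    shapes are.
    """

    shapes: np.ndarray  # n x p x 3
    centroid_sizes: np.ndarray  # n
    consensus: np.ndarray  # p x 3
    component: str = "whole"  # whole | symmetric | asymmetric
    scaled: bool = True
    iterations: list[float] = field(default_factory=list)  # total residual per pass
    specimen_ids: list[str] = field(default_factory=list)
    metadata: "object | None" = None  # pandas frame of specimen metadata

    @property
    def n_specimens(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.shapes.shape[1]

    def flattened(self) -> np.ndarray:
        """n x 3p matrix of shape variables (landmark-major flattening)."""
        return self.shapes.reshape(self.n_specimens, -1)


@dataclass(frozen=True)
class OPAResult:
    """Least-squares superimposition of one configuration onto another."""

    fitted: np.ndarray
    residual: float
    rotation: np.ndarray  # 3x3, applied on the right: (x - mean) @ R
    scale: float
    translation: np.ndarray  # added after rotation/scale
    moving_centroid: np.ndarray  # centroid of the moving configuration

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted similarity transform to arbitrary points."""
        return self.scale * (coords - self.moving_centroid) @ self.rotation + self.translation


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared landmark distances from the centroid."""
    config = np.asarray(config, dtype=float)
    valid = np.isfinite(config).all(axis=1)
    pts = config[valid]
    if pts.shape[0] < 2:
        raise ValueError("centroid size needs >= 2 non-missing landmarks")
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def opa_fit(
    moving: np.ndarray,
    target: np.ndarray,
    allow_scale: bool = False,
    allow_reflection: bool = False,
) -> OPAResult:
    """Ordinary Procrustes fit of ``moving`` onto ``target``.

    Minimizes ``sum ||fitted - target||**2`` over translations, rotations
    (determinant +1 unless ``allow_reflection``) and, optionally, scale.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape:
        raise ValueError("configurations must share dimensions")
    mu_m = moving.mean(axis=0)
    mu_t = target.mean(axis=0)
    A = moving - mu_m
    B = target - mu_t
    if np.linalg.matrix_rank(A) < 2 or np.linalg.matrix_rank(B) < 2:
        raise ValueError("degenerate configuration (rank < 2)")
    # Kabsch via SVD of the cross-covariance
    U, s, Vt = np.linalg.svd(A.T @ B)
    sign = np.sign(np.linalg.det(U @ Vt))
    d = np.ones(len(s))
    if not allow_reflection and sign < 0:
        d[-1] = -1.0
    R = (U * d) @ Vt
    trace = float((s * d).sum())
    scale = trace / float((A**2).sum()) if allow_scale else 1.0
    fitted = scale * A @ R + mu_t
    residual = float(((fitted - target) ** 2).sum())
    return OPAResult(
        fitted=fitted,
        residual=residual,
        rotation=R,
        scale=scale,
        translation=mu_t,
        moving_centroid=mu_m,
    )


def _centre(config: np.ndarray) -> np.ndarray:
    return config - config.mean(axis=0)


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus to a deterministic orientation.

    Aligns principal axes with the coordinate axes; per-axis sign fixed by
    the coordinate's third moment (falling back to the largest-magnitude
    element), with a determinant correction on the weakest axis.  Makes GPA
    output invariant to rigid motions of the input set.
    """
    _, s, Vt = np.linalg.svd(consensus - consensus.mean(axis=0), full_matrices=False)
    V = Vt.T
    proj = (consensus - consensus.mean(axis=0)) @ V
    for j in range(3):
        skew = float((proj[:, j] ** 3).sum())
        if abs(skew) > 1e-12:
            sign = np.sign(skew)
        else:
            sign = np.sign(proj[np.argmax(np.abs(proj[:, j])), j]) or 1.0
        V[:, j] *= sign
    if np.linalg.det(V) < 0:
        V[:, int(np.argmin(s))] *= -1.0
    return V


def gpa_align(
    dataset: "ShapeDataset | np.ndarray",
    scale: bool = True,
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
) -> AlignedDataset:
    """Generalized Procrustes superimposition.

    Iteratively aligns every configuration to the running consensus until
    the change in total residual drops below ``tol``.  Deterministic: no
    randomness anywhere.  Original centroid sizes are recorded before any
    scaling.
    """
    if isinstance(dataset, ShapeDataset):
        for s in dataset.specimens:
            if s.missing_mask.any():
                raise ValueError(
                    f"specimen {s.specimen_id!r} has missing landmarks; impute before GPA"
                )
        configs = dataset.coords_array()
        ids = [s.specimen_id for s in dataset.specimens]
        meta = dataset.metadata_frame()
    else:
        configs = np.asarray(dataset, dtype=float)
        ids = [f"c{i}" for i in range(configs.shape[0])]
        meta = None
    n = configs.shape[0]
    if n < 1:
        raise ValueError("empty dataset")

    sizes = np.array([centroid_size(c) for c in configs])
    shapes = np.stack([_centre(c) for c in configs])
    if scale:
        shapes /= sizes[:, None, None]

    consensus = shapes[0].copy()
    log: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        for i in range(n):
            shapes[i] = opa_fit(shapes[i], consensus).fitted
        # re-centre to kill floating-point translation drift, which the
        # unit-size normalization would otherwise amplify geometrically
        consensus = _centre(shapes.mean(axis=0))
        if scale:
            consensus = consensus / centroid_size(consensus)
        total = float(((shapes - consensus) ** 2).sum())
        log.append(total)
        if abs(prev - total) < tol:
            break
        prev = total
    else:
        raise ConvergenceError(f"GPA did not converge; residual log: {log}")

    # final pass so stored consensus is exactly the mean of stored shapes
    for i in range(n):
        shapes[i] = opa_fit(shapes[i], consensus).fitted
    consensus = shapes.mean(axis=0)

    # canonical orientation: principal axes of the consensus, signs fixed,
    # so results are invariant to rigid motions of the input
    V = _canonical_rotation(consensus)
    shapes = shapes @ V
    consensus = consensus @ V

    return AlignedDataset(
        shapes=shapes,
        centroid_sizes=sizes,
        consensus=consensus,
        component="whole",
        scaled=scale,
        iterations=log,
        specimen_ids=ids,
        metadata=meta,
    )


def reflect_relabel(
    config: np.ndarray, template: LandmarkTemplate, axis: str = "x"
) -> np.ndarray:
    """Mirror a configuration across ``axis`` and swap bilateral labels.

    Midline landmarks keep their rows; each (left, right) pair swaps rows.
    Applying the operation twice returns the input exactly.
    """
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    out = np.asarray(config, dtype=float).copy()
    out[:, ax] *= -1.0
    for left, right in template.paired:
        i, j = template.index(left), template.index(right)
        out[[i, j]] = out[[j, i]]
    return out


def symmetric_decomposition(
    dataset: ShapeDataset, axis: str = "x", scale: bool = True
) -> tuple[AlignedDataset, AlignedDataset]:
    """Object-symmetry decomposition of a bilaterally structured dataset.

    GPA is run on the doubled set (originals plus reflected-relabelled
    copies); the symmetric component of each specimen is the mean of its two
    aligned copies and the asymmetric component the half-difference.
    Downstream shape analyses consume the symmetric component.
    """
    template = dataset.template
    if not template.paired:
        raise TemplateError("symmetric decomposition needs a template with bilateral pairs")
    originals = dataset.coords_array()
    reflected = np.stack([reflect_relabel(c, template, axis) for c in originals])
    doubled = np.concatenate([originals, reflected])
    aligned = gpa_align(doubled, scale=scale)
    n = originals.shape[0]
    orig_aligned = aligned.shapes[:n]
    refl_aligned = aligned.shapes[n:]
    sym = 0.5 * (orig_aligned + refl_aligned)
    asym = 0.5 * (orig_aligned - refl_aligned)
    sizes = aligned.centroid_sizes[:n]
    ids = [s.specimen_id for s in dataset.specimens]
    meta = dataset.metadata_frame()
    sym_ds = AlignedDataset(
        shapes=sym,
        centroid_sizes=sizes,
        consensus=sym.mean(axis=0),
        component="symmetric",
        scaled=scale,
        iterations=aligned.iterations,
        specimen_ids=ids,
        metadata=meta,
    )
    asym_ds = AlignedDataset(
        shapes=asym,
        centroid_sizes=sizes,
        consensus=asym.mean(axis=0),
        component="asymmetric",
        scaled=scale,
        iterations=aligned.iterations,
        specimen_ids=ids,
        metadata=meta,
    )
    return sym_ds, asym_ds


# ---------------------------------------------------------------------------
# thin-plate spline imputation
# ---------------------------------------------------------------------------

def _tps_system(src: np.ndarray) -> np.ndarray:
    """Assemble the 3D TPS interpolation matrix with kernel U(r) = r."""
    k = src.shape[0]
    r = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    P = np.hstack([np.ones((k, 1)), src])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = r
    L[:k, k:] = P
    L[k:, :k] = P.T
    return L


def _tps_map(src: np.ndarray, dst: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Evaluate the TPS interpolant src -> dst at ``query`` points."""
    k = src.shape[0]
    L = _tps_system(src)
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = dst
    try:
        coef = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular thin-plate-spline system") from exc
    w, a = coef[:k], coef[k:]
    r = np.linalg.norm(query[:, None, :] - src[None, :, :], axis=2)
    Pq = np.hstack([np.ones((query.shape[0], 1)), query])
    return r @ w + Pq @ a


def estimate_missing_tps(specimen: SpecimenRecord, reference: np.ndarray) -> SpecimenRecord:
    """Impute missing landmarks with a 3D thin-plate spline (kernel U(r)=r).

    The spline maps the complete ``reference`` onto the specimen's observed
    landmarks; missing positions are the images of the corresponding
    reference positions.  Observed landmarks are untouched; imputed rows are
    flagged in ``imputed_mask``.
    """
    reference = np.asarray(reference, dtype=float)
    if not specimen.missing_mask.any():
        return specimen
    observed = ~specimen.missing_mask
    if observed.sum() < 4:
        raise ValueError(
            f"specimen {specimen.specimen_id!r}: need >= 4 observed landmarks for TPS"
        )
    src = reference[observed]
    if np.linalg.matrix_rank(src - src.mean(axis=0)) < 3:
        raise ValueError(
            f"specimen {specimen.specimen_id!r}: observed landmarks are coplanar"
        )
    dst = specimen.coords[observed]
    query = reference[specimen.missing_mask]
    filled = specimen.coords.copy()
    filled[specimen.missing_mask] = _tps_map(src, dst, query)
    return replace(
        specimen,
        coords=filled,
        missing_mask=np.zeros_like(specimen.missing_mask),
        imputed_mask=specimen.imputed_mask | specimen.missing_mask,
    )


def impute_dataset(dataset: ShapeDataset) -> ShapeDataset:
    """Impute every incomplete specimen against the consensus of complete ones."""
    complete = [s for s in dataset.specimens if s.is_complete]
    if any(not s.is_complete for s in dataset.specimens):
        if len(complete) < 2:
            raise ValueError("need >= 2 complete specimens to build an imputation reference")
        reference = gpa_align(np.stack([s.coords for s in complete]), scale=False).consensus
        specimens = [
            s if s.is_complete else estimate_missing_tps(s, reference)
            for s in dataset.specimens
        ]
        return ShapeDataset(dataset.template, specimens)
    return dataset


# ---------------------------------------------------------------------------
# view merging
# ---------------------------------------------------------------------------

def merge_views(
    dorsal: SpecimenRecord,
    ventral: SpecimenRecord,
    template: LandmarkTemplate,
    max_fit_residual: float | None = None,
) -> SpecimenRecord:
    """Rigidly merge dorsal and ventral digitizations of one specimen.

    The ventral view is superimposed onto the dorsal frame (rotation and
    translation only — both views are mm measurements of the same object)
    using the landmarks labelled ``common`` in the template; after the fit
    the two copies of each common landmark are averaged.

    ``max_fit_residual`` optionally rejects merges whose common-landmark fit
    residual suggests a digitizing blunder.
    """
    common = [n for n, v in template.views.items() if v == "common"]
    idx = np.array([template.index(n) for n in common], dtype=int)
    usable = (~dorsal.missing_mask[idx]) & (~ventral.missing_mask[idx])
    if usable.sum() < 3:
        raise ValueError(
            f"specimen {dorsal.specimen_id!r}: need >= 3 common landmarks observed "
            f"in both views, have {int(usable.sum())}"
        )
    idx = idx[usable]
    fit = opa_fit(ventral.coords[idx], dorsal.coords[idx], allow_scale=False)
    if max_fit_residual is not None and fit.residual > max_fit_residual:
        raise ValueError(
            f"specimen {dorsal.specimen_id!r}: view-merge residual {fit.residual:.4g} "
            f"exceeds threshold {max_fit_residual:.4g}"
        )
    p = template.n_landmarks
    merged = np.full((p, 3), np.nan)
    missing = np.ones(p, dtype=bool)
    ventral_in_dorsal = fit.transform(ventral.coords)
    for j, name in enumerate(template.landmark_names):
        view = template.views.get(name)
        has_d = not dorsal.missing_mask[j]
        has_v = not ventral.missing_mask[j]
        if view == "common" and has_d and has_v:
            merged[j] = 0.5 * (dorsal.coords[j] + ventral_in_dorsal[j])
            missing[j] = False
        elif view in ("dorsal", "common") and has_d:
            merged[j] = dorsal.coords[j]
            missing[j] = False
        elif view in ("ventral", "common") and has_v:
            merged[j] = ventral_in_dorsal[j]
            missing[j] = False
    return SpecimenRecord(
        specimen_id=dorsal.specimen_id,
        coords=merged,
        missing_mask=missing,
        year=dorsal.year,
        period=dorsal.period,
        sex=dorsal.sex,
        replicate=dorsal.replicate,
    )
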