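"""EEG-fMRI fusion: CDR difference maps, voxel-element overlap, ROI means.

The EEG source model is a tetrahedral mesh with a current density
reconstruction (CDR) value per element and condition; subtracting the
correct-trial map from the error-trial map gives the CDR difference map of
activity unique to errors.  The fMRI contrast volume (incongruent-error
minus incongruent-correct) lives on a voxel grid with a RAS affine.  A voxel
"overlaps" an element when its centroid (affine applied to the voxel index)
falls inside the tetrahedron under a barycentric containment test; the
fusion score of a mapped voxel is the product of its contrast value and the
containing element's CDR-difference value.  Region-of-interest summaries are
plain means over contributing voxels/elements; voxels without a mapped
element are excluded (never zero-filled) and empty sets yield a missing
score, not a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TetMesh", "CDRDiffMap", "ContrastVolume", "ROIMaskVolume",
    "FusionVolume", "cdr_difference", "map_voxels_to_elements", "fuse",
    "roi_mean_volume", "roi_mean_mesh", "build_roi_score_table",
    "REGION_LABELS",
]

REGION_LABELS = {"dacc": 1, "pcc": 2}
BARY_TOL = 1e-9


@dataclass
class TetMesh:
    """Tetrahedral source mesh in world (mm) coordinates.

    ``nodes`` (N, 3); ``elements`` (E, 4) node indices; optional per-element
    CDR values per condition.  Degenerate (non-positive volume) elements are
    rejected at construction.
    """
    nodes: np.ndarray
    elements: np.ndarray
    cdr_error: Optional[np.ndarray] = None
    cdr_correct: Optional[np.ndarray] = None

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, float)
        self.elements = np.asarray(self.elements, int)
        if self.elements.min() < 0 or self.elements.max() >= len(self.nodes):
            raise ValueError("element node index out of range")
        vols = np.abs(self.volumes())
        if np.any(vols <= 1e-12):
            bad = np.where(vols <= 1e-12)[0]
            raise ValueError(f"degenerate zero-volume element(s) {bad[:5]}")
        for name in ("cdr_error", "cdr_correct"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, float)
                if v.shape != (len(self.elements),) or \
                        not np.all(np.isfinite(v)):
                    raise ValueError(f"bad {name} values")
                setattr(self, name, v)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def corners(self) -> np.ndarray:
        return self.nodes[self.elements]  # (E, 4, 3)

    def volumes(self) -> np.ndarray:
        c = self.corners()
        return np.linalg.det(c[:, 1:] - c[:, :1]) / 6.0

    def centroids(self) -> np.ndarray:
        return self.corners().mean(axis=1)


@dataclass
class CDRDiffMap:
    """Per-element error-minus-correct CDR values on a mesh geometry."""
    mesh: TetMesh
    values: np.ndarray
    ern_latency_ms: Optional[float] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.mesh.n_elements,):
            raise ValueError("diff values must match the element count")


@dataclass
class ContrastVolume:
    """fMRI contrast on a voxel grid; ``affine`` maps (i,j,k,1) to mm."""
    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.ascontiguousarray(self.data, float)
        self.affine = np.asarray(self.affine, float)
        if self.data.ndim != 3 or self.affine.shape != (4, 4):
            raise ValueError("expected 3-D data and a 4x4 affine")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite contrast values")

    def voxel_centroids(self) -> np.ndarray:
        idx = np.indices(self.data.shape).reshape(3, -1).T
        homo = np.column_stack([idx, np.ones(len(idx))])
        return (homo @ self.affine.T)[:, :3]


@dataclass
class ROIMaskVolume:
    """Integer labels on the contrast grid: 0 background, 1 dACC, 2 PCC."""
    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, float)
        extra = set(np.unique(self.labels)) - {0, 1, 2}
        if extra:
            raise ValueError(f"unexpected mask labels {sorted(extra)}")


@dataclass
class FusionVolume:
    """Contrast x CDR-difference, defined only on mapped voxels."""
    data: np.ndarray
    defined: np.ndarray
    affine: np.ndarray


def cdr_difference(mesh: TetMesh,
                   ern_latency_ms: Optional[float] = None) -> CDRDiffMap:
    """Error-trial CDR minus correct-trial CDR, per element."""
    if mesh.cdr_error is None or mesh.cdr_correct is None:
        raise ValueError("mesh lacks CDR values for one or both conditions")
    return CDRDiffMap(mesh, mesh.cdr_error - mesh.cdr_correct,
                      ern_latency_ms)


def _barycentric(corners: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of ``points`` in one tetrahedron."""
    t = (corners[1:] - corners[0]).T  # 3x3
    sol = np.linalg.solve(t, (points - corners[0]).T).T
    return np.column_stack([1.0 - sol.sum(axis=1), sol])


def map_voxels_to_elements(vol: ContrastVolume, mesh: TetMesh,
                           tol: float = BARY_TOL) -> np.ndarray:
    """Element index containing each voxel centroid, or -1.

    Containment by barycentric coordinates with tolerance ``tol``; when a
    centroid lies on a shared face the lowest element index wins.
    """
    pts = vol.voxel_centroids()
    owner = np.full(len(pts), -1, dtype=int)
    corners = mesh.corners()
    lo = corners.min(axis=1) - tol
    hi = corners.max(axis=1) + tol
    for e in range(mesh.n_elements):
        cand = np.where((owner < 0)
                        & np.all(pts >= lo[e], axis=1)
                        & np.all(pts <= hi[e], axis=1))[0]
        if len(cand) == 0:
            continue
        bary = _barycentric(corners[e], pts[cand])
        inside = np.all(bary >= -tol, axis=1)
        owner[cand[inside]] = e
    return owner


def fuse(vol: ContrastVolume, diff: CDRDiffMap,
         vmap: np.ndarray) -> FusionVolume:
    """Multiply each mapped voxel's contrast by its element's CDR difference."""
    vmap = np.asarray(vmap, int)
    if vmap.shape != (vol.data.size,):
        raise ValueError("voxel-element map does not match the volume grid")
    if vmap.max() >= diff.mesh.n_elements:
        raise ValueError("voxel-element map refers to unknown elements")
    vm = vmap.reshape(vol.data.shape)
    defined = vm >= 0
    out = np.where(defined,
                   vol.data * diff.values[np.clip(vm, 0, None)], np.nan)
    return FusionVolume(out, defined, vol.affine)


def roi_mean_volume(values, mask: ROIMaskVolume,
                    region: str) -> Tuple[float, int]:
    """Mean over voxels carrying the region label and a defined value.

    Accepts a :class:`ContrastVolume` (all voxels defined) or a
    :class:`FusionVolume` (only mapped voxels defined).  Returns
    ``(mean, n_voxels)``; an empty contributing set yields ``(nan, 0)``.
    """
    label = REGION_LABELS[region]
    if not np.any(mask.labels == label):
        raise ValueError(f"region {region!r} has no voxels in the mask")
    if isinstance(values, FusionVolume):
        ok = values.defined & (mask.labels == label)
    else:
        if values.data.shape != mask.labels.shape or \
                not np.allclose(values.affine, mask.affine):
            raise ValueError("volume and mask grids do not match")
        ok = mask.labels == label
    n = int(ok.sum())
    if n == 0:
        return float("nan"), 0
    return float(values.data[ok].mean()), n


def roi_mean_mesh(diff: CDRDiffMap, mask: ROIMaskVolume,
                  region: str) -> Tuple[float, int]:
    """Mean CDR difference over elements whose centroid lies in the region."""
    label = REGION_LABELS[region]
    if not np.any(mask.labels == label):
        raise ValueError(f"region {region!r} has no voxels in the mask")
    cent = diff.mesh.centroids()
    inv = np.linalg.inv(mask.affine)
    homo = np.column_stack([cent, np.ones(len(cent))])
    ijk = np.round((homo @ inv.T)[:, :3]).astype(int)
    ok = np.all((ijk >= 0) & (ijk < mask.labels.shape), axis=1)
    sel = np.zeros(len(cent), bool)
    sel[ok] = mask.labels[tuple(ijk[ok].T)] == label
    n = int(sel.sum())
    if n == 0:
        return float("nan"), 0
    return float(diff.values[sel].mean()), n


def build_roi_score_table(entries) -> pd.DataFrame:
    """Tidy ROI score table from per-subject/wave fusion artifacts.

    ``entries`` yields dicts with keys ``subject``, ``wave``, ``mesh``
    (TetMesh with both CDR conditions), ``volume`` (ContrastVolume),
    ``mask`` (ROIMaskVolume), optional ``vmap`` (precomputed voxel-element
    map) and ``ern_latency_ms``.  A missing mesh or volume propagates as a
    missing score (fusion requires both); nothing is fabricated.
    """
    rows = []
    for ent in entries:
        subject, wave = ent["subject"], ent["wave"]
        mesh, vol, mask = ent.get("mesh"), ent.get("volume"), ent["mask"]
        latency = ent.get("ern_latency_ms")
        diff = cdr_difference(mesh, latency) if mesh is not None else None
        vmap = None
        if mesh is not None and vol is not None:
            vmap = ent.get("vmap")
            if vmap is None:
                vmap = map_voxels_to_elements(vol, mesh)
            fused = fuse(vol, diff, vmap)
        for region in REGION_LABELS:
            scores = {
                "eeg": roi_mean_mesh(diff, mask, region)
                if diff is not None else (float("nan"), 0),
                "fmri": roi_mean_volume(vol, mask, region)
                if vol is not None else (float("nan"), 0),
                "fusion": roi_mean_volume(fused, mask, region)
                if vmap is not None else (float("nan"), 0),
            }
            for modality, (score, n) in scores.items():
                rows.append({"subject": subject, "wave": wave,
                             "modality": modality, "region": region,
                             "score": score, "n_voxels_or_elements": n,
                             "ern_latency_ms": latency})
    return pd.DataFrame(rows)
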