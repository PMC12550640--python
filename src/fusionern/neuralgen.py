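"""Synthetic neural data: shared geometry, planted ROI signals, EEG epochs.

The mesh and voxel grid share one bounding box.  Each axis-aligned cube of
the mesh lattice is split into five tetrahedra with alternating parity so
faces conform and the box is tiled exactly; every voxel centroid therefore
falls inside some element.  Signals are planted so that the downstream ROI
means recover the subject's true activations:

* EEG: in-ROI elements carry the true EEG activation in the error-condition
  CDR (correct-condition CDR is pure background), so the ROI mean of the
  CDR difference equals the truth plus element noise.
* fMRI: in-ROI voxels carry the true fMRI activation in the contrast.
* fusion: the product construction means the fusion ROI mean recovers the
  product of the EEG and fMRI truths (exactly so at zero noise); that
  product is the fusion modality's "true activation" in this generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .config import EpochParams, GeneratorConfig, GeometryParams
from .erp import CORRECT, ERROR, EpochSet
from .fusion import (ContrastVolume, ROIMaskVolume, TetMesh,
                     map_voxels_to_elements)

__all__ = ["NeuralGeometry", "build_geometry", "plant_subject_wave",
           "simulate_epochs", "generate_neural_data"]

# five-tetrahedron cube decomposition, by cube-corner offsets; the odd
# parity is the x-mirror so shared faces conform across neighboring cubes
_TETS_EVEN = [
    ((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)),
    ((1, 1, 0), (1, 0, 0), (0, 1, 0), (1, 1, 1)),
    ((1, 0, 1), (1, 0, 0), (0, 0, 1), (1, 1, 1)),
    ((0, 1, 1), (0, 1, 0), (0, 0, 1), (1, 1, 1)),
    ((1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)),
]
_TETS_ODD = [tuple((1 - x, y, z) for x, y, z in tet) for tet in _TETS_EVEN]


@dataclass
class NeuralGeometry:
    """Shared mesh/grid geometry with the ROI mask and voxel-element map."""
    mesh: TetMesh
    mask: ROIMaskVolume
    affine: np.ndarray
    element_region: np.ndarray   # 0 background, else REGION_LABELS value
    vmap: np.ndarray


def _grid_affine(geo: GeometryParams) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = geo.voxel_size_mm
    return aff


def _build_mask(geo: GeometryParams) -> ROIMaskVolume:
    labels = np.zeros(geo.grid_shape, dtype=np.int16)
    for label, box in ((1, geo.dacc_box), (2, geo.pcc_box)):
        sl = tuple(slice(a, b) for a, b in box)
        if labels[sl].size == 0:
            raise ValueError(f"ROI box {box} selects no voxels")
        labels[sl] = label
    return ROIMaskVolume(labels, _grid_affine(geo))


def _build_mesh(geo: GeometryParams) -> TetMesh:
    vs, cube = geo.voxel_size_mm, geo.mesh_cube_mm
    extent = np.array(geo.grid_shape) * vs
    ncubes = extent / cube
    if not np.allclose(ncubes, np.round(ncubes)):
        raise ValueError("grid extent must be a multiple of the cube size")
    ncubes = np.round(ncubes).astype(int)
    axes = [(-0.5 * vs) + cube * np.arange(n + 1) for n in ncubes]
    nodes = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1
                     ).reshape(-1, 3)
    nx, ny, nz = ncubes + 1

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    elements = []
    for i in range(ncubes[0]):
        for j in range(ncubes[1]):
            for k in range(ncubes[2]):
                tets = _TETS_EVEN if (i + j + k) % 2 == 0 else _TETS_ODD
                for tet in tets:
                    elements.append([nid(i + dx, j + dy, k + dz)
                                     for dx, dy, dz in tet])
    return TetMesh(nodes, np.asarray(elements, int))


def build_geometry(geo: GeometryParams) -> NeuralGeometry:
    mesh = _build_mesh(geo)
    mask = _build_mask(geo)
    vol = ContrastVolume(np.zeros(geo.grid_shape), mask.affine)
    vmap = map_voxels_to_elements(vol, mesh)
    # element ROI membership: centroid falls in a labeled voxel
    cent = mesh.centroids()
    inv = np.linalg.inv(mask.affine)
    ijk = np.round((np.column_stack([cent, np.ones(len(cent))])
                    @ inv.T)[:, :3]).astype(int)
    ok = np.all((ijk >= 0) & (ijk < mask.labels.shape), axis=1)
    region = np.zeros(mesh.n_elements, dtype=np.int16)
    region[ok] = mask.labels[tuple(ijk[ok].T)]
    return NeuralGeometry(mesh, mask, mask.affine, region, vmap)


def plant_subject_wave(geometry: NeuralGeometry, truth_row, wave: str,
                       config: GeneratorConfig, rng):
    """Per-subject/wave mesh CDR values and contrast volume.

    ``truth_row`` is a row of the latent-truth table; wave-15 activation is
    baseline plus change.  Returns ``(mesh_with_cdr, contrast_volume)``.
    """
    geo = config.geometry

    def activation(mod, reg):
        lev = truth_row[f"{mod}_{reg}_13"]
        if wave == "15":
            lev = lev + truth_row[f"{mod}_{reg}_change"]
        return float(lev)

    e = geometry.mesh.n_elements
    cdr_error = rng.normal(0.0, geo.cdr_noise_sd, e) \
        if geo.cdr_noise_sd > 0 else np.zeros(e)
    cdr_correct = rng.normal(0.0, geo.cdr_noise_sd, e) \
        if geo.cdr_noise_sd > 0 else np.zeros(e)
    contrast = rng.normal(0.0, geo.contrast_noise_sd, geo.grid_shape) \
        if geo.contrast_noise_sd > 0 else np.zeros(geo.grid_shape)
    for reg, label in (("dacc", 1), ("pcc", 2)):
        cdr_error[geometry.element_region == label] += activation("eeg", reg)
        contrast[geometry.mask.labels == label] += activation("fmri", reg)
    mesh = TetMesh(geometry.mesh.nodes, geometry.mesh.elements,
                   cdr_error=cdr_error, cdr_correct=cdr_correct)
    return mesh, ContrastVolume(contrast, geometry.affine)


def simulate_epochs(true_eeg_dacc: float, ep: EpochParams, rng) -> EpochSet:
    """Epoched EEG with an ERN planted on error trials.

    Error trials carry a negative Gaussian-shaped deflection at the
    configured latency on the frontocentral channels, with amplitude
    ``ern_gain * true_eeg_dacc`` microvolt; correct trials are noise only.
    """
    time_ms = np.arange(ep.t_min_ms, ep.t_max_ms + 1e-9,
                        1000.0 / ep.sampling_rate)
    if not (time_ms[0] <= ep.ern_latency_ms <= time_ms[-1]):
        raise ValueError("epoch window does not cover the ERN latency")
    n_ch, n_t = len(ep.channels), len(time_ms)
    n_tr = ep.n_error_trials + ep.n_correct_trials
    data = rng.normal(0.0, ep.noise_sd, (n_ch, n_t, n_tr)) \
        if ep.noise_sd > 0 else np.zeros((n_ch, n_t, n_tr))
    condition = np.array([ERROR] * ep.n_error_trials
                         + [CORRECT] * ep.n_correct_trials)
    bump = np.exp(-0.5 * ((time_ms - ep.ern_latency_ms)
                          / (ep.ern_width_ms / 2.0)) ** 2)
    amp = ep.ern_gain * true_eeg_dacc
    fc = [ep.channels.index(c) for c in ep.frontocentral]
    for ch in fc:
        data[ch, :, :ep.n_error_trials] += (amp * bump)[:, None]
    return EpochSet(ep.sampling_rate, time_ms, tuple(ep.channels), data,
                    condition)


def generate_neural_data(truth, config: GeneratorConfig,
                         seed: Optional[int] = None,
                         geometry: Optional[NeuralGeometry] = None):
    """Yield per-subject/wave neural artifacts for the whole cohort.

    Generates ``(subject_id, wave, mesh, contrast_volume, epochs)`` lazily
    (memory stays flat for large cohorts); the shared geometry is built once.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    if geometry is None:
        geometry = build_geometry(cfg.geometry)
    for _, row in truth.iterrows():
        for wave in ("13", "15"):
            mesh, vol = plant_subject_wave(geometry, row, wave, cfg, rng)
            act = row["eeg_dacc_13"] + (row["eeg_dacc_change"]
                                        if wave == "15" else 0.0)
            epochs = simulate_epochs(float(act), cfg.epochs, rng)
            yield row["subject_id"], wave, mesh, vol, epochs
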