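"""Voxel- and component-level preprocessing.

Turns fMRI matrices into the reduced, windowed, batched sequences the trainer
consumes: global-mean masking, per-voxel variance normalization, 4th-degree
polynomial detrending, PCA reduction (no whitening) on the subject-stacked
matrix, per-component mean removal, then sliding-window segmentation.

Windowing convention: each window reserves the frame immediately before it as
initial-state input and carries one following target frame, so a sequence of
T frames yields T - w - 1 stride-1 windows (249 frames, w = 20 -> 228).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class VoxelDataset:
    """Per-subject (time x voxels) matrices sharing one voxel grid."""

    data: list  # list of (T, V) arrays
    mask: np.ndarray | None = None
    tr: float = 2.0

    def __post_init__(self):
        shapes = {d.shape[1] for d in self.data}
        if len(shapes) != 1:
            raise ValueError("all subjects must share the voxel count")
        if any(d.shape[0] < 2 for d in self.data):
            raise ValueError("every subject needs at least 2 time points")


@dataclass
class ReducedDataset:
    """PCA-reduced per-subject sequences (N x T x D) plus the spatial basis."""

    sequences: np.ndarray            # (N, T, D)
    spatial_basis: np.ndarray | None = None  # (V, D)
    subject_ids: list = field(default_factory=list)
    group_labels: np.ndarray | None = None
    tr: float = 2.0

    def __post_init__(self):
        self.sequences = np.asarray(self.sequences, dtype=float)
        if self.sequences.ndim != 3:
            raise ValueError("sequences must be (subjects, time, components)")
        n, t, d = self.sequences.shape
        if n < 1 or t < 3:
            raise ValueError("need at least 1 subject and 3 time points")
        if self.spatial_basis is not None and self.spatial_basis.shape[1] != d:
            raise ValueError("spatial basis column count must equal D")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:04d}" for i in range(n)]

    @property
    def n_subjects(self):
        return self.sequences.shape[0]

    @property
    def n_timepoints(self):
        return self.sequences.shape[1]

    @property
    def dim(self):
        return self.sequences.shape[2]


@dataclass
class WindowSet:
    """Window slices: (subject, start) pairs; the slice models frames
    [start, start + w] with context frame start - 1."""

    slices: list  # list of (subject_index, start_index)
    window: int
    stride: int
    dataset: ReducedDataset

    def __len__(self):
        return len(self.slices)

    def gather(self, indices):
        """Assemble (B, w+1, D) frames and (B, D) context for given slices."""
        seq = self.dataset.sequences
        w = self.window
        frames = np.stack([seq[s, st:st + w + 1] for s, st in (self.slices[i] for i in indices)])
        context = np.stack([seq[s, st - 1] for s, st in (self.slices[i] for i in indices)])
        return frames, context


def global_mean_mask(voxel_data: VoxelDataset) -> np.ndarray:
    """Mask voxels whose mean (over all subjects and time) falls below the
    overall mean of the mean image."""
    stacked = np.concatenate([np.asarray(d, dtype=float) for d in voxel_data.data], axis=0)
    if not np.all(np.isfinite(stacked)):
        raise ValueError("voxel data contains non-finite values")
    mean_image = stacked.mean(axis=0)
    mask = mean_image >= mean_image.mean()
    if not mask.any():
        raise ValueError("global-mean mask removed every voxel; check input scaling")
    return mask


def variance_normalize(ts: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Divide by the sample SD (no recentering). Zero-variance series come
    back as NaN and are flagged by the caller."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    sd = ts.std(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = ts / sd
    out = np.where(sd == 0, np.nan, out)
    return out


def polynomial_detrend(ts: np.ndarray, degree: int = 4) -> np.ndarray:
    """Residuals of a least-squares polynomial fit over the time index."""
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[0]
    if T <= degree:
        raise ValueError(f"series length {T} too short for degree-{degree} detrend")
    t = np.arange(T, dtype=float)
    t = (t - t.mean()) / max(t.std(), 1.0)  # conditioning
    basis = np.vander(t, degree + 1)
    coef, *_ = np.linalg.lstsq(basis, ts, rcond=None)
    return ts - basis @ coef


def preprocess_voxels(voxel_data: VoxelDataset, detrend_degree: int = 4):
    """Mask, variance-normalize and detrend every subject; returns the list of
    cleaned (T, V_in_mask) matrices plus the mask (zero-variance voxels
    dropped from the mask with a warning)."""
    mask = global_mean_mask(voxel_data)
    cleaned = []
    masked = [np.asarray(d, dtype=float)[:, mask] for d in voxel_data.data]
    sds = np.stack([d.std(axis=0, ddof=1) for d in masked])
    degenerate = (sds == 0).any(axis=0)
    if degenerate.any():
        warnings.warn(f"dropping {int(degenerate.sum())} zero-variance voxels")
        idx = np.flatnonzero(mask)
        mask = mask.copy()
        mask[idx[degenerate]] = False
        masked = [d[:, ~degenerate] for d in masked]
    for d in masked:
        vn = variance_normalize(d)
        cleaned.append(polynomial_detrend(vn, degree=detrend_degree))
    return cleaned, mask


def pca_reduce(matrices: list, k: int, subject_ids=None, group_labels=None,
               tr: float = 2.0) -> ReducedDataset:
    """PCA on the subject-concatenated (time-stacked) matrix; keep the top-k
    spatial directions, no whitening, then remove each component time
    course's mean per subject.

    The sign of each principal direction is fixed so its largest-magnitude
    weight is positive.
    """
    stacked = np.concatenate([np.asarray(m, dtype=float) for m in matrices], axis=0)
    total_t, v = stacked.shape
    if k > min(total_t, v):
        raise ValueError(f"k={k} exceeds min(time={total_t}, voxels={v})")
    col_mean = stacked.mean(axis=0)
    centered = stacked - col_mean
    # thin SVD of the centered stack: right singular vectors = spatial PCs
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(svals > svals[0] * max(total_t, v) * np.finfo(float).eps))
    if k > rank:
        raise ValueError(f"k={k} exceeds achievable rank {rank}")
    basis = vt[:k].T  # (V, k)
    flip = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    basis = basis * flip

    seqs, start = [], 0
    for m in matrices:
        t = m.shape[0]
        load = centered[start:start + t] @ basis
        load = load - load.mean(axis=0)  # per-component mean removal
        seqs.append(load)
        start += t
    return ReducedDataset(sequences=np.stack(seqs), spatial_basis=basis,
                          subject_ids=list(subject_ids) if subject_ids else [],
                          group_labels=group_labels, tr=tr)


def window_segments(dataset: ReducedDataset, w: int, stride: int = 1) -> WindowSet:
    """Stride-`stride` windows starting at frame 1 (frame 0 is the reserved
    initial-state input); each window needs one following target frame, so
    starts run over 1 .. T - w - 1 and the stride-1 count is T - w - 1."""
    T = dataset.n_timepoints
    if T < w + 2:
        raise ValueError(f"sequence length {T} < w + 2 = {w + 2}: no valid window")
    starts = range(1, T - w, stride)
    slices = [(s, st) for s in range(dataset.n_subjects) for st in starts]
    return WindowSet(slices=slices, window=w, stride=stride, dataset=dataset)


def make_batches(windows: WindowSet, batch_size: int, rng) -> list:
    """Seeded shuffle of all window slices, partitioned into batches of index
    arrays; the final short batch is kept."""
    if len(windows) == 0:
        raise ValueError("empty window set")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    order = rng.permutation(len(windows))
    return [order[i:i + batch_size] for i in range(0, len(order), batch_size)]


# ---------------------------------------------------------------------------
# persistence / external formats
# ---------------------------------------------------------------------------


def save_reduced(path, dataset: ReducedDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("sequences", data=dataset.sequences)
        if dataset.spatial_basis is not None:
            f.create_dataset("spatial_basis", data=dataset.spatial_basis)
        f.create_dataset("subject_ids",
                         data=np.array(dataset.subject_ids, dtype=h5py.string_dtype()))
        if dataset.group_labels is not None:
            f.create_dataset("group_labels", data=np.asarray(dataset.group_labels, dtype=int))
        f.attrs["tr"] = dataset.tr


def load_reduced(path) -> ReducedDataset:
    with h5py.File(path, "r") as f:
        kw = {"sequences": f["sequences"][()], "tr": float(f.attrs.get("tr", 2.0))}
        if "spatial_basis" in f:
            kw["spatial_basis"] = f["spatial_basis"][()]
        if "subject_ids" in f:
            kw["subject_ids"] = [s.decode() if isinstance(s, bytes) else str(s)
                                 for s in f["subject_ids"][()]]
        if "group_labels" in f:
            kw["group_labels"] = f["group_labels"][()]
    return ReducedDataset(**kw)


def read_timecourse_manifest(manifest_path) -> ReducedDataset:
    """Read pre-reduced component time courses from a CSV manifest with
    columns ``subject,path[,group]``; each referenced file holds rows = time,
    columns = components."""
    import os

    man = pd.read_csv(manifest_path)
    if "path" not in man.columns:
        raise ValueError("manifest needs a 'path' column")
    base = os.path.dirname(str(manifest_path))
    seqs, ids = [], []
    for _, row in man.iterrows():
        p = row["path"]
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        seqs.append(pd.read_csv(p).to_numpy(dtype=float))
        ids.append(str(row.get("subject", len(ids))))
    groups = man["group"].to_numpy() if "group" in man.columns else None
    return ReducedDataset(sequences=np.stack(seqs), subject_ids=ids, group_labels=groups)


def save_mask_nifti(path, mask: np.ndarray, shape, affine=None) -> None:
    """Write a boolean voxel mask back to a 3-D NIfTI volume."""
    import nibabel as nib

    vol = np.asarray(mask, dtype=np.uint8).reshape(shape)
    nib.save(nib.Nifti1Image(vol, affine if affine is not None else np.eye(4)),
             str(path))


def load_nifti_subjects(paths, mask_path=None):
    """Read 4-D NIfTI volumes into a VoxelDataset (voxels flattened)."""
    import nibabel as nib

    data, tr = [], 2.0
    for p in paths:
        img = nib.load(str(p))
        arr = np.asarray(img.get_fdata(), dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"{p}: expected a 4-D volume")
        zooms = img.header.get_zooms()
        if len(zooms) >= 4 and zooms[3] > 0:
            tr = float(zooms[3])
        data.append(arr.reshape(-1, arr.shape[3]).T)  # (T, V)
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()).reshape(-1) > 0
    return VoxelDataset(data=data, mask=mask, tr=tr)
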