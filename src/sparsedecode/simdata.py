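"""Synthetic block-design fMRI generator.

Produces two-run, three-task datasets on a square voxel grid: spatial
sources times HRF-convolved time courses on a constant baseline, plus
Gaussian noise scaled to a requested contrast-to-noise ratio (CNR =
task response amplitude / noise standard deviation at a voxel).

Default geometry follows the reference design: a 50 x 50 grid, 27
spatial sources, baseline intensity 800, task-block amplitude 1.5,
shared-region amplitude 2, unique-event amplitude 1, and a paradigm of
twelve 40 s task blocks (four per task) alternating with twelve 20 s
rest blocks at TR = 2 s.  Every dimension is configurable so tests can
run at desk scale.

Two dataset groups are supported: group 1 uses one task-ROI layout for
both runs (same tasks at train and test time); group 2 uses disjoint
task-ROI layouts between run 1 and run 2 (cross-decoding).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.stats import gamma as gamma_dist

__all__ = [
    "Paradigm",
    "SourceMap",
    "SimulatedRun",
    "TrainTestDataset",
    "canonical_hrf",
    "make_paradigm",
    "make_source_map",
    "generate_run",
    "generate_group",
    "save_collection",
    "load_collection",
    "export_nifti",
]

REST = 0  # label used for rest volumes

# fractional (row0, row1, col0, col1) task-ROI rectangles per layout.
# "a" serves group 1 and group-2 run 1.  "b" (group-2 run 2) holds each
# task's ROI at a shifted location: half of its columns are novel, half
# overlap the run-1 ROI of the same task.  Cross-decoding needs that
# partial overlap — with fully disjoint task regions no classifier can
# transfer labels to the novel tasks and every method sits at chance.
_TASK_LAYOUTS = {
    "a": [
        (0.03, 0.36, 0.03, 0.36),
        (0.03, 0.36, 0.62, 0.95),
        (0.62, 0.95, 0.03, 0.36),
    ],
    "b": [
        (0.195, 0.525, 0.03, 0.36),
        (0.195, 0.525, 0.62, 0.95),
        (0.62, 0.95, 0.195, 0.525),
    ],
}
_SHARED_RECT = (0.44, 0.56, 0.44, 0.56)


@dataclass(frozen=True)
class Paradigm:
    """Block paradigm: alternating task and rest blocks on a TR grid."""

    tr_seconds: float = 2.0
    block_length_task: float = 40.0
    block_length_rest: float = 20.0
    n_blocks_per_task: int = 4
    task_order: tuple = ()  # length n_tasks * n_blocks_per_task
    n_tasks: int = 3

    def __post_init__(self) -> None:
        if len(self.task_order) != self.n_tasks * self.n_blocks_per_task:
            raise ValueError("task_order length must equal n_tasks * n_blocks_per_task")
        for t in (self.block_length_task, self.block_length_rest):
            if (t / self.tr_seconds) % 1 != 0:
                raise ValueError("block lengths must align to the TR grid")

    @property
    def n_task_blocks(self) -> int:
        return len(self.task_order)

    @property
    def n_volumes(self) -> int:
        cycle = self.block_length_task + self.block_length_rest
        return int(round(self.n_task_blocks * cycle / self.tr_seconds))

    def volume_labels(self) -> np.ndarray:
        """Per-volume condition: task id during task blocks, REST otherwise."""
        task_vols = int(self.block_length_task / self.tr_seconds)
        rest_vols = int(self.block_length_rest / self.tr_seconds)
        labels = []
        for task in self.task_order:
            labels.extend([task] * task_vols)
            labels.extend([REST] * rest_vols)
        return np.asarray(labels)

    def boxcar(self, task: int) -> np.ndarray:
        """0/1 regressor marking the volumes of one task."""
        return (self.volume_labels() == task).astype(float)

    def boxcar_union(self) -> np.ndarray:
        """0/1 regressor marking all task volumes."""
        return (self.volume_labels() != REST).astype(float)


def make_paradigm(
    seed: int,
    n_tasks: int = 3,
    n_blocks_per_task: int = 4,
    tr_seconds: float = 2.0,
    block_length_task: float = 40.0,
    block_length_rest: float = 20.0,
) -> Paradigm:
    """Pseudo-random block order from a seed; counts per task are exact.

    Datasets that must share a block order (all subjects at one noise
    level) are given the same seed.
    """
    rng = np.random.default_rng(seed)
    order = np.repeat(np.arange(1, n_tasks + 1), n_blocks_per_task)
    rng.shuffle(order)
    return Paradigm(
        tr_seconds=tr_seconds,
        block_length_task=block_length_task,
        block_length_rest=block_length_rest,
        n_blocks_per_task=n_blocks_per_task,
        task_order=tuple(int(t) for t in order),
        n_tasks=n_tasks,
    )


def canonical_hrf(tr_seconds: float = 2.0, duration: float = 32.0) -> np.ndarray:
    """Double-gamma hemodynamic response sampled at the TR.

    Difference of two gamma densities (peak ~5 s, undershoot ~15 s),
    rescaled to unit peak height.
    """
    t = np.arange(0.0, duration, tr_seconds)
    peak = gamma_dist.pdf(t, a=6.0, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def _rect_mask(grid_shape, rect) -> np.ndarray:
    H, W = grid_shape
    r0, r1, c0, c1 = rect
    mask = np.zeros(grid_shape, dtype=bool)
    mask[int(r0 * H) : int(r1 * H), int(c0 * W) : int(c1 * W)] = True
    return mask


@dataclass(frozen=True)
class SourceMap:
    """Spatial layout of one run: task ROIs, shared ROI, nuisance sources."""

    grid_shape: tuple = (50, 50)
    task_maps: np.ndarray = None  # (n_tasks, H, W), 0/1-valued before transform
    shared_map: np.ndarray = None  # (H, W)
    noise_maps: np.ndarray = None  # (n_noise_sources, H, W)
    task_amplitude: float = 1.5
    shared_amplitude: float = 2.0
    unique_amplitude: float = 1.0
    baseline: float = 800.0

    @property
    def n_tasks(self) -> int:
        return self.task_maps.shape[0]

    @property
    def n_sources(self) -> int:
        return self.task_maps.shape[0] + 1 + self.noise_maps.shape[0]

    def task_roi_mask(self, task: int) -> np.ndarray:
        """Boolean voxel mask of one task's ROI (1-based task id)."""
        return self.task_maps[task - 1] > 0

    def transformed(self, translation=(0.0, 0.0), rotation_deg=0.0, scale=1.0):
        """Rigid+scale perturbation of every spatial map (subject variation)."""

        def warp(img):
            out = img.astype(float)
            if rotation_deg:
                out = ndimage.rotate(out, rotation_deg, reshape=False, order=1)
            if scale != 1.0:
                out = ndimage.zoom(out, scale, order=1)
                out = _crop_or_pad(out, img.shape)
            if any(translation):
                out = ndimage.shift(out, translation, order=1)
            return out

        return replace(
            self,
            task_maps=np.stack([warp(m) for m in self.task_maps]),
            shared_map=warp(self.shared_map),
            noise_maps=np.stack([warp(m) for m in self.noise_maps]),
        )


def _crop_or_pad(img: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=img.dtype)
    h = min(img.shape[0], shape[0])
    w = min(img.shape[1], shape[1])
    src0 = ((img.shape[0] - h) // 2, (img.shape[1] - w) // 2)
    dst0 = ((shape[0] - h) // 2, (shape[1] - w) // 2)
    out[dst0[0] : dst0[0] + h, dst0[1] : dst0[1] + w] = img[
        src0[0] : src0[0] + h, src0[1] : src0[1] + w
    ]
    return out


def make_source_map(
    layout: str = "a",
    grid_shape: tuple = (50, 50),
    n_sources: int = 27,
    n_tasks: int = 3,
    seed: int = 0,
) -> SourceMap:
    """Build the spatial sources of one run.

    ``n_tasks`` rectangular task ROIs (positions from ``layout``), one
    shared central ROI engaged by every task, and the remainder as
    nuisance blobs with heavy-tailed (Laplace-drawn) peak weights at
    seeded random positions.
    """
    if layout not in _TASK_LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {sorted(_TASK_LAYOUTS)}")
    if n_sources < n_tasks + 2:
        raise ValueError("need at least n_tasks + 2 sources")
    rects = _TASK_LAYOUTS[layout][:n_tasks]
    task_maps = np.stack([_rect_mask(grid_shape, r).astype(float) for r in rects])
    shared_map = _rect_mask(grid_shape, _SHARED_RECT).astype(float)

    rng = np.random.default_rng(seed)
    H, W = grid_shape
    yy, xx = np.mgrid[0:H, 0:W]
    n_noise = n_sources - n_tasks - 1
    # nuisance sources live outside the task-responsive regions so ROI
    # voxels carry pure task responses in the noiseless limit
    keep_out = (task_maps.sum(axis=0) + shared_map) > 0
    blobs = []
    for _ in range(n_noise):
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        sigma = rng.uniform(0.04, 0.10) * min(H, W)
        peak = rng.laplace(loc=0.0, scale=1.0)  # super-Gaussian weights
        blob = peak * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        blob[np.abs(blob) < 0.02 * np.abs(peak)] = 0.0  # compact support
        blob[keep_out] = 0.0
        blobs.append(blob)
    return SourceMap(
        grid_shape=grid_shape,
        task_maps=task_maps,
        shared_map=shared_map,
        noise_maps=np.stack(blobs),
    )


@dataclass
class SimulatedRun:
    """One generated run: data plus all bookkeeping needed to decode it."""

    data: np.ndarray  # (n_volumes, n_voxels)
    volume_labels: np.ndarray
    paradigm: Paradigm
    cnr: float
    subject_id: int
    seed: int
    group: int
    grid_shape: tuple
    source_map: SourceMap = field(repr=False, default=None)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def _unique_event_course(n_volumes: int, hrf: np.ndarray, rng, p: float = 0.2):
    events = (rng.random(n_volumes) < p).astype(float)
    return np.convolve(events, hrf)[:n_volumes]


def generate_run(
    paradigm: Paradigm,
    source_map: SourceMap,
    cnr: float,
    subject_transform: dict | None = None,
    seed: int = 0,
    noise_sd: float | None = None,
    head_motion: bool = False,
    group: int = 1,
    subject_id: int = 0,
) -> SimulatedRun:
    """Generate one run of synthetic BOLD data.

    The signal is ``baseline + sum_s timecourse_s(t) * map_s(v)``: task
    ROIs follow their task's box-car at the task amplitude (the shared
    ROI follows the union box-car at its own amplitude), nuisance
    sources follow HRF-convolved Bernoulli unique events.  I.i.d.
    Gaussian noise is added with SD ``task_amplitude / cnr`` so that the
    response-amplitude-to-noise ratio at a task voxel equals ``cnr``
    (pass ``noise_sd=0.0`` for a noiseless run).
    """
    if cnr <= 0:
        raise ValueError("cnr must be > 0")
    rng = np.random.default_rng(seed)
    if subject_transform:
        source_map = source_map.transformed(**subject_transform)

    hrf = canonical_hrf(paradigm.tr_seconds)
    T = paradigm.n_volumes
    H, W = source_map.grid_shape
    signal = np.zeros((T, H * W))

    for task in range(1, source_map.n_tasks + 1):
        tc = np.convolve(source_map.task_amplitude * paradigm.boxcar(task), hrf)[:T]
        signal += np.outer(tc, source_map.task_maps[task - 1].ravel())
    tc = np.convolve(source_map.shared_amplitude * paradigm.boxcar_union(), hrf)[:T]
    signal += np.outer(tc, source_map.shared_map.ravel())
    for blob in source_map.noise_maps:
        tc = source_map.unique_amplitude * _unique_event_course(T, hrf, rng)
        signal += np.outer(tc, blob.ravel())

    if noise_sd is None:
        noise_sd = source_map.task_amplitude / cnr
    data = source_map.baseline + signal
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)

    if head_motion:
        data = _apply_head_motion(data, (H, W), rng)

    return SimulatedRun(
        data=data,
        volume_labels=paradigm.volume_labels(),
        paradigm=paradigm,
        cnr=cnr,
        subject_id=subject_id,
        seed=seed,
        group=group,
        grid_shape=(H, W),
        source_map=source_map,
    )


def _apply_head_motion(data: np.ndarray, grid_shape, rng) -> np.ndarray:
    """Simplified rigid drift: a bounded random walk of per-volume
    translation (< 2% of the field) and rotation (< 5 degrees)."""
    H, W = grid_shape
    max_shift = 0.02 * min(H, W)
    T = data.shape[0]
    steps = rng.normal(0.0, 0.05, size=(T, 3))  # dy, dx, dtheta increments
    path = np.clip(np.cumsum(steps, axis=0), -1.0, 1.0)
    out = np.empty_like(data)
    for t in range(T):
        frame = data[t].reshape(H, W)
        dy, dx = path[t, 0] * max_shift, path[t, 1] * max_shift
        theta = path[t, 2] * 5.0
        frame = ndimage.rotate(frame, theta, reshape=False, order=1, mode="nearest")
        frame = ndimage.shift(frame, (dy, dx), order=1, mode="nearest")
        out[t] = frame.ravel()
    return out


@dataclass
class TrainTestDataset:
    """One (subject, CNR) record: a training run and a testing run."""

    subject_id: int
    cnr: float
    group: int
    train: SimulatedRun
    test: SimulatedRun


def generate_group(
    group: int,
    n_subjects: int = 12,
    cnr_levels=None,
    master_seed: int = 0,
    grid_shape: tuple = (50, 50),
    n_sources: int = 27,
    n_tasks: int = 3,
    head_motion: bool = False,
    paradigm_kwargs: dict | None = None,
) -> list:
    """Generate a full dataset collection (one record per subject x CNR).

    Group 1 reuses one task-ROI layout for both runs; group 2 trains on
    layout "a" and tests on the disjoint layout "b" (cross-decoding).
    All subjects at one CNR level share one block order per run; block
    orders differ across CNR levels.  Identical ``master_seed`` gives a
    bit-identical collection.
    """
    if group not in (1, 2):
        raise ValueError("group must be 1 or 2")
    if cnr_levels is None:
        cnr_levels = np.round(np.arange(0.08, 0.161, 0.01), 3)
    paradigm_kwargs = paradigm_kwargs or {}
    root = np.random.default_rng(master_seed)
    layout_seed = int(root.integers(2**31))
    level_seeds = root.integers(2**31, size=(len(cnr_levels), 2))
    subject_rng = np.random.default_rng(int(root.integers(2**31)))

    base_maps = {
        "train": make_source_map("a", grid_shape, n_sources, n_tasks, seed=layout_seed),
        "test": make_source_map(
            "a" if group == 1 else "b", grid_shape, n_sources, n_tasks, seed=layout_seed + 1
        ),
    }
    transforms = []
    for _ in range(n_subjects):
        transforms.append(
            {
                "translation": tuple(
                    subject_rng.uniform(-0.02, 0.02) * min(grid_shape)
                    for _ in range(2)
                ),
                "rotation_deg": float(subject_rng.uniform(-5.0, 5.0)),
                "scale": float(subject_rng.uniform(0.98, 1.02)),
            }
        )

    collection = []
    for level, cnr in enumerate(cnr_levels):
        paradigms = {
            "train": make_paradigm(int(level_seeds[level, 0]), n_tasks=n_tasks, **paradigm_kwargs),
            "test": make_paradigm(int(level_seeds[level, 1]), n_tasks=n_tasks, **paradigm_kwargs),
        }
        for subject in range(n_subjects):
            runs = {}
            for ri, role in enumerate(("train", "test")):
                run_seed = master_seed + 100_000 * level + 100 * subject + ri
                runs[role] = generate_run(
                    paradigms[role],
                    base_maps[role],
                    float(cnr),
                    subject_transform=transforms[subject],
                    seed=run_seed,
                    head_motion=head_motion,
                    group=group,
                    subject_id=subject,
                )
            collection.append(
                TrainTestDataset(
                    subject_id=subject,
                    cnr=float(cnr),
                    group=group,
                    train=runs["train"],
                    test=runs["test"],
                )
            )
    return collection


# ---------------------------------------------------------------------------
# persistence


def save_collection(collection, path) -> None:
    """Write a dataset collection to one HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        for i, ds in enumerate(collection):
            g = f.create_group(f"dataset_{i:04d}")
            g.attrs["subject_id"] = ds.subject_id
            g.attrs["cnr"] = ds.cnr
            g.attrs["group"] = ds.group
            for role in ("train", "test"):
                run: SimulatedRun = getattr(ds, role)
                rg = g.create_group(role)
                rg.create_dataset("data", data=run.data, compression="gzip")
                rg.create_dataset("volume_labels", data=run.volume_labels)
                rg.attrs["cnr"] = run.cnr
                rg.attrs["seed"] = run.seed
                rg.attrs["grid_shape"] = run.grid_shape
                rg.attrs["tr_seconds"] = run.paradigm.tr_seconds
                rg.attrs["block_length_task"] = run.paradigm.block_length_task
                rg.attrs["block_length_rest"] = run.paradigm.block_length_rest
                rg.attrs["n_blocks_per_task"] = run.paradigm.n_blocks_per_task
                rg.attrs["task_order"] = run.paradigm.task_order
                rg.attrs["n_tasks"] = run.paradigm.n_tasks


def load_collection(path) -> list:
    """Read back a collection written by :func:`save_collection`."""
    import h5py

    collection = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            runs = {}
            for role in ("train", "test"):
                rg = g[role]
                paradigm = Paradigm(
                    tr_seconds=float(rg.attrs["tr_seconds"]),
                    block_length_task=float(rg.attrs["block_length_task"]),
                    block_length_rest=float(rg.attrs["block_length_rest"]),
                    n_blocks_per_task=int(rg.attrs["n_blocks_per_task"]),
                    task_order=tuple(int(t) for t in rg.attrs["task_order"]),
                    n_tasks=int(rg.attrs["n_tasks"]),
                )
                runs[role] = SimulatedRun(
                    data=rg["data"][...],
                    volume_labels=rg["volume_labels"][...],
                    paradigm=paradigm,
                    cnr=float(rg.attrs["cnr"]),
                    subject_id=int(g.attrs["subject_id"]),
                    seed=int(rg.attrs["seed"]),
                    group=int(g.attrs["group"]),
                    grid_shape=tuple(rg.attrs["grid_shape"]),
                )
            collection.append(
                TrainTestDataset(
                    subject_id=int(g.attrs["subject_id"]),
                    cnr=float(g.attrs["cnr"]),
                    group=int(g.attrs["group"]),
                    train=runs["train"],
                    test=runs["test"],
                )
            )
    return collection


def export_nifti(run: SimulatedRun, path, labels_path=None) -> None:
    """Export one run as 4-D NIfTI (H x W x 1 x T) plus a label TSV."""
    import nibabel as nib

    H, W = run.grid_shape
    vol = run.data.T.reshape(H, W, 1, run.n_volumes)
    img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
    img.header["pixdim"][4] = run.paradigm.tr_seconds
    nib.save(img, str(path))
    if labels_path is not None:
        import pandas as pd

        pd.DataFrame(
            {"volume": np.arange(run.n_volumes), "label": run.volume_labels}
        ).to_csv(labels_path, sep="\t", index=False)
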