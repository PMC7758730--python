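"""SVD-compressed representation of widefield movies.

A pixel x time movie ``S`` is factored as ``S = A L B^T`` and truncated to the
top ``k`` singular values.  The store keeps ``U = A[:, :k]`` (orthonormal
spatial components) and ``V = (L B^T)[:k]`` (singular-value-scaled temporal
components), so that the fluorescence of pixel ``n`` is reconstructed directly
as ``f_n(t) = U[n] @ V``.  All downstream analyses (spectral power maps,
hemodynamic correction) operate on ``U`` and ``V`` without ever materializing
the full movie.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "SVDStore",
    "compress_movie",
    "reconstruct_pixels",
    "extract_pixel_trace",
    "frame_slice",
    "save_store",
    "load_store",
]

DEFAULT_RANK = 500


@dataclass
class SVDStore:
    """Truncated SVD of a pixel x time movie.

    Attributes
    ----------
    U : (pixels, k) array
        Orthonormal spatial components.  Pixels are flattened row-major from
        ``pixel_shape``.
    V : (k, t) array
        Singular-value-scaled temporal components (``L B^T`` truncated), so
        ``U @ V`` reconstructs the movie.
    singular_values : (k,) array
        Nonincreasing, nonnegative.
    timestamps : (t,) array
        Frame times in seconds, strictly increasing.
    pixel_shape : (rows, cols)
    channel_tag : {"calcium", "hemo", "corrected"}
    """

    U: np.ndarray
    V: np.ndarray
    singular_values: np.ndarray
    timestamps: np.ndarray
    pixel_shape: tuple[int, int]
    channel_tag: str = "calcium"
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.U.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.U.shape[0]

    @property
    def n_frames(self) -> int:
        return self.V.shape[1]

    @property
    def fs(self) -> float:
        """Median sampling rate (frames/s) of this channel."""
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    def pixel_index(self, row: int, col: int) -> int:
        rows, cols = self.pixel_shape
        if not (0 <= row < rows and 0 <= col < cols):
            raise IndexError(
                f"pixel ({row}, {col}) outside grid {self.pixel_shape}"
            )
        return row * cols + col

    def validate(self) -> None:
        if self.U.shape[0] != self.pixel_shape[0] * self.pixel_shape[1]:
            raise ValueError("U rows do not match pixel_shape")
        if self.U.shape[1] != self.V.shape[0]:
            raise ValueError("U/V rank mismatch")
        if self.V.shape[1] != self.timestamps.shape[0]:
            raise ValueError("V columns do not match timestamps")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        sv = self.singular_values
        if np.any(sv < -1e-12) or np.any(np.diff(sv) > 1e-9 * max(1.0, sv[0] if len(sv) else 1.0)):
            raise ValueError("singular values must be nonincreasing and >= 0")


def frame_slice(timestamps: np.ndarray, start_s: float, end_s: float) -> slice:
    """Half-open frame slice [start_s, end_s) on a timestamp vector."""
    i0 = int(np.searchsorted(timestamps, start_s, side="left"))
    i1 = int(np.searchsorted(timestamps, end_s, side="left"))
    return slice(i0, i1)


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # SVD sign ambiguity: force the largest-magnitude entry of each spatial
    # component positive so repeated compressions agree.
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs[:, None]


def compress_movie(
    frames: np.ndarray,
    timestamps: np.ndarray,
    k: int = DEFAULT_RANK,
    pixel_shape: tuple[int, int] | None = None,
    channel_tag: str = "calcium",
) -> SVDStore:
    """Compress a pixel x time movie to its top-``k`` SVD components.

    Parameters
    ----------
    frames : (pixels, t) array
        Flattened movie (row-major pixel ordering).  A 3-D ``(rows, cols, t)``
        stack is accepted and reshaped.
    timestamps : (t,) array of seconds.
    k : requested rank; capped at ``min(pixels, t)``.
    pixel_shape : grid shape; required when ``frames`` is 2-D and non-square.

    No mean-centering is applied before the decomposition (configurable
    upstream by subtracting a baseline; the raw decomposition keeps pixel
    traces directly reconstructable as ``U @ V``).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 3:
        pixel_shape = frames.shape[:2]
        frames = frames.reshape(-1, frames.shape[2])
    if frames.ndim != 2:
        raise ValueError("frames must be (pixels, t) or (rows, cols, t)")
    if not np.all(np.isfinite(frames)):
        raise ValueError("frames contain non-finite values")
    if k <= 0:
        raise ValueError("k must be positive")
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.shape[0] != frames.shape[1]:
        raise ValueError("timestamps length does not match frame count")
    if pixel_shape is None:
        side = int(round(np.sqrt(frames.shape[0])))
        if side * side != frames.shape[0]:
            raise ValueError("pixel_shape required for non-square pixel count")
        pixel_shape = (side, side)

    k = min(k, min(frames.shape))
    A, s, Bt = np.linalg.svd(frames, full_matrices=False)
    U = A[:, :k]
    V = s[:k, None] * Bt[:k]
    U, V = _fix_signs(U, V)
    return SVDStore(
        U=U,
        V=V,
        singular_values=s[:k].copy(),
        timestamps=timestamps.copy(),
        pixel_shape=tuple(pixel_shape),
        channel_tag=channel_tag,
        meta={"discarded_energy": float(np.sum(s[k:] ** 2))},
    )


def reconstruct_pixels(
    store: SVDStore,
    pixel_indices: np.ndarray | list[int],
    time_slice: slice | None = None,
) -> np.ndarray:
    """Reconstruct selected pixel traces, ``U[idx] @ V[:, sl]``.

    Never materializes the full movie: cost is ``len(idx) * k * n_frames``.
    An empty index set returns an empty ``(0, n)`` array.
    """
    idx = np.asarray(pixel_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= store.n_pixels):
        raise IndexError("pixel index out of range")
    sl = time_slice if time_slice is not None else slice(None)
    return store.U[idx] @ store.V[:, sl]


def extract_pixel_trace(store: SVDStore, row: int, col: int) -> tuple[np.ndarray, np.ndarray]:
    """Time series of one pixel as ``(timestamps, trace)``."""
    n = store.pixel_index(row, col)
    trace = store.U[n] @ store.V
    return store.timestamps, trace


def save_store(store: SVDStore, path, group: str = "/") -> None:
    """Persist a store to HDF5 (datasets /U, /V, /sv, /timestamps, /meta)."""
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        for name in ("U", "V", "sv", "timestamps"):
            if name in g:
                del g[name]
        g.create_dataset("U", data=store.U)
        g.create_dataset("V", data=store.V)
        g.create_dataset("sv", data=store.singular_values)
        g.create_dataset("timestamps", data=store.timestamps)
        g.attrs["pixel_shape"] = store.pixel_shape
        g.attrs["k"] = store.k
        g.attrs["channel_tag"] = store.channel_tag


def load_store(path, group: str = "/") -> SVDStore:
    with h5py.File(path, "r") as f:
        g = f[group]
        store = SVDStore(
            U=g["U"][()],
            V=g["V"][()],
            singular_values=g["sv"][()],
            timestamps=g["timestamps"][()],
            pixel_shape=tuple(int(x) for x in g.attrs["pixel_shape"]),
            channel_tag=str(g.attrs["channel_tag"]),
        )
    store.validate()
    return store
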