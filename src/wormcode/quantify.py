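"""Reporter fluorescence quantification from 3-D image stacks.

A neuron's reporter signal is read out from an epifluorescence z-stack by
(1) extracting a 3-D box around the cell location, (2) integrating the K
brightest voxels in the box (K chosen once so the whole cell is always
covered), and (3) subtracting K times the background level, estimated as the
mode of the voxel-intensity distribution in the box.  The mode is robust to
the bright minority of cell voxels and captures the diffuse background (e.g.
gut autofluorescence) that dominates the box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageStack", "CellROI", "max_projection", "integrate_brightest",
           "mode_background", "net_intensity", "read_stack", "write_stack"]


@dataclass(frozen=True)
class ImageStack:
    """3-D fluorescence stack: ``voxels[z, y, x]`` counts, sections z_step µm apart."""

    voxels: np.ndarray
    z_step: float = 2.0

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3 or v.shape[0] < 1:
            raise ValueError("stack must be a 3-D array with at least one section")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("voxel intensities must be finite and non-negative")
        object.__setattr__(self, "voxels", v)

    @property
    def n_sections(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class CellROI:
    """Extraction box around a cell: center (z, y, x), half-widths, K brightest voxels.

    The box is the closed interval ``center - half_widths .. center +
    half_widths`` per axis, clipped at the stack boundary; coordinates are
    0-based.
    """

    center: tuple
    half_widths: tuple
    k_brightest: int

    def __post_init__(self):
        if len(self.center) != 3 or len(self.half_widths) != 3:
            raise ValueError("center and half_widths must be (z, y, x) triples")
        if self.k_brightest < 1:
            raise ValueError("k_brightest must be >= 1")
        object.__setattr__(self, "center", tuple(int(c) for c in self.center))
        object.__setattr__(self, "half_widths", tuple(int(h) for h in self.half_widths))


def _box(stack: ImageStack, roi: CellROI) -> np.ndarray:
    sl = []
    for c, h, size in zip(roi.center, roi.half_widths, stack.voxels.shape):
        if not 0 <= c < size:
            raise ValueError(f"ROI center {roi.center} outside stack shape "
                             f"{stack.voxels.shape}")
        sl.append(slice(max(0, c - h), min(size, c + h + 1)))
    box = stack.voxels[tuple(sl)]
    if box.size == 0:
        raise ValueError("empty extraction box")
    return box


def max_projection(stack: ImageStack) -> np.ndarray:
    """Maximum-intensity projection along z: ``out[y, x] = max_z voxels[z, y, x]``."""
    return stack.voxels.max(axis=0)


def integrate_brightest(stack: ImageStack, roi: CellROI) -> float:
    """Sum of the ``k_brightest`` largest voxel values in the extraction box.

    Ties at the k-th value are resolved by voxel scan order (z, y, x), which
    does not affect the sum.
    """
    box = _box(stack, roi).reshape(-1)
    k = roi.k_brightest
    if k > box.size:
        raise ValueError(f"k_brightest={k} exceeds box voxel count {box.size}")
    if k == box.size:
        return float(box.sum())
    top = np.partition(box, box.size - k)[box.size - k:]
    return float(top.sum())


def mode_background(stack: ImageStack, roi: CellROI) -> float:
    """Per-voxel background: mode of the intensity histogram in the extraction box.

    The histogram bin width is max(1 count, the Freedman-Diaconis width over
    the box); bins are aligned so the box minimum sits at a bin center, and
    the mode is the center of the tallest bin (ties broken toward the lowest
    bin — the background is the dim majority).
    """
    box = _box(stack, roi).reshape(-1).astype(float)
    lo, hi = box.min(), box.max()
    iqr = float(np.subtract(*np.percentile(box, [75, 25])))
    width = max(1.0, 2.0 * iqr / max(1.0, box.size ** (1.0 / 3.0)))
    # edges offset by half a width: centers fall at lo, lo+width, ...
    n_bins = int(np.floor((hi - lo) / width + 0.5)) + 1
    edges = lo - 0.5 * width + width * np.arange(n_bins + 1)
    counts, _ = np.histogram(box, bins=edges)
    return float(lo + width * int(np.argmax(counts)))


def net_intensity(stack: ImageStack, roi: CellROI) -> float:
    """Background-corrected integrated intensity: brightest-K sum minus K x mode."""
    return integrate_brightest(stack, roi) - roi.k_brightest * mode_background(stack, roi)


def read_stack(path, z_step: float = 2.0) -> ImageStack:
    """Read a multi-page TIFF as an ImageStack."""
    import tifffile
    return ImageStack(voxels=tifffile.imread(path), z_step=z_step)


def write_stack(stack: ImageStack, path) -> None:
    """Write an ImageStack as a multi-page TIFF (16-bit when values allow)."""
    import tifffile
    v = stack.voxels
    if np.issubdtype(v.dtype, np.floating):
        v = np.round(v)
    if v.max(initial=0) <= np.iinfo(np.uint16).max:
        v = v.astype(np.uint16)
    tifffile.imwrite(path, v, photometric="minisblack")
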