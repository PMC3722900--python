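"""ROI propagation, necrosis exclusion and mean-signal extraction.

The tumour ROI is drawn once on the reference high-b image (b=800 by
default, where tumour/background contrast is best) and transferred unchanged
to every other b-value image of the co-acquired stack — an identity transfer,
since all b-value images share the voxel grid.  The mean signal intensity
over the retained voxels, per b-value, is the curve every downstream fit
consumes.

Necrotic or cystic tumour portions must not contaminate the ROI mean: they
are fluid-like (fast diffusion, so steep high-b signal loss) and
T2-hyperintense at b=0.  ``exclude_necrosis`` encodes both signatures as
tunable thresholds relative to robust ROI statistics.

Image container
---------------
``ImageStack`` holds one array of shape (n_b, *grid) plus its b-value
scheme.  Stacks round-trip through ``save_stack``/``load_stack`` as plain
NumPy ``.npz`` archives with keys ``data``, ``b_values``, and optionally
``tumour_mask``/``necrosis_mask`` — a deliberately simple array container so
fixtures need no medical-imaging I/O stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ivim import BValueScheme, SignalCurve

__all__ = [
    "ImageStack",
    "RoiDefinition",
    "NecrosisThresholds",
    "propagate_roi",
    "exclude_necrosis",
    "extract_mean_signal",
    "save_stack",
    "load_stack",
]


@dataclass
class ImageStack:
    """Per-b-value image volumes sharing one voxel grid."""

    scheme: BValueScheme
    data: np.ndarray  # shape (n_b, *grid)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.scheme.b_values):
            raise ValueError("first axis must index the scheme's b-values")
        if self.data.ndim not in (3, 4):
            raise ValueError("grid must be 2-D or 3-D")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    def image(self, b: float) -> np.ndarray:
        return self.data[self.scheme.index_of(b)]


def _as_voxel_array(voxels, ndim: int) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(list(voxels), dtype=int))
    if arr.size == 0:
        raise ValueError("empty voxel set")
    if arr.shape[1] != ndim:
        raise ValueError(f"voxel indices must have {ndim} coordinates")
    return arr


@dataclass(frozen=True)
class RoiDefinition:
    """Voxel-index ROI drawn on the reference b-value image.

    Voxels are 0-based array-order index tuples (not polygons).
    """

    voxels: tuple[tuple[int, ...], ...]
    area_mm2: float = float("nan")
    reference_b: float = 800.0

    def __post_init__(self) -> None:
        if len(self.voxels) == 0:
            raise ValueError("ROI must contain at least one voxel")

    @classmethod
    def from_mask(cls, mask: np.ndarray, area_mm2: float = float("nan"),
                  reference_b: float = 800.0) -> "RoiDefinition":
        vox = tuple(map(tuple, np.argwhere(np.asarray(mask, dtype=bool))))
        return cls(voxels=vox, area_mm2=area_mm2, reference_b=reference_b)


@dataclass(frozen=True)
class NecrosisThresholds:
    """Relative cutoffs for the two necrosis/cyst exclusion rules.

    A voxel is excluded when its high-b attenuation ratio S(b_max)/S(0)
    falls below ``high_b_ratio_factor`` times the ROI median ratio or below
    the absolute ``fluid_ratio_floor`` (steep signal loss: fluid-like fast
    diffusion — the floor corresponds to D >~ 1.9e-3 mm^2/s at b=1000), or
    when its b=0 signal exceeds ``b0_hyper_factor`` times the ROI median b=0
    signal (T2-hyperintensity).  The relative cutoffs adapt to arbitrary
    signal scales; the absolute floor catches the degenerate case of a ROI
    that is necrotic throughout, which relative statistics cannot see.  All
    three are deliberately tunable because the exclusion is a radiologist
    judgement call in practice.
    """

    high_b_ratio_factor: float = 0.5
    b0_hyper_factor: float = 3.0
    fluid_ratio_floor: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.high_b_ratio_factor < 1.0:
            raise ValueError("high_b_ratio_factor must be in (0, 1)")
        if self.b0_hyper_factor <= 1.0:
            raise ValueError("b0_hyper_factor must exceed 1")
        if not 0.0 <= self.fluid_ratio_floor < 1.0:
            raise ValueError("fluid_ratio_floor must be in [0, 1)")


def propagate_roi(roi: RoiDefinition, scheme: BValueScheme) -> dict[float, tuple]:
    """Transfer the ROI to every b-value image (rigid identity transfer)."""
    scheme.index_of(roi.reference_b)  # raises if absent
    return {float(b): roi.voxels for b in scheme.b_values}


def extract_mean_signal(stack: ImageStack, voxels, scheme: BValueScheme | None = None
                        ) -> SignalCurve:
    """Arithmetic mean of the voxel signals per b-value, in scheme order."""
    scheme = scheme or stack.scheme
    vox = _as_voxel_array(voxels, stack.data.ndim - 1)
    idx = (slice(None),) + tuple(vox.T)
    values = stack.data[idx]  # (n_b, n_vox)
    return SignalCurve(scheme=scheme, s=values.mean(axis=1))


def exclude_necrosis(
    stack: ImageStack,
    roi: RoiDefinition,
    thresholds: NecrosisThresholds = NecrosisThresholds(),
) -> tuple[RoiDefinition, dict]:
    """Remove necrotic/cystic voxels from the ROI.

    Returns the reduced ROI and a report with per-rule removal counts.
    Raises if the exclusion would empty the ROI, naming the rule responsible.
    """
    vox = _as_voxel_array(roi.voxels, stack.data.ndim - 1)
    coords = tuple(vox.T)
    s0 = stack.image(0.0)[coords]
    s_hi = stack.image(stack.scheme.b_max)[coords]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s0 > 0, s_hi / np.where(s0 > 0, s0, 1.0), 0.0)

    ratio_cutoff = max(
        thresholds.high_b_ratio_factor * float(np.median(ratio)),
        thresholds.fluid_ratio_floor,
    )
    b0_cutoff = thresholds.b0_hyper_factor * float(np.median(s0))
    drop_steep = ratio < ratio_cutoff
    drop_hyper = s0 > b0_cutoff
    keep = ~(drop_steep | drop_hyper)

    report = {
        "n_input": int(vox.shape[0]),
        "n_removed_high_b_ratio": int(np.sum(drop_steep)),
        "n_removed_b0_hyperintense": int(np.sum(drop_hyper & ~drop_steep)),
        "n_remaining": int(np.sum(keep)),
        "ratio_cutoff": ratio_cutoff,
        "b0_cutoff": b0_cutoff,
    }
    if not np.any(keep):
        rule = ("high_b_ratio" if np.sum(drop_steep) >= np.sum(drop_hyper)
                else "b0_hyperintense")
        raise ValueError(
            f"necrosis exclusion (rule {rule!r}) would remove every ROI voxel"
        )
    reduced = RoiDefinition(
        voxels=tuple(map(tuple, vox[keep])),
        area_mm2=roi.area_mm2 * float(np.sum(keep)) / vox.shape[0]
        if np.isfinite(roi.area_mm2) else roi.area_mm2,
        reference_b=roi.reference_b,
    )
    return reduced, report


def save_stack(path: str | Path, stack: ImageStack,
               tumour_mask: np.ndarray | None = None,
               necrosis_mask: np.ndarray | None = None) -> None:
    extras = {}
    if tumour_mask is not None:
        extras["tumour_mask"] = np.asarray(tumour_mask, dtype=bool)
    if necrosis_mask is not None:
        extras["necrosis_mask"] = np.asarray(necrosis_mask, dtype=bool)
    np.savez(path, data=stack.data,
             b_values=np.asarray(stack.scheme.b_values, dtype=float), **extras)


def load_stack(path: str | Path) -> tuple[ImageStack, np.ndarray | None, np.ndarray | None]:
    with np.load(path) as z:
        b_values = tuple(float(b) for b in z["b_values"])
        scheme = BValueScheme(b_values=b_values)
        stack = ImageStack(scheme=scheme, data=z["data"])
        tm = z["tumour_mask"] if "tumour_mask" in z else None
        nm = z["necrosis_mask"] if "necrosis_mask" in z else None
    return stack, tm, nm
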