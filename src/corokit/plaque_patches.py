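"""Plaque-classifier data preparation bookkeeping and architecture spec.

The tissue classifier operates on small square patches sampled from the
region of interest between the lumen and adventitia borders.  This module
implements the dataset bookkeeping — seeded patch-center sampling inside
the ROI, rotation augmentation (90 and 180 degrees), and a frame-grouped
train/validation split so no frame leaks across the two sets — and builds
the layer-by-layer architecture specification (shapes and parameter
counts).  Training clinical models is out of scope: no annotated frames are
shipped, only the machinery to reproduce the dataset arithmetic and the
network definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from .types import PolarFrame, RadialContour

__all__ = [
    "Patch",
    "PatchSet",
    "extract_patches",
    "augment_patches",
    "split_patches",
    "build_architecture_spec",
]

PLAQUE_CLASSES = ("CA", "FT", "LT", "MT", "BK")  # calcified, fibrous, lipid, mixed, background


@dataclass
class Patch:
    frame_id: int
    center: Tuple[int, int]       # (aline/row, depth/col) or (row, col)
    size_px: int
    rotation_deg: int = 0         # 0 | 90 | 180
    label: Optional[str] = None


@dataclass
class PatchSet:
    """A collection of patches plus its bookkeeping counts."""

    patches: List[Patch] = field(default_factory=list)
    n_originals: int = 0

    @property
    def n_total(self) -> int:
        return len(self.patches)

    @property
    def frame_ids(self) -> Set[int]:
        return {p.frame_id for p in self.patches}


def roi_mask(frame_shape: Tuple[int, int], lumen: RadialContour,
             adventitia: RadialContour) -> np.ndarray:
    """Boolean mask of the tissue ROI between the two borders (polar grid)."""
    n, nd = frame_shape
    cols = np.arange(nd)[None, :]
    return (cols > lumen.radii[:, None]) & (cols < adventitia.radii[:, None])


def extract_patches(frame: PolarFrame, lumen: RadialContour,
                    adventitia: RadialContour, n_per_frame: int = 1000,
                    patch_px: int = 25, seed: int = 0) -> PatchSet:
    """Sample ``n_per_frame`` patch centers uniformly from the tissue ROI.

    Centers are drawn (seeded) from the pixels between the lumen and
    adventitia contours, then clipped so patches never cross the frame
    bounds.  If the ROI holds fewer pixels than requested, sampling falls
    back to replacement with a warning.
    """
    rng = np.random.default_rng(seed)
    mask = roi_mask((frame.n_alines, frame.n_depth), lumen, adventitia)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty ROI between contours")
    replace = rows.size < n_per_frame
    if replace:
        warnings.warn("ROI smaller than n_per_frame; sampling with replacement")
    pick = rng.choice(rows.size, size=n_per_frame, replace=replace)
    half = patch_px // 2
    patches = []
    for k in pick:
        r = int(np.clip(rows[k], half, frame.n_alines - 1 - half))
        c = int(np.clip(cols[k], half, frame.n_depth - 1 - half))
        patches.append(Patch(frame_id=frame.frame_index, center=(r, c),
                             size_px=patch_px))
    return PatchSet(patches=patches, n_originals=n_per_frame)


def augment_patches(ps: PatchSet, rotations: Sequence[int] = (90, 180)) -> PatchSet:
    """Add one rotated copy per original per rotation (never re-rotated).

    With both default rotations the augmented count is three times the
    originals.
    """
    rotations = tuple(rotations)
    if any(r not in (90, 180) for r in rotations):
        raise ValueError("supported rotations: 90, 180 degrees")
    originals = [p for p in ps.patches if p.rotation_deg == 0]
    out = list(ps.patches)
    for rot in rotations:
        out.extend(Patch(p.frame_id, p.center, p.size_px, rotation_deg=rot,
                         label=p.label) for p in originals)
    return PatchSet(patches=out, n_originals=ps.n_originals)


def split_patches(ps: PatchSet, train_fraction: float = 0.7, seed: int = 0,
                  group_by_frame: bool = True) -> Tuple[PatchSet, PatchSet]:
    """Split into train/validation sets, by frame by default.

    With ``group_by_frame`` the *frames* are partitioned (seeded shuffle, the
    first 70% of frames go to training) so validation patches never share a
    frame with training patches.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if group_by_frame:
        frames = sorted(ps.frame_ids)
        order = rng.permutation(len(frames))
        n_train = int(round(train_fraction * len(frames)))
        train_frames = {frames[i] for i in order[:n_train]}
        train = [p for p in ps.patches if p.frame_id in train_frames]
        val = [p for p in ps.patches if p.frame_id not in train_frames]
    else:
        order = rng.permutation(ps.n_total)
        n_train = int(round(train_fraction * ps.n_total))
        train = [ps.patches[i] for i in order[:n_train]]
        val = [ps.patches[i] for i in order[n_train:]]
    return (PatchSet(patches=train, n_originals=ps.n_originals),
            PatchSet(patches=val, n_originals=ps.n_originals))


# ---------------------------------------------------------------------------
# architecture specification

FILTER_PLANS = {
    # nine CONV blocks in three groups of three
    "OCT": (32, 32, 32, 64, 64, 64, 128, 128, 128),
    "IVUS": (16, 16, 16, 32, 32, 32, 128, 128, 128),
}


def build_architecture_spec(modality: str = "OCT", patch_px: int = 25,
                            n_classes: int = 5) -> dict:
    """Layer-by-layer spec of the patch classifier, with shapes and counts.

    Nine CONV blocks (3x3 conv + batch norm + ReLU), max pooling after
    blocks 3 and 6, global average pooling after block 9, then FC 512,
    dropout 0.5, FC ``n_classes`` and softmax.  The filter plan depends on
    the modality; spatial shapes follow from ``patch_px``.
    """
    modality = modality.upper()
    if modality not in FILTER_PLANS:
        raise ValueError("modality must be 'OCT' or 'IVUS'")
    if patch_px < 13:
        raise ValueError("patch too small: need patch_px >= 13 so two max-pools "
                         "and the average pool keep a >= 1x1 map")
    plan = FILTER_PLANS[modality]
    layers: List[dict] = []
    h = patch_px
    c_in = 1
    n_params = 0
    for i, c_out in enumerate(plan, start=1):
        conv_p = (3 * 3 * c_in + 1) * c_out
        bn_p = 2 * c_out
        n_params += conv_p + bn_p
        layers.append({"kind": "conv_block", "index": i, "filters": c_out,
                       "kernel": (3, 3), "activation": "relu",
                       "batch_norm": True, "output_shape": (h, h, c_out),
                       "params": conv_p + bn_p})
        c_in = c_out
        if i in (3, 6):
            h = h // 2
            layers.append({"kind": "max_pool", "pool": (2, 2),
                           "output_shape": (h, h, c_in), "params": 0})
    layers.append({"kind": "avg_pool_global", "output_shape": (1, 1, c_in),
                   "params": 0})
    fc1 = (c_in + 1) * 512
    n_params += fc1
    layers.append({"kind": "fc", "units": 512, "activation": "relu",
                   "output_shape": (512,), "params": fc1})
    layers.append({"kind": "dropout", "rate": 0.5, "output_shape": (512,),
                   "params": 0})
    fc2 = (512 + 1) * n_classes
    n_params += fc2
    layers.append({"kind": "fc", "units": n_classes, "activation": None,
                   "output_shape": (n_classes,), "params": fc2})
    layers.append({"kind": "softmax", "output_shape": (n_classes,), "params": 0})
    return {"modality": modality, "patch_px": patch_px, "n_classes": n_classes,
            "layers": layers, "total_params": n_params}
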