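"""Run configuration for the analysis pipeline.

All physical parameters are in µm / minutes so a config is independent of the
movie's pixel scale; per-movie pixel quantities are derived at run time.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters controlling every stage of the pipeline.

    Attributes
    ----------
    patch_size_um
        Side of the square block-matching patches (µm); sub-cellular sized.
    search_radius_um
        Half-side of the block-matching search window (µm).  ``None`` lets
        the motion stage derive it from the largest expected per-frame
        displacement plus a 2-pixel margin.
    strip_width_um
        Width of the distance bins of the velocity magnitude map (µm);
        ``None`` means one patch width.
    n_distance_intervals
        Number of equal distance intervals used for descriptor vectors.
    max_distance_um
        Farthest distance from the wound edge represented in maps and
        descriptors (µm).
    closure_area_fraction
        The wound counts as fully closed when its area drops below this
        fraction of the initial wound area.
    seg_window_um
        Side of the local-variance window of the segmenter (µm); ``None``
        means half a patch.
    seg_variance_threshold
        Fixed threshold on the local-variance image; ``None`` selects the
        threshold automatically (Otsu).
    min_ncc
        Minimum normalized cross-correlation score for a patch displacement
        to be considered valid.
    variance_floor_frac
        Patches whose intensity variance is below this fraction of the
        movie's median patch variance are flagged invalid (textureless).
    smoothing_window
        Width (frames) of the centered moving average applied to per-anchor
        velocity profiles.
    anchor_mode
        ``"advect"``: displacement anchors are relabeled by their remaining
        distance to the wound as they accumulate displacement (an "average
        cell" is tracked); ``"fixed"``: anchors stay in their initial strip.
    svm_c, svm_standardize
        Linear-SVM regularization constant and whether features are
        standardized on each training fold.
    phases_used
        Number of healing phases entering velocity descriptors (3 → length
        18; 2 → length 12, for cohorts where full closure is not reached).
    rng_seed
        Seed for every stochastic component of a run.
    """

    patch_size_um: float = 18.5
    search_radius_um: Optional[float] = None
    strip_width_um: Optional[float] = None
    n_distance_intervals: int = 6
    max_distance_um: float = 350.0
    closure_area_fraction: float = 0.01
    seg_window_um: Optional[float] = None
    seg_variance_threshold: Optional[float] = None
    min_ncc: float = 0.5
    variance_floor_frac: float = 0.1
    smoothing_window: int = 5
    anchor_mode: str = "advect"
    svm_c: float = 1.0
    svm_standardize: bool = True
    phases_used: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("patch_size_um", "max_distance_um"):
            v = getattr(self, attr)
            if not v > 0:
                raise ValueError(f"{attr} must be > 0, got {v}")
        for attr in ("search_radius_um", "strip_width_um", "seg_window_um"):
            v = getattr(self, attr)
            if v is not None and not v > 0:
                raise ValueError(f"{attr} must be > 0 when given, got {v}")
        if self.n_distance_intervals < 1:
            raise ValueError("n_distance_intervals must be >= 1")
        if not 0.0 < self.closure_area_fraction < 1.0:
            raise ValueError("closure_area_fraction must lie in (0, 1)")
        if self.anchor_mode not in ("advect", "fixed"):
            raise ValueError(f"anchor_mode must be 'advect' or 'fixed', got {self.anchor_mode!r}")
        if self.phases_used not in (2, 3):
            raise ValueError("phases_used must be 2 or 3")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")

    # -- derived pixel-scale quantities -----------------------------------

    def patch_size_px(self, pixel_size_um: float) -> int:
        px = int(round(self.patch_size_um / pixel_size_um))
        return max(px, 8)

    def seg_window_px(self, pixel_size_um: float) -> int:
        um = self.seg_window_um if self.seg_window_um is not None else self.patch_size_um / 2.0
        return max(int(round(um / pixel_size_um)), 3)

    def strip_width(self) -> float:
        return self.strip_width_um if self.strip_width_um is not None else self.patch_size_um

    # -- (de)serialization -------------------------------------------------

    def to_json(self, path: str | os.PathLike) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
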