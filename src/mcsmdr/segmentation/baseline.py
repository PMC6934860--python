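"""Classical threshold-based spheroid segmentation.

Serves as the comparator the network is judged against: Gaussian
smoothing, Otsu threshold, morphological closing, largest connected
component, hole filling.  On clean, homogeneous synthetic frames this
is essentially exact; strong intensity inhomogeneity over the spheroid
and soft boundaries are what break it.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import closing, disk

from ..containers import SegMask


def baseline_segment(frame: np.ndarray, sigma: float = 2.0) -> SegMask:
    """Otsu-based segmentation of a single-channel frame."""
    frame = np.asarray(frame, dtype=np.float32)
    if frame.ndim != 2:
        raise ValueError("expected a single-channel 2-D frame")
    if np.ptp(frame) == 0:  # blank frame: nothing to threshold
        return SegMask(np.zeros(frame.shape, np.uint8), source="baseline",
                       empty_warning=True)
    sm = gaussian(frame, sigma=sigma, preserve_range=True)
    fg = sm > threshold_otsu(sm)
    fg = closing(fg, disk(3)).astype(bool)
    if fg.any():
        lab, nlab = ndi.label(fg)
        if nlab > 1:
            sizes = ndi.sum(fg, lab, index=np.arange(1, nlab + 1))
            fg = lab == (1 + int(np.argmax(sizes)))
        fg = ndi.binary_fill_holes(fg)
    return SegMask(fg.astype(np.uint8), source="baseline",
                   empty_warning=not bool(fg.any()))
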