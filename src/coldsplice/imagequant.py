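"""Single-cell compartmental fluorescence quantification.

Cells are segmented into soma, nucleus and cytoplasm and each channel's
mean intensity per unit area is reported per compartment.  The cytoplasm
is defined as the area inside the soma but outside the nucleus, so the
three masks always satisfy soma = nucleus ⊎ cytoplasm.  Segmentation uses
a global Otsu threshold on the background-removed channel (nucleus), or
Otsu scaled by a floor factor to capture the dimmer cytoplasm (soma),
followed by morphological cleanup and a largest-connected-component rule
(inputs are single-cell crops; multi-cell inputs keep the largest cell).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.morphology import disk

__all__ = [
    "MultiChannelImage",
    "BackgroundResult",
    "SegmentationMasks",
    "CompartmentIntensities",
    "read_tiff",
    "remove_background",
    "segment_nucleus",
    "segment_soma",
    "build_masks",
    "segment_cell",
    "measure_compartments",
]

COMPARTMENTS = ("soma", "nucleus", "cytoplasm")


@dataclass
class MultiChannelImage:
    """Named 2-D intensity channels of equal shape (e.g. nuclear_stain, reporter)."""

    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels must share one shape, got {shapes}")
        for name, ch in self.channels.items():
            arr = np.asarray(ch, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} must be 2-D, got ndim={arr.ndim}")
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"channel {name!r} must be finite and non-negative")
            self.channels[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not present; have {sorted(self.channels)}")
        return self.channels[name]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def read_tiff(path: str | Path, channel_names: list[str] | None = None) -> MultiChannelImage:
    """Read a multi-page TIFF as a MultiChannelImage (8/16-bit promoted to float).

    Pages map to ``channel_names`` in order; without names, pages become
    channel_0, channel_1, ...
    """
    import tifffile

    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    names = channel_names or [f"channel_{i}" for i in range(stack.shape[0])]
    if len(names) != stack.shape[0]:
        raise ValueError(f"{len(names)} channel names for {stack.shape[0]} pages")
    return MultiChannelImage({n: stack[i].astype(float) for i, n in enumerate(names)})


@dataclass
class BackgroundResult:
    corrected: np.ndarray
    background: float
    method: str
    params: dict = field(default_factory=dict)


def remove_background(
    channel: np.ndarray, method: str = "median_background", radius: int = 25
) -> BackgroundResult:
    """Estimate and subtract the background level of one channel; clip at 0.

    Default method builds a coarse foreground mask with a triangle threshold
    and subtracts the median of the remaining (background) pixels.  If the
    mask covers the whole image the global minimum is subtracted instead
    (with a warning).  ``rolling_ball`` subtracts a rolling-ball background
    surface of the given radius.
    """
    channel = np.asarray(channel, dtype=float)
    if method == "rolling_ball":
        from skimage.restoration import rolling_ball

        bg = rolling_ball(channel, radius=radius)
        return BackgroundResult(
            corrected=np.clip(channel - bg, 0.0, None),
            background=float(np.median(bg)),
            method=method,
            params={"radius": radius},
        )
    if method != "median_background":
        raise ValueError(f"unknown background method {method!r}")
    if np.ptp(channel) == 0:
        bg = float(channel.flat[0])
    else:
        fg = channel > threshold_triangle(channel)
        if fg.mean() > 0.5:
            # triangle collapses when zero-clipped noise spikes the histogram;
            # fall back to Otsu for the coarse foreground
            fg = channel > threshold_otsu(channel)
        if fg.all():
            warnings.warn("coarse foreground covers the whole image; subtracting the minimum",
                          stacklevel=2)
            bg = float(channel.min())
        else:
            bg = float(np.median(channel[~fg]))
    return BackgroundResult(
        corrected=np.clip(channel - bg, 0.0, None),
        background=bg,
        method="median_background",
        params={},
    )


def _contrast_ok(
    corrected: np.ndarray, raw: np.ndarray, mask: np.ndarray, min_separation: float = 4.0
) -> bool:
    """True when the mask's foreground stands clear of the background noise.

    Otsu always splits a histogram, even of pure noise; a real cell must
    separate from the background by at least ``min_separation`` noise
    standard deviations, with the noise scale taken robustly (scaled MAD of
    the raw channel outside the mask, unaffected by zero clipping).
    """
    if not mask.any() or mask.all():
        return mask.any()
    sep = corrected[mask].mean() - corrected[~mask].mean()
    bg_raw = raw[~mask]
    sigma = 1.4826 * float(np.median(np.abs(bg_raw - np.median(bg_raw))))
    return sep >= min_separation * max(sigma, 1e-12)


def _largest_component(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndi.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        return np.zeros_like(mask, dtype=bool)
    return labels == best


def segment_nucleus(
    image: MultiChannelImage,
    source: str = "nuclear_stain",
    closing_radius: int = 2,
    min_area: int = 50,
) -> np.ndarray:
    """Nucleus mask: Otsu on the background-removed source channel.

    The source is the nuclear stain when available, or the reporter channel
    when the reporter protein is predominantly nuclear.  Binary closing
    cleans the boundary and only the largest connected component is kept;
    an all-False mask signals no cell found.
    """
    raw = image[source]
    corrected = remove_background(raw).corrected
    if np.ptp(corrected) == 0:
        return np.zeros(corrected.shape, dtype=bool)
    mask = corrected > threshold_otsu(corrected)
    if not _contrast_ok(corrected, raw, mask):
        return np.zeros(corrected.shape, dtype=bool)
    mask = ndi.binary_closing(mask, structure=disk(closing_radius))
    return _largest_component(mask, min_area)


def segment_soma(
    image: MultiChannelImage,
    source: str = "reporter",
    nucleus: np.ndarray | None = None,
    floor_factor: float = 0.5,
    closing_radius: int = 2,
    min_area: int = 50,
) -> np.ndarray:
    """Soma mask: Otsu lowered by ``floor_factor`` to capture dim cytoplasm.

    The plain Otsu threshold on a cell whose nucleus is much brighter than
    its cytoplasm would cut at the nucleus boundary; scaling the threshold
    down keeps the dimmer cytoplasmic rim.  Holes are filled, the largest
    component kept, and the nucleus (when given) unioned in so nucleus ⊆
    soma always holds.
    """
    raw = image[source]
    corrected = remove_background(raw).corrected
    if np.ptp(corrected) == 0:
        mask = np.zeros(corrected.shape, dtype=bool)
    else:
        otsu_mask = corrected > threshold_otsu(corrected)
        if not _contrast_ok(corrected, raw, otsu_mask):
            mask = np.zeros(corrected.shape, dtype=bool)
        else:
            mask = corrected > floor_factor * threshold_otsu(corrected)
            mask = ndi.binary_closing(mask, structure=disk(closing_radius))
            mask = ndi.binary_fill_holes(mask)
            mask = _largest_component(mask, min_area)
    if nucleus is not None and mask.any():
        mask = mask | nucleus
    return mask


@dataclass
class SegmentationMasks:
    """Nucleus/soma/cytoplasm partition of one cell (soma = nucleus ⊎ cytoplasm)."""

    nucleus: np.ndarray
    soma: np.ndarray
    cytoplasm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.nucleus.shape != self.soma.shape:
            raise ValueError("nucleus and soma masks must share one shape")
        if (self.nucleus & ~self.soma).any():
            raise ValueError("nucleus mask must be contained in the soma mask")
        self.cytoplasm = self.soma & ~self.nucleus

    @property
    def found(self) -> bool:
        return bool(self.soma.any())


def build_masks(nucleus: np.ndarray, soma: np.ndarray) -> SegmentationMasks:
    """Build the compartment partition, enforcing nucleus ⊆ soma by union."""
    return SegmentationMasks(nucleus=nucleus, soma=soma | nucleus)


def segment_cell(
    image: MultiChannelImage,
    nucleus_source: str = "nuclear_stain",
    soma_source: str = "reporter",
    **kwargs,
) -> SegmentationMasks:
    """Full segmentation of a single-cell crop; ``found`` is False for empty fields."""
    nucleus = segment_nucleus(image, source=nucleus_source,
                              **{k: v for k, v in kwargs.items() if k in ("closing_radius", "min_area")})
    soma = segment_soma(image, source=soma_source, nucleus=nucleus,
                        **{k: v for k, v in kwargs.items()
                           if k in ("floor_factor", "closing_radius", "min_area")})
    return build_masks(nucleus, soma)


@dataclass
class CompartmentIntensities:
    """Mean intensity per unit area and pixel area per compartment, one channel."""

    channel: str
    means: dict  # compartment -> float | None (None = empty compartment)
    areas: dict  # compartment -> int


def measure_compartments(
    channel: np.ndarray, masks: SegmentationMasks, name: str = "channel"
) -> CompartmentIntensities:
    """Mean of the (background-removed) channel over each compartment mask.

    The caller chooses whether to background-correct the channel first; the
    measurement itself is a plain masked mean (total intensity / area).
    Empty compartments report mean None.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.shape != masks.soma.shape:
        raise ValueError("channel and masks must share one shape")
    means, areas = {}, {}
    for comp in COMPARTMENTS:
        mask = getattr(masks, comp)
        area = int(mask.sum())
        areas[comp] = area
        means[comp] = float(channel[mask].mean()) if area else None
    return CompartmentIntensities(channel=name, means=means, areas=areas)
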