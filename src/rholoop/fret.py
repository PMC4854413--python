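"""Leading-edge ratiometric FRET quantification.

Semi-automated pipeline for two-channel ratio imaging of Raichu-type GTPase
biosensors in migrating cells:

1. per-frame sub-pixel channel registration by upsampled cross-correlation
   (0.01-px precision), with Fourier-domain resampling;
2. band-pass filtering of the bright direct-acceptor (YFP-YFP) channel with
   an a-trous (stationary) wavelet transform, summing detail scales 2-8 of
   the separable linear 3-tap kernel, which removes both pixel noise and
   stationary background;
3. fixed-threshold segmentation (grey value > 2000 on 16-bit data) and
   8-connected component labelling, keeping the largest object as the cell
   mask;
4. a ring mask 40 px wide at the cell boundary, quartered along the longer
   axis of its bounding box; the extremal quarters are the front/back
   crescents, with the front chosen from a hint at frame 0 and carried
   forward by maximal overlap;
5. the per-frame leading-edge ratio: both ratio channels Gaussian-smoothed
   (sigma 1.0 px), divided pixel-wise inside the front crescent ignoring
   zero-denominator pixels, and averaged.

The FRET ratio (sensitised emission over donor) is a proxy for GTPase
activity; absolute calibration, bleed-through and photobleaching correction
are out of scope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.registration import phase_cross_correlation

DEFAULT_THRESHOLD = 2000
DEFAULT_RING_WIDTH = 40
DEFAULT_KEEP_SCALES = (2, 8)
DEFAULT_SIGMA = 1.0

CHANNELS = ("donor_donor", "fret", "acceptor_direct")


class FretError(ValueError):
    """Raised for degenerate image inputs (empty masks, thin cells, ...)."""


@dataclass
class ChannelStack:
    """Time-lapse stacks of the three imaging channels.

    ``donor_donor`` is the CFP-CFP (donor) channel, ``fret`` the CFP-YFP
    sensitised-emission channel and ``acceptor_direct`` the bright YFP-YFP
    channel used for masking.  Arrays are (T, H, W); registration returns
    float arrays, acquisition data are unsigned 16-bit grey.
    """

    donor_donor: np.ndarray
    fret: np.ndarray
    acceptor_direct: np.ndarray

    def __post_init__(self) -> None:
        shapes = {c: getattr(self, c).shape for c in CHANNELS}
        if len(set(shapes.values())) != 1:
            raise FretError(f"channel shapes differ: {shapes}")
        if self.donor_donor.ndim != 3 or self.donor_donor.shape[0] < 1:
            raise FretError("channels must be (T, H, W) with T >= 1")

    @property
    def n_frames(self) -> int:
        return self.donor_donor.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.donor_donor.shape[1:]


@dataclass
class CellMask:
    """Largest thresholded object of one frame (single 8-connected blob)."""

    mask: np.ndarray  # bool (H, W)
    frame_index: int


@dataclass
class CrescentROI:
    """Ring mask plus its two extremal crescents for one frame."""

    ring: np.ndarray
    front: np.ndarray
    back: np.ndarray
    long_axis: int          # 0 = rows, 1 = columns
    selected_front: int     # 0 = low end of the long axis, 1 = high end
    frame_index: int = 0


@dataclass
class RatioTimecourse:
    """Per-frame mean leading-edge FRET ratio and per-cell summary."""

    front_mean: np.ndarray            # (T,), NaN where no valid pixel
    back_mean: np.ndarray
    n_pixels: np.ndarray              # valid (nonzero-denominator) front px
    rois: list[CrescentROI] = field(default_factory=list)

    @property
    def summary(self) -> float:
        """Mean over all frames with at least one valid pixel."""
        return float(np.nanmean(self.front_mean))

    def to_csv(self) -> str:
        lines = ["frame,front_mean,back_mean,n_pixels"]
        for t in range(len(self.front_mean)):
            lines.append(
                f"{t},{self.front_mean[t]:.6f},{self.back_mean[t]:.6f},"
                f"{int(self.n_pixels[t])}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "summary": self.summary,
                "front_mean": [None if np.isnan(v) else float(v) for v in self.front_mean],
                "back_mean": [None if np.isnan(v) else float(v) for v in self.back_mean],
                "n_pixels": [int(v) for v in self.n_pixels],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def register_channels(
    stack: ChannelStack,
    reference: str = "acceptor_direct",
    upsample_factor: int = 100,
) -> tuple[ChannelStack, np.ndarray]:
    """Align the moving channels onto ``reference`` frame by frame.

    Shifts are estimated to 1/upsample_factor of a pixel (default 0.01 px)
    by upsampled cross-correlation and applied in the Fourier domain, which
    preserves sub-pixel precision without an interpolation-kernel choice.
    Returns the registered stack and the estimated shifts, shape
    (T, n_moving, 2).  Degenerate (constant) frames get zero shift with a
    warning.
    """
    if reference not in CHANNELS:
        raise FretError(f"unknown reference channel {reference!r}")
    moving = [c for c in CHANNELS if c != reference]
    ref = np.asarray(getattr(stack, reference), dtype=float)
    out = {reference: ref.copy()}
    shifts = np.zeros((stack.n_frames, len(moving), 2))
    for ci, chan in enumerate(moving):
        data = np.asarray(getattr(stack, chan), dtype=float)
        reg = np.empty_like(data)
        for t in range(stack.n_frames):
            if ref[t].std() == 0 or data[t].std() == 0:
                warnings.warn(
                    f"frame {t}, channel {chan}: constant image, assuming zero shift",
                    stacklevel=2,
                )
                reg[t] = data[t]
                continue
            shift, _, _ = phase_cross_correlation(
                ref[t], data[t], upsample_factor=upsample_factor,
                normalization=None,
            )
            shifts[t, ci] = shift
            reg[t] = fourier_translate(data[t], shift)
            corr = np.corrcoef(ref[t].ravel(), reg[t].ravel())[0, 1]
            if not np.isfinite(corr) or corr < 0.2:
                warnings.warn(
                    f"frame {t}, channel {chan}: low-confidence shift "
                    f"(correlation {corr:.2f} after alignment)",
                    stacklevel=2,
                )
        out[chan] = reg
    return ChannelStack(**out), shifts


def fourier_translate(image: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Translate a 2-D image by a (possibly fractional) (dy, dx) shift."""
    f = np.fft.fft2(np.asarray(image, dtype=float))
    return np.real(np.fft.ifft2(ndimage.fourier_shift(f, shift)))


# ---------------------------------------------------------------------------
# a-trous wavelet band-pass
# ---------------------------------------------------------------------------

_KERNEL = np.array([1.0, 2.0, 1.0]) / 4.0


def _atrous_smooth(image: np.ndarray, scale: int) -> np.ndarray:
    """Separable smoothing at the given scale: the 3-tap kernel (1,2,1)/4
    with taps dilated by 2**(scale-1); mirror boundary handling."""
    dilation = 2 ** (scale - 1)
    kernel = np.zeros(2 * dilation + 1)
    kernel[[0, dilation, -1]] = _KERNEL
    out = ndimage.convolve1d(image, kernel, axis=0, mode="mirror")
    return ndimage.convolve1d(out, kernel, axis=1, mode="mirror")


def atrous_decompose(image: np.ndarray, n_scales: int):
    """Stationary wavelet decomposition: detail planes 1..n_scales and the
    residual smooth plane.  Summing all planes reconstructs the input."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise FretError("atrous transform expects a 2-D image")
    span = 2 ** (n_scales - 1) * 2 + 1
    if min(image.shape) < span:
        raise FretError(
            f"image {image.shape} smaller than the scale-{n_scales} kernel span {span}"
        )
    details = []
    current = image
    for scale in range(1, n_scales + 1):
        smooth = _atrous_smooth(current, scale)
        details.append(current - smooth)
        current = smooth
    return details, current


def atrous_bandpass(
    image: np.ndarray, keep_scales: tuple[int, int] = DEFAULT_KEEP_SCALES
) -> np.ndarray:
    """Band-pass filter: sum of a-trous detail planes ``keep_scales[0]`` to
    ``keep_scales[1]`` (default 2-8), removing high-frequency pixel noise
    (scale 1) and stationary background (the residual)."""
    lo, hi = keep_scales
    if not 1 <= lo <= hi:
        raise FretError(f"invalid keep_scales {keep_scales}")
    details, _ = atrous_decompose(image, hi)
    return np.sum(details[lo - 1: hi], axis=0)


# ---------------------------------------------------------------------------
# segmentation and ROIs
# ---------------------------------------------------------------------------

def segment_cell(
    filtered: np.ndarray, threshold: float = DEFAULT_THRESHOLD, frame_index: int = 0
) -> CellMask:
    """Largest 8-connected component above the fixed threshold."""
    binary = np.asarray(filtered) > threshold
    if not binary.any():
        raise FretError(f"frame {frame_index}: no pixel above threshold {threshold}")
    labels = measure.label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return CellMask(labels == int(np.argmax(counts)), frame_index)


def ring_and_crescents(
    cell: CellMask,
    width: int = DEFAULT_RING_WIDTH,
    front_hint: int | None = None,
    previous_front: np.ndarray | None = None,
) -> CrescentROI:
    """Build the ring mask and its two extremal crescents.

    The ring is the mask minus the mask eroded by a disc of radius ``width``
    (computed with the exact Euclidean distance transform, which is
    equivalent and much faster).  The axis-aligned minimum bounding box of
    the ring is divided into four equal parts along its longer axis; the two
    extremal quarters intersected with the ring give the crescents.  The
    front crescent is picked by ``front_hint`` (0 = low end, 1 = high end of
    the long axis) on the first frame and by maximal pixel overlap with
    ``previous_front`` on later frames.
    """
    mask = cell.mask
    if not mask.any():
        raise FretError(f"frame {cell.frame_index}: empty cell mask")
    dist = ndimage.distance_transform_edt(mask)
    eroded = dist > width
    if not eroded.any():
        raise FretError(
            f"frame {cell.frame_index}: cell thinner than twice the ring "
            f"width ({width} px); erosion leaves nothing"
        )
    ring = mask & ~eroded
    rows = np.flatnonzero(ring.any(axis=1))
    cols = np.flatnonzero(ring.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    axis = 0 if (r1 - r0) >= (c1 - c0) else 1
    lo, hi = (r0, r1) if axis == 0 else (c0, c1)
    quarter = (hi - lo) / 4.0
    coords = np.arange(ring.shape[axis])
    low_band = (coords >= lo) & (coords < lo + quarter)
    high_band = (coords >= hi - quarter) & (coords < hi)
    low = ring & (low_band[:, None] if axis == 0 else low_band[None, :])
    high = ring & (high_band[:, None] if axis == 0 else high_band[None, :])
    if previous_front is not None:
        overlap_low = int((low & previous_front).sum())
        overlap_high = int((high & previous_front).sum())
        selected = 1 if overlap_high > overlap_low else 0
    elif front_hint is not None:
        if front_hint not in (0, 1):
            raise FretError("front_hint must be 0 (low end) or 1 (high end)")
        selected = front_hint
    else:
        raise FretError("first frame needs a front_hint to identify the cell front")
    front, back = (high, low) if selected == 1 else (low, high)
    return CrescentROI(ring, front, back, axis, selected, cell.frame_index)


# ---------------------------------------------------------------------------
# ratio quantification
# ---------------------------------------------------------------------------

def leading_edge_ratio(
    stack: ChannelStack,
    rois: list[CrescentROI],
    sigma: float = DEFAULT_SIGMA,
) -> RatioTimecourse:
    """Mean FRET ratio (fret / donor_donor) inside the front crescent.

    Both channels are Gaussian-smoothed (default sigma 1.0 px) *before* the
    division — smoothing the ratio image instead provably changes means on
    gradient images — and zero-denominator pixels are excluded.  Frames in
    which the whole crescent has zero denominator yield NaN with a warning.
    """
    if len(rois) != stack.n_frames:
        raise FretError("one ROI per frame is required")
    T = stack.n_frames
    front_mean = np.full(T, np.nan)
    back_mean = np.full(T, np.nan)
    n_pixels = np.zeros(T, dtype=int)
    for t in range(T):
        num = ndimage.gaussian_filter(np.asarray(stack.fret[t], dtype=float), sigma)
        den = ndimage.gaussian_filter(
            np.asarray(stack.donor_donor[t], dtype=float), sigma
        )
        valid = den != 0
        for which, sel in (("front", rois[t].front), ("back", rois[t].back)):
            good = sel & valid
            n = int(good.sum())
            if which == "front":
                n_pixels[t] = n
            if n == 0:
                warnings.warn(
                    f"frame {t}: {which} crescent entirely zero-denominator",
                    stacklevel=2,
                )
                continue
            value = float(np.mean(num[good] / den[good]))
            if which == "front":
                front_mean[t] = value
            else:
                back_mean[t] = value
    return RatioTimecourse(front_mean, back_mean, n_pixels, list(rois))


@dataclass
class FretConfig:
    """Tunable pipeline parameters (all defaults per the acquisition setup
    the pipeline was designed for: 16-bit EMCCD frames)."""

    threshold: float = DEFAULT_THRESHOLD
    ring_width: int = DEFAULT_RING_WIDTH
    keep_scales: tuple[int, int] = DEFAULT_KEEP_SCALES
    sigma: float = DEFAULT_SIGMA
    front_hint: int = 1
    register: bool = True


def quantify_stack(stack: ChannelStack, config: FretConfig | None = None):
    """Run the full pipeline; returns (RatioTimecourse, masks, shifts)."""
    config = config or FretConfig()
    shifts = None
    if config.register:
        stack, shifts = register_channels(stack)
    masks: list[CellMask] = []
    rois: list[CrescentROI] = []
    previous_front: np.ndarray | None = None
    for t in range(stack.n_frames):
        filtered = atrous_bandpass(stack.acceptor_direct[t], config.keep_scales)
        cell = segment_cell(filtered, config.threshold, frame_index=t)
        roi = ring_and_crescents(
            cell,
            config.ring_width,
            front_hint=config.front_hint if previous_front is None else None,
            previous_front=previous_front,
        )
        previous_front = roi.front
        masks.append(cell)
        rois.append(roi)
    timecourse = leading_edge_ratio(stack, rois, config.sigma)
    return timecourse, masks, shifts
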