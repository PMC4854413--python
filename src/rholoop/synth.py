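"""Seed-deterministic generators standing in for the study's raw data.

Two generators:

* random logical networks of configurable size and edge density, used as a
  test surface for the simulation and perturbation machinery;
* two-channel FRET image stacks of a moving elliptical "cell" with a known
  front/back ratio step, a bright masking channel, Poisson-like shot noise
  and Gaussian read noise — a rigid-translation stand-in for real biosensor
  acquisitions that lets every stage of the image pipeline be checked
  against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expr import Lit, Not, and_, or_
from .fret import ChannelStack, fourier_translate
from .model import BooleanNetwork, NodeSpec, UpdateRule


@dataclass(frozen=True)
class RandomNetworkParams:
    n_nodes: int = 10
    edge_density: float = 0.25       # expected fraction of nodes regulating each node
    activator_ratio: float = 0.7     # probability a literal enters un-negated
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        if not 0 <= self.activator_ratio <= 1:
            raise ValueError("activator_ratio must be in [0, 1]")


def gen_random_network(p: RandomNetworkParams) -> BooleanNetwork:
    """A valid random network: every node gets a rule that is an OR of 1-3
    conjunctions over randomly drawn (possibly negated) literals."""
    rng = np.random.default_rng(p.seed)
    names = [f"n{i:02d}" for i in range(p.n_nodes)]
    nodes = [
        NodeSpec(name, "intermediate", int(rng.integers(2))) for name in names
    ]
    rules = []
    for name in names:
        n_regs = max(1, int(rng.binomial(p.n_nodes, p.edge_density)))
        regs = list(rng.choice(names, size=min(n_regs, p.n_nodes), replace=False))
        n_terms = int(rng.integers(1, 4))
        terms = []
        for _ in range(n_terms):
            size = int(rng.integers(1, min(3, len(regs)) + 1))
            chosen = rng.choice(regs, size=size, replace=False)
            literals = [
                Lit(r) if rng.random() < p.activator_ratio else Not(Lit(r))
                for r in chosen
            ]
            terms.append(and_(*literals))
        rules.append(UpdateRule(name, or_(*terms), "random"))
    return BooleanNetwork(nodes, rules, metadata=f"random network seed={p.seed}")


# ---------------------------------------------------------------------------
# synthetic FRET stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCellParams:
    """Ground-truth parameters of a generated biosensor movie.

    The "cell" is an ellipse translating rigidly by ``translation`` px per
    frame; the true FRET ratio is ``ratio_front`` on the leading half
    (towards the direction of motion, along the long axis) and
    ``ratio_back`` on the trailing half.  ``noise`` is a photon gain:
    0 gives noiseless expected intensities, 1 pure Poisson counting, larger
    values proportionally noisier; Gaussian read noise has sd ``2 * noise``.
    """

    shape: tuple[int, int] = (320, 320)
    semi_axes: tuple[float, float] = (110.0, 80.0)  # (long, short), px
    center: tuple[float, float] = (160.0, 160.0)    # (x, y) at frame 0
    translation: tuple[float, float] = (2.0, 0.0)   # (dx, dy) per frame
    ratio_front: float = 1.8
    ratio_back: float = 1.1
    donor_level: float = 1000.0
    acceptor_level: float = 30000.0
    background: float = 0.0
    noise: float = 0.0
    n_frames: int = 20
    channel_shift: tuple[float, float] = (0.0, 0.0)  # (dy, dx) of donor+fret
    distractor: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio_front <= 0 or self.ratio_back <= 0:
            raise ValueError("ratios must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        H, W = self.shape
        a = self.semi_axes[0]
        b = self.semi_axes[1]
        for t in (0, self.n_frames - 1):
            cx = self.center[0] + t * self.translation[0]
            cy = self.center[1] + t * self.translation[1]
            if not (a <= cx <= W - 1 - a and b <= cy <= H - 1 - b):
                raise ValueError(f"ellipse leaves the frame at t={t}")


@dataclass
class FretGroundTruth:
    """What the generator knows: per-frame masks, centres and true ratios."""

    masks: np.ndarray                 # (T, H, W) bool
    centers: np.ndarray               # (T, 2) as (x, y)
    ratio_front: float
    ratio_back: float
    front_hint: int                   # crescent index of the leading edge
    channel_shift: tuple[float, float]
    ratio_map: np.ndarray = field(repr=False, default=None)  # (T, H, W)


def gen_fret_stack(p: SyntheticCellParams) -> tuple[ChannelStack, FretGroundTruth]:
    """Generate the three channels plus the ground-truth record."""
    rng = np.random.default_rng(p.seed)
    H, W = p.shape
    yy, xx = np.mgrid[0:H, 0:W]
    T = p.n_frames
    donor = np.zeros((T, H, W))
    fret = np.zeros((T, H, W))
    acceptor = np.zeros((T, H, W))
    masks = np.zeros((T, H, W), dtype=bool)
    centers = np.zeros((T, 2))
    ratio_maps = np.zeros((T, H, W))
    a, b = p.semi_axes
    dx, dy = p.translation
    motion = np.array([dx, dy])
    if not motion.any():
        motion = np.array([1.0, 0.0])
    # long axis along x: the leading half is the side of the centre that the
    # x-component of motion points to (pipeline crescent index 1 = high end)
    front_positive = motion[0] >= 0
    for t in range(T):
        cx = p.center[0] + t * dx
        cy = p.center[1] + t * dy
        centers[t] = (cx, cy)
        inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        masks[t] = inside
        ahead = (xx - cx) > 0 if front_positive else (xx - cx) < 0
        ratio = np.where(ahead, p.ratio_front, p.ratio_back)
        ratio_maps[t] = ratio
        donor[t] = np.where(inside, p.donor_level, 0.0) + p.background
        fret[t] = np.where(inside, ratio * p.donor_level, 0.0) + p.background
        acceptor[t] = np.where(inside, p.acceptor_level, 0.0) + p.background
        if p.distractor:
            blob = (xx - W * 0.08) ** 2 + (yy - H * 0.08) ** 2 <= 10.0 ** 2
            acceptor[t] = np.where(blob, p.acceptor_level, acceptor[t])
    if p.noise > 0:
        for arr in (donor, fret, acceptor):
            counts = rng.poisson(np.maximum(arr, 0) / p.noise) * p.noise
            arr[:] = counts + rng.normal(0.0, 2.0 * p.noise, size=arr.shape)
    if any(p.channel_shift):
        shift = np.asarray(p.channel_shift, dtype=float)
        for arr in (donor, fret):
            for t in range(T):
                arr[t] = fourier_translate(arr[t], shift)
    to_u16 = lambda a: np.clip(np.round(a), 0, 65535).astype(np.uint16)
    stack = ChannelStack(to_u16(donor), to_u16(fret), to_u16(acceptor))
    truth = FretGroundTruth(
        masks=masks,
        centers=centers,
        ratio_front=p.ratio_front,
        ratio_back=p.ratio_back,
        front_hint=1 if front_positive else 0,
        channel_shift=p.channel_shift,
        ratio_map=ratio_maps,
    )
    return stack, truth
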