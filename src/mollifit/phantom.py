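"""Synthetic MOLLI phantom generator.

Emulates the two clinical sampling schemes — pre-contrast MOLLI 5(3)3
(5 images after the first inversion, a pause, 3 after the second; 8 TIs) and
post-contrast MOLLI 4(1)3(1)2 (4 + 3 + 2 images across three inversions;
9 TIs) — on a digital cardiac phantom: a blood-pool disk inside a myocardial
annulus on a zero-signal (air) background.  Every pixel's noiseless signal
follows the three-parameter relaxation curve of its compartment; noise is
Rician by default (independent Gaussian noise on two orthogonal channels,
then magnitude), matching magnitude MR images.  Ground truth (per-pixel
a, b, c, T1 and compartment masks) is returned alongside so every fitting
stage can be validated without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapping import TIImageStack
from .signal_model import RelaxationParams, zero_crossing_time

__all__ = [
    "Disk",
    "Annulus",
    "Rectangle",
    "Compartment",
    "PhantomSpec",
    "GroundTruth",
    "MOLLI_BLOCKS",
    "generate_molli_tis",
    "generate_phantom",
    "canonical_pre_spec",
    "canonical_post_spec",
]

#: images acquired per inversion block, by scheme tag
MOLLI_BLOCKS = {"5(3)3": (5, 3), "4(1)3(1)2": (4, 3, 2)}


@dataclass(frozen=True)
class Disk:
    """Filled circle; center in (row, col) pixels."""

    center: tuple[float, float]
    radius: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        d2 = (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2
        return d2 <= self.radius**2


@dataclass(frozen=True)
class Annulus:
    """Ring between two radii; center in (row, col) pixels."""

    center: tuple[float, float]
    r_inner: float
    r_outer: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        d2 = (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2
        return (d2 >= self.r_inner**2) & (d2 <= self.r_outer**2)


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned box, half-open on the high edge: rows [r0, r1), cols [c0, c1)."""

    r0: int
    c0: int
    r1: int
    c1: int

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.r0 : self.r1, self.c0 : self.c1] = True
        return m


@dataclass(frozen=True)
class Compartment:
    """A tissue region with its relaxation ground truth.

    ``a`` and ``c`` follow the ideal-inversion convention ``a = -2c`` unless
    set explicitly; ``t1_ms`` is the *true* T1 — for the ideal inversion it
    equals the apparent T1, so the generating rate is ``b = 1/t1_ms``
    rescaled by the Look-Locker relation when ``a != -2c``.
    """

    name: str
    region: object
    t1_ms: float
    a: float
    c: float

    def __post_init__(self):
        if self.t1_ms <= 0:
            raise ValueError("compartment t1_ms must be positive")

    @classmethod
    def ideal(cls, name: str, region, t1_ms: float, m0: float) -> "Compartment":
        """Ideal inversion: plateau ``m0``, start ``-m0`` (a = 2 m0, c = -m0)."""
        return cls(name=name, region=region, t1_ms=t1_ms, a=2.0 * m0, c=-m0)

    def params(self) -> RelaxationParams:
        # invert the Look-Locker relation: T1 = (1/b)(a/(a+c) - 1)
        factor = self.a / (self.a + self.c) - 1.0
        if factor <= 0:
            raise ValueError("compartment (a, c) must give a positive T1 factor")
        return RelaxationParams(a=self.a, b=factor / self.t1_ms, c=self.c)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic MOLLI acquisition.

    ``noise_sigma`` is the per-channel Gaussian sd in signal units;
    ``noise_model`` is ``"rician"`` (two-channel, magnitude) or ``"gaussian"``
    (added to the signed signal, for analytic tests).  ``seed`` fully
    determines the output.  Later-listed compartments take precedence where
    regions overlap; uncovered pixels are zero-signal air.
    """

    shape: tuple[int, int] = (64, 64)
    compartments: tuple[Compartment, ...] = ()
    scheme: str = "5(3)3"
    rr_ms: float = 1000.0
    ti_bases: tuple[float, ...] = (120.0, 200.0)
    noise_sigma: float = 0.0
    seed: int = 0
    is_magnitude: bool = True
    noise_model: str = "rician"

    def __post_init__(self):
        if not self.compartments:
            raise ValueError("phantom needs at least one compartment")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Per-pixel generating parameters and compartment masks."""

    t1: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    masks: dict[str, np.ndarray]
    tissue: np.ndarray  # True where any compartment covers the pixel

    def flip_count(self, tis: np.ndarray, row: int, col: int) -> int:
        """Analytic polarity flip count: number of TIs before the zero crossing."""
        p = RelaxationParams(self.a[row, col], self.b[row, col], self.c[row, col])
        t0 = zero_crossing_time(p)
        return int(np.sum(np.asarray(tis) < t0))


def generate_molli_tis(scheme: str, rr_ms: float, ti_bases) -> np.ndarray:
    """Pooled, sorted inversion times of a MOLLI scheme.

    Block ``k`` (with ``n_k`` images and first-TI offset ``ti_bases[k]``)
    contributes ``ti_bases[k] + j * rr_ms`` for ``j = 0..n_k-1``; blocks are
    pooled and sorted ascending.  5(3)3 yields 8 TIs, 4(1)3(1)2 yields 9.
    """
    if scheme not in MOLLI_BLOCKS:
        raise ValueError(f"unknown MOLLI scheme {scheme!r}; know {sorted(MOLLI_BLOCKS)}")
    if rr_ms <= 0:
        raise ValueError("rr_ms must be positive")
    blocks = MOLLI_BLOCKS[scheme]
    bases = tuple(float(b) for b in ti_bases)
    if len(bases) != len(blocks):
        raise ValueError(
            f"scheme {scheme} has {len(blocks)} inversion blocks, got {len(bases)} ti_bases"
        )
    if len(set(bases)) != len(bases):
        raise ValueError("ti_bases must be distinct")
    tis = np.sort(
        np.concatenate([base + rr_ms * np.arange(nk) for base, nk in zip(bases, blocks)])
    )
    if np.any(np.diff(tis) <= 0):
        raise ValueError("ti_bases and rr_ms produce duplicate inversion times")
    return tis


def generate_phantom(spec: PhantomSpec) -> tuple[TIImageStack, GroundTruth]:
    """Simulate a TI image stack plus its ground truth.

    The noiseless signed signal of each covered pixel is its compartment's
    relaxation curve at each TI.  Under the Rician model, Gaussian noise of
    sd ``noise_sigma`` is added independently to the signed signal and to a
    zero-mean orthogonal channel, and the magnitude is taken; under the
    Gaussian model the noise is added to the signed signal directly.
    """
    rows, cols = spec.shape
    tis = generate_molli_tis(spec.scheme, spec.rr_ms, spec.ti_bases)
    n = tis.size

    a = np.zeros(spec.shape)
    b = np.zeros(spec.shape)
    c = np.zeros(spec.shape)
    t1 = np.full(spec.shape, np.nan)
    masks: dict[str, np.ndarray] = {}
    claimed = np.zeros(spec.shape, dtype=bool)
    for comp in spec.compartments:  # later compartments take precedence
        m = comp.region.mask(spec.shape)
        p = comp.params()
        a[m], b[m], c[m] = p.a, p.b, p.c
        t1[m] = comp.t1_ms
        masks[comp.name] = m
        claimed |= m
    # exclusive masks: later-listed compartments win overlaps
    taken = np.zeros(spec.shape, dtype=bool)
    for comp in reversed(spec.compartments):
        masks[comp.name] = masks[comp.name] & ~taken
        taken |= masks[comp.name]

    signed = a[..., None] * (1.0 - np.exp(-b[..., None] * tis)) + c[..., None]
    signed[~claimed] = 0.0

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        if spec.noise_model == "rician":
            real = signed + rng.normal(0.0, spec.noise_sigma, signed.shape)
            imag = rng.normal(0.0, spec.noise_sigma, signed.shape)
            noisy = np.hypot(real, imag) if spec.is_magnitude else real
        elif spec.noise_model == "gaussian":
            noisy = signed + rng.normal(0.0, spec.noise_sigma, signed.shape)
            if spec.is_magnitude:
                noisy = np.abs(noisy)
        else:
            raise ValueError(f"unknown noise_model {spec.noise_model!r}")
    else:
        noisy = np.abs(signed) if spec.is_magnitude else signed.copy()

    stack = TIImageStack(
        voxels=noisy,
        tis=tis,
        protocol="pre_5(3)3" if spec.scheme == "5(3)3" else "post_4(1)3(1)2",
        is_magnitude=spec.is_magnitude,
    )
    truth = GroundTruth(t1=t1, a=a, b=b, c=c, masks=masks, tissue=claimed)
    return stack, truth


def _cardiac_compartments(shape, myo_t1, blood_t1, myo_m0=175.0, blood_m0=200.0):
    r0, c0 = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r_out = 0.42 * min(shape)
    r_in = 0.26 * min(shape)
    return (
        Compartment.ideal("myocardium", Annulus((r0, c0), r_in, r_out), myo_t1, myo_m0),
        Compartment.ideal("blood", Disk((r0, c0), 0.96 * r_in), blood_t1, blood_m0),
    )


def canonical_pre_spec(
    shape=(64, 64), noise_sigma: float = 0.0, seed: int = 0, **kw
) -> PhantomSpec:
    """Pre-contrast cardiac phantom: myocardium T1 = 950 ms, blood T1 = 1500 ms, 5(3)3."""
    return PhantomSpec(
        shape=shape,
        compartments=_cardiac_compartments(shape, 950.0, 1500.0),
        scheme="5(3)3",
        ti_bases=(120.0, 200.0),
        noise_sigma=noise_sigma,
        seed=seed,
        **kw,
    )


def canonical_post_spec(
    shape=(64, 64), noise_sigma: float = 0.0, seed: int = 0, **kw
) -> PhantomSpec:
    """Post-contrast cardiac phantom: myocardium T1 = 470 ms, blood T1 = 280 ms, 4(1)3(1)2."""
    return PhantomSpec(
        shape=shape,
        compartments=_cardiac_compartments(shape, 470.0, 280.0),
        scheme="4(1)3(1)2",
        ti_bases=(120.0, 200.0, 280.0),
        noise_sigma=noise_sigma,
        seed=seed,
        **kw,
    )
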