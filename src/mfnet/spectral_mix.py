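"""Frequency-space amplitude mixing.

An image is decomposed into the amplitude (modulus) and phase (argument)
of its 2-D discrete Fourier transform.  Amplitude spectra of two
co-registered modalities of the same case are blended by a convex
combination at ratio ``lam`` while the source phase — which carries the
anatomical semantics, and therefore the segmentation label — is kept
unchanged.  The inverse transform of the blended spectrum yields an
augmented image whose "style" interpolates between the two modalities.

Conventions: unnormalized forward DFT, ``1/(W*H)``-normalized inverse
(the numpy default).  The mixing result is invariant to this choice as
long as forward and inverse agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError, RangeError

__all__ = [
    "SpectralPair",
    "MixedSample",
    "decompose",
    "compose",
    "mix_amplitude",
    "mix_images",
    "sample_lambda",
]


@dataclass(frozen=True)
class SpectralPair:
    """Amplitude/phase decomposition of one real 2-D slice.

    ``amplitude`` is non-negative; ``phase`` is in radians in (-pi, pi].
    Together they losslessly represent the complex spectrum
    ``amplitude * exp(1j * phase)``.
    """

    amplitude: np.ndarray
    phase: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape


@dataclass(frozen=True)
class MixedSample:
    """An amplitude-mixed image together with its provenance.

    The mask is inherited from the source modality: phase (and hence
    anatomy) is untouched by amplitude mixing, so the source label stays
    valid.
    """

    image: np.ndarray
    lam: float
    source_modality: str
    donor_modality: str
    mask: np.ndarray

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise RangeError(f"lam must be in [0, 1], got {self.lam}")
        if self.source_modality == self.donor_modality:
            raise InvalidInputError(
                "source and donor modality must differ, both are "
                f"{self.source_modality!r}"
            )


def decompose(image: np.ndarray, slice_name: str = "<image>") -> SpectralPair:
    """Split a real 2-D image into amplitude and phase spectra."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 2:
        raise InvalidInputError(
            f"decompose expects a 2-D image of at least 2x2, got shape {image.shape}"
        )
    if not np.all(np.isfinite(image)):
        raise InvalidInputError(f"non-finite values in slice {slice_name}")
    spectrum = np.fft.fft2(image)
    return SpectralPair(amplitude=np.abs(spectrum), phase=np.angle(spectrum))


def compose(amplitude: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Inverse transform of ``amplitude * exp(1j * phase)``; real part."""
    amplitude = np.asarray(amplitude, dtype=np.float64)
    phase = np.asarray(phase, dtype=np.float64)
    if amplitude.shape != phase.shape:
        raise InvalidInputError(
            f"amplitude shape {amplitude.shape} != phase shape {phase.shape}"
        )
    if np.any(amplitude < 0):
        raise InvalidInputError("amplitude must be non-negative")
    return np.fft.ifft2(amplitude * np.exp(1j * phase)).real


def mix_amplitude(
    a_src: np.ndarray,
    a_donor: np.ndarray,
    lam: float,
    band_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Convex combination ``(1 - lam) * a_src + lam * a_donor``.

    ``band_mask``, if given, restricts mixing to the True entries of a
    boolean frequency mask (source amplitude is kept elsewhere).  The
    default mixes the full spectrum.
    """
    a_src = np.asarray(a_src, dtype=np.float64)
    a_donor = np.asarray(a_donor, dtype=np.float64)
    if a_src.shape != a_donor.shape:
        raise InvalidInputError(
            f"amplitude shapes differ: {a_src.shape} vs {a_donor.shape}"
        )
    if not (0.0 <= lam <= 1.0):
        raise RangeError(f"lam must be in [0, 1], got {lam}")
    mixed = (1.0 - lam) * a_src + lam * a_donor
    if band_mask is not None:
        band_mask = np.asarray(band_mask, dtype=bool)
        if band_mask.shape != a_src.shape:
            raise InvalidInputError("band_mask shape must match amplitudes")
        mixed = np.where(band_mask, mixed, a_src)
    return mixed


def mix_images(
    src,
    donor,
    lam: float,
    band_mask: np.ndarray | None = None,
    clip: bool = True,
    _allow_same_modality: bool = False,
) -> MixedSample:
    """Full pipeline: decompose both slices, mix amplitudes, recompose.

    ``src`` and ``donor`` are :class:`~mfnet.data_io.ModalityImage`-like
    objects (fields ``pixels``, ``mask``, ``modality_id``) of the same
    case with identical spatial shape and distinct modalities.  The
    output keeps the source mask and is clipped to [0, 1] unless
    ``clip=False`` (useful for spectral-linearity checks).
    """
    if src.pixels.shape != donor.pixels.shape:
        raise InvalidInputError(
            f"source shape {src.pixels.shape} != donor shape {donor.pixels.shape}"
        )
    if src.modality_id == donor.modality_id and not _allow_same_modality:
        raise InvalidInputError(
            f"source and donor modality must differ, both are {src.modality_id!r}"
        )
    sp_src = decompose(src.pixels, slice_name=getattr(src, "source_path", "<src>"))
    sp_donor = decompose(donor.pixels, slice_name=getattr(donor, "source_path", "<donor>"))
    mixed_amp = mix_amplitude(sp_src.amplitude, sp_donor.amplitude, lam, band_mask)
    image = compose(mixed_amp, sp_src.phase)
    if clip:
        image = np.clip(image, 0.0, 1.0)
    donor_id = donor.modality_id
    if src.modality_id == donor_id:  # only reachable with _allow_same_modality
        donor_id = f"{donor_id}*"
    return MixedSample(
        image=image,
        lam=float(lam),
        source_modality=src.modality_id,
        donor_modality=donor_id,
        mask=np.asarray(src.mask).copy(),
    )


def sample_lambda(
    rng: np.random.Generator,
    low: float = 0.0,
    high: float = 1.0,
) -> float:
    """Draw the interpolation ratio uniformly from [low, high] (default [0, 1])."""
    if not (0.0 <= low <= high <= 1.0):
        raise RangeError(f"invalid lambda range [{low}, {high}]")
    if low == high:
        return float(low)
    return float(rng.uniform(low, high))
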