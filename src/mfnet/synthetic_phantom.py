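"""Synthetic multi-modal, two-domain head-slice phantoms.

Each case is a shared tissue-label geometry (head ellipse, a few internal
structures, one tumour blob) rendered into three modality images via
modality-specific tissue->intensity transfer curves, then corrupted by a
smooth multiplicative bias field and additive Gaussian noise.  Domains
"A" and "B" share the geometry model but differ in appearance
(transfer curves, bias amplitude, noise), emulating two acquisition
sites with different scanners and contrast agents.  The tumour blob is the
segmentation target; the mask is valid for all three modalities by
construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import GenerationError, InvalidInputError

__all__ = [
    "PhantomCase",
    "DomainParams",
    "default_domain_params",
    "generate_case",
    "generate_dataset",
    "write_dataset",
    "MODALITIES",
    "LABELS",
]

MODALITIES = ("m1", "m2", "m3")

# tissue labels of the shared geometry
LABELS = {
    "background": 0,
    "head": 1,
    "structure_a": 2,
    "structure_b": 3,
    "structure_c": 4,
    "tumour": 5,
    "tumour_rim": 6,
}


@dataclass(frozen=True)
class DomainParams:
    """Appearance parameters of one domain.

    ``transfer`` maps modality id -> per-label intensity lookup (index =
    tissue label).  Geometry is never part of this object: the domain
    shift is appearance-only.
    """

    domain_id: str
    transfer: dict[str, np.ndarray]
    bias_amplitude: float
    noise_sigma: float
    contrast_jitter: float = 0.05


@dataclass(frozen=True)
class PhantomCase:
    case_id: str
    domain_id: str
    images: dict[str, np.ndarray]
    mask: np.ndarray
    geometry_seed: int
    appearance_seed: int
    tissue: np.ndarray = field(repr=False, default=None)


def default_domain_params(domain_id: str) -> DomainParams:
    """Built-in appearance presets for the two domains.

    Modality roles: m1 structure-bright (anatomy), m2 fluid-bright,
    m3 rim-enhanced tumour.  Domain B shifts every transfer curve by at
    least 0.08 on some tissue and uses different bias/noise levels.
    """
    if domain_id == "A":
        t = {
            "m1": np.array([0.02, 0.55, 0.75, 0.40, 0.65, 0.35, 0.38]),
            "m2": np.array([0.02, 0.35, 0.20, 0.80, 0.30, 0.70, 0.65]),
            "m3": np.array([0.02, 0.50, 0.65, 0.45, 0.55, 0.30, 0.90]),
        }
        return DomainParams(domain_id="A", transfer=t, bias_amplitude=0.10,
                            noise_sigma=0.02)
    if domain_id == "B":
        # B's curves are convex blends of A's modality curves plus small
        # offsets: an appearance-only shift of the kind produced by a
        # different scanner/contrast agent.  Each curve differs from its
        # domain-A counterpart by >= 0.08 on at least one tissue.
        t = {
            "m1": np.array([0.05, 0.47, 0.4775, 0.65, 0.4875, 0.5725, 0.5585]),
            "m2": np.array([0.00, 0.405, 0.405, 0.605, 0.405, 0.48, 0.755]),
            "m3": np.array([0.04, 0.5425, 0.715, 0.4475, 0.615, 0.3425, 0.686]),
        }
        return DomainParams(domain_id="B", transfer=t, bias_amplitude=0.16,
                            noise_sigma=0.035)
    raise InvalidInputError(f"unknown domain id {domain_id!r} (expected 'A' or 'B')")


def _ellipse_mask(size: int, cy, cx, ry, rx, angle) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - cy
    x = xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * x + sa * y
    v = -sa * x + ca * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _make_geometry(rng: np.random.Generator, size: int, max_tries: int = 50):
    """Tissue-label map and tumour mask; tumour is 1-8 % of the head area."""
    tissue = np.zeros((size, size), dtype=np.int8)
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    ry = rng.uniform(0.33, 0.42) * size
    rx = rng.uniform(0.30, 0.40) * size
    head = _ellipse_mask(size, cy, cx, ry, rx, rng.uniform(-0.3, 0.3))
    tissue[head] = LABELS["head"]
    head_area = int(head.sum())

    # internal structures: 2-4 ellipses strictly inside the head
    n_struct = int(rng.integers(2, 5))
    struct_labels = [LABELS["structure_a"], LABELS["structure_b"], LABELS["structure_c"]]
    for j in range(n_struct):
        for _ in range(max_tries):
            scy = cy + rng.uniform(-0.5, 0.5) * ry
            scx = cx + rng.uniform(-0.5, 0.5) * rx
            sry = rng.uniform(0.08, 0.22) * ry
            srx = rng.uniform(0.08, 0.22) * rx
            blob = _ellipse_mask(size, scy, scx, sry, srx, rng.uniform(0, np.pi))
            if blob.any() and (blob <= head).all():
                tissue[blob] = struct_labels[j % len(struct_labels)]
                break

    # tumour blob: irregular ellipse, 1-8 % of head area, inside the head
    target_frac = rng.uniform(0.015, 0.07)
    for _ in range(max_tries):
        r0 = np.sqrt(target_frac * head_area / np.pi)
        tcy = cy + rng.uniform(-0.45, 0.45) * ry
        tcx = cx + rng.uniform(-0.45, 0.45) * rx
        tum = _ellipse_mask(
            size, tcy, tcx,
            r0 * rng.uniform(0.8, 1.25), r0 * rng.uniform(0.8, 1.25),
            rng.uniform(0, np.pi),
        )
        # roughen the boundary a little, then close holes
        jitter = rng.random(tum.shape) < 0.4
        tum_r = tum & ~(jitter & ~ndimage.binary_erosion(tum, iterations=1))
        tum_r = ndimage.binary_closing(tum_r)
        frac = tum_r.sum() / head_area
        if tum_r.any() and (tum_r <= head).all() and 0.01 <= frac <= 0.08:
            core = ndimage.binary_erosion(tum_r, iterations=max(1, size // 64))
            tissue[tum_r] = LABELS["tumour_rim"]
            if core.any():
                tissue[core] = LABELS["tumour"]
            return tissue, tum_r
    raise GenerationError(
        f"could not place a feasible tumour after {max_tries} tries"
    )


def _bias_field(rng: np.random.Generator, size: int, amplitude: float) -> np.ndarray:
    coarse = rng.random((4, 4))
    field_ = ndimage.zoom(coarse, size / 4.0, order=3, mode="nearest")[:size, :size]
    field_ = (field_ - field_.min()) / max(np.ptp(field_), 1e-12)
    return 1.0 + amplitude * (field_ - 0.5)


def generate_case(
    geometry_seed: int,
    appearance_seed: int,
    domain_params: DomainParams,
    size: int = 96,
    case_id: str = "case_0000",
) -> PhantomCase:
    """Render one deterministic phantom case.

    Geometry depends only on ``geometry_seed``; appearance (transfer
    jitter, bias field, noise) only on ``appearance_seed`` and the
    domain parameters, so the same geometry can be re-rendered in either
    domain.
    """
    if size < 16:
        raise InvalidInputError(f"size must be >= 16, got {size}")
    geo_rng = np.random.default_rng(geometry_seed)
    app_rng = np.random.default_rng(appearance_seed)
    tissue, tumour = _make_geometry(geo_rng, size)
    images: dict[str, np.ndarray] = {}
    for mod in MODALITIES:
        curve = domain_params.transfer[mod].copy()
        jit = domain_params.contrast_jitter
        curve = np.clip(curve + app_rng.uniform(-jit, jit, size=curve.shape), 0.0, 1.0)
        img = curve[tissue]
        img = img * _bias_field(app_rng, size, domain_params.bias_amplitude)
        img = img + app_rng.normal(0.0, domain_params.noise_sigma, size=img.shape)
        images[mod] = np.clip(img, 0.0, 1.0)
    return PhantomCase(
        case_id=case_id,
        domain_id=domain_params.domain_id,
        images=images,
        mask=tumour.astype(np.uint8),
        geometry_seed=geometry_seed,
        appearance_seed=appearance_seed,
        tissue=tissue,
    )


def generate_dataset(
    n_cases: int,
    domain_id: str,
    master_seed: int,
    size: int = 96,
    domain_params: DomainParams | None = None,
    case_prefix: str | None = None,
) -> list[PhantomCase]:
    """Generate ``n_cases`` independent cases, deterministic in ``master_seed``."""
    if n_cases < 1:
        raise InvalidInputError("n_cases must be >= 1")
    params = domain_params or default_domain_params(domain_id)
    prefix = case_prefix if case_prefix is not None else f"{domain_id}"
    seed_seq = np.random.SeedSequence([master_seed, ord(domain_id[0])])
    children = seed_seq.spawn(n_cases)
    cases = []
    for i, child in enumerate(children):
        gseed, aseed = child.generate_state(2).tolist()
        cases.append(
            generate_case(
                geometry_seed=gseed,
                appearance_seed=aseed,
                domain_params=params,
                size=size,
                case_id=f"{prefix}_{i:04d}",
            )
        )
    return cases


def write_dataset(cases: list[PhantomCase], out_dir, manifest_name: str = "manifest.csv") -> Path:
    """Write cases as 8-bit grayscale PNGs plus a manifest CSV.

    Manifest columns: ``path,mask_path,case_id,domain,modality``; paths
    are relative to the manifest location.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        mask_name = f"{case.case_id}_mask.png"
        iio.imwrite(out_dir / mask_name, (case.mask * 255).astype(np.uint8))
        for mod, img in case.images.items():
            img_name = f"{case.case_id}_{mod}.png"
            iio.imwrite(
                out_dir / img_name,
                np.round(img * 255).astype(np.uint8),
            )
            rows.append([img_name, mask_name, case.case_id, case.domain_id, mod])
    manifest = out_dir / manifest_name
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "mask_path", "case_id", "domain", "modality"])
        writer.writerows(rows)
    return manifest
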