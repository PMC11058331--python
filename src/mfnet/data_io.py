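"""Dataset manifests, image/mask loading and the two training streams.

A manifest is a CSV with header ``path,mask_path,case_id,domain,modality``
(paths relative to the manifest file).  Splits are assigned per case —
never per slice — so no case leaks across train/val/test.  The original
stream yields unmodified (image, mask) samples; the mixed stream yields
amplitude-mixed samples built on the fly with a freshly drawn ratio per
item.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import spectral_mix
from .exceptions import InvalidInputError, ManifestError

logger = logging.getLogger(__name__)

__all__ = [
    "ModalityImage",
    "ManifestRecord",
    "DatasetManifest",
    "load_manifest",
    "load_image",
    "split_cases",
    "make_streams",
    "DataStreams",
]

REQUIRED_COLUMNS = ("path", "mask_path", "case_id", "domain", "modality")


@dataclass(frozen=True)
class ModalityImage:
    """One loaded slice of one modality of one case, with its binary mask."""

    pixels: np.ndarray
    mask: np.ndarray
    case_id: str
    modality_id: str
    domain_id: str
    source_path: str = "<memory>"

    def __post_init__(self):
        if self.pixels.shape != self.mask.shape:
            raise InvalidInputError(
                f"pixels shape {self.pixels.shape} != mask shape {self.mask.shape} "
                f"({self.source_path})"
            )
        if not np.all(np.isin(self.mask, (0, 1))):
            raise InvalidInputError(f"mask is not binary ({self.source_path})")


@dataclass(frozen=True)
class ManifestRecord:
    path: Path
    mask_path: Path
    case_id: str
    domain_id: str
    modality_id: str
    split: str | None = None


@dataclass(frozen=True)
class DatasetManifest:
    records: tuple[ManifestRecord, ...]

    def __post_init__(self):
        self._check_split_integrity()

    def _check_split_integrity(self) -> None:
        by_case: dict[str, set] = {}
        for r in self.records:
            if r.split is not None:
                by_case.setdefault(r.case_id, set()).add(r.split)
        offenders = [c for c, s in by_case.items() if len(s) > 1]
        if offenders:
            raise ManifestError(
                f"cases assigned to multiple splits: {sorted(offenders)}"
            )

    @property
    def case_ids(self) -> list[str]:
        seen = dict.fromkeys(r.case_id for r in self.records)
        return list(seen)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(
            tuple(r for r in self.records if r.split == split)
        )


def load_manifest(path, check_files: bool = True) -> DatasetManifest:
    """Read and validate a manifest CSV; all offending rows are reported."""
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in cols]
        if missing:
            raise ManifestError(f"manifest {path} missing columns: {missing}")
        records = []
        errors = []
        base = path.parent
        for i, row in enumerate(reader, start=2):  # header is line 1
            img = base / row["path"]
            msk = base / row["mask_path"]
            if check_files:
                if not img.exists():
                    errors.append(f"row {i}: missing image file {img}")
                if not msk.exists():
                    errors.append(f"row {i}: missing mask file {msk}")
            records.append(
                ManifestRecord(
                    path=img,
                    mask_path=msk,
                    case_id=row["case_id"],
                    domain_id=row["domain"],
                    modality_id=row["modality"],
                    split=row.get("split") or None,
                )
            )
        if errors:
            raise ManifestError(
                f"manifest {path} has {len(errors)} bad rows:\n" + "\n".join(errors)
            )
    return DatasetManifest(tuple(records))


def save_manifest(manifest: DatasetManifest, path) -> None:
    path = Path(path)
    base = path.parent
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(REQUIRED_COLUMNS) + ["split"])
        for r in manifest.records:
            writer.writerow(
                [
                    _relative_or_abs(r.path, base),
                    _relative_or_abs(r.mask_path, base),
                    r.case_id,
                    r.domain_id,
                    r.modality_id,
                    r.split or "",
                ]
            )


def _relative_or_abs(p: Path, base: Path) -> str:
    try:
        return str(Path(p).relative_to(base))
    except ValueError:
        return str(p)


def load_image(record: ManifestRecord, target_size: int | None = None) -> ModalityImage:
    """Load one record: intensities to [0, 1], optional resize.

    The image is resized bilinearly, the mask with nearest neighbour and
    re-binarized, so masks stay strictly {0, 1}.
    """
    import imageio.v3 as iio
    from skimage.transform import resize

    try:
        img = iio.imread(record.path)
    except OSError as exc:
        raise InvalidInputError(f"cannot decode image {record.path}: {exc}") from exc
    try:
        msk = iio.imread(record.mask_path)
    except OSError as exc:
        raise InvalidInputError(f"cannot decode mask {record.mask_path}: {exc}") from exc
    if img.ndim == 3:  # grayscale stored with redundant channels
        img = img[..., 0]
    if msk.ndim == 3:
        msk = msk[..., 0]
    info = np.iinfo(img.dtype) if np.issubdtype(img.dtype, np.integer) else None
    pixels = img.astype(np.float64) / (info.max if info else 1.0)
    mask = (msk.astype(np.float64) > (np.iinfo(msk.dtype).max / 2 if np.issubdtype(msk.dtype, np.integer) else 0.5)).astype(np.float64)
    if target_size is not None and pixels.shape != (target_size, target_size):
        pixels = resize(pixels, (target_size, target_size), order=1, anti_aliasing=False)
        mask = resize(mask, (target_size, target_size), order=0, anti_aliasing=False)
        mask = (mask > 0.5).astype(np.float64)
    return ModalityImage(
        pixels=np.clip(pixels, 0.0, 1.0),
        mask=mask,
        case_id=record.case_id,
        modality_id=record.modality_id,
        domain_id=record.domain_id,
        source_path=str(record.path),
    )


def split_cases(
    manifest: DatasetManifest,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> DatasetManifest:
    """Random case-level train/val split, reproducible under ``seed``."""
    if not (0.0 < train_fraction < 1.0):
        raise InvalidInputError(f"train_fraction must be in (0, 1), got {train_fraction}")
    cases = manifest.case_ids
    if len(cases) < 2:
        raise InvalidInputError("need at least 2 cases to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(cases)))
    n_train = int(round(train_fraction * len(cases)))
    n_train = min(max(n_train, 1), len(cases) - 1)
    train_ids = {cases[i] for i in order[:n_train]}
    new_records = tuple(
        replace(r, split="train" if r.case_id in train_ids else "val")
        for r in manifest.records
    )
    return DatasetManifest(new_records)


class DataStreams:
    """Aligned per-epoch original (T1-task) and mixed (T2-task) streams.

    Images are held in memory (desk scale).  Each epoch reshuffles with
    the stream's own generator; for every original sample of a
    multi-modality case, a mixed counterpart is built with a donor
    modality drawn uniformly from the case's other modalities and a
    freshly sampled ratio.  Cases with a single modality contribute to
    the original stream only.
    """

    def __init__(
        self,
        images: list[ModalityImage],
        rng: np.random.Generator,
        lam: float | None = None,
        lam_range: tuple[float, float] = (0.0, 1.0),
        band_mask: np.ndarray | None = None,
    ):
        if not images:
            raise InvalidInputError("empty image list")
        self.images = list(images)
        self.rng = rng
        self.lam = lam
        self.lam_range = lam_range
        self.band_mask = band_mask
        self._by_case: dict[str, dict[str, ModalityImage]] = {}
        for im in self.images:
            self._by_case.setdefault(im.case_id, {})[im.modality_id] = im
        for cid, mods in self._by_case.items():
            if len(mods) < 2:
                logger.warning(
                    "case %s has a single modality; it feeds the original stream only",
                    cid,
                )

    def _sample_mixed(self, im: ModalityImage) -> spectral_mix.MixedSample | None:
        mods = self._by_case[im.case_id]
        donors = [m for m in mods if m != im.modality_id]
        if not donors:
            return None
        donor_id = donors[int(self.rng.integers(len(donors)))]
        lam = (
            float(self.lam)
            if self.lam is not None
            else spectral_mix.sample_lambda(self.rng, *self.lam_range)
        )
        return spectral_mix.mix_images(
            im, mods[donor_id], lam, band_mask=self.band_mask
        )

    def epoch(self) -> tuple[list[ModalityImage], list[spectral_mix.MixedSample]]:
        """One shuffled epoch: originals plus mixed counterparts."""
        order = self.rng.permutation(len(self.images))
        originals = [self.images[i] for i in order]
        mixed = []
        for im in originals:
            ms = self._sample_mixed(im)
            if ms is not None:
                mixed.append(ms)
        return originals, mixed


def make_streams(
    images: list[ModalityImage],
    rng: np.random.Generator,
    lam: float | None = None,
    lam_range: tuple[float, float] = (0.0, 1.0),
    band_mask: np.ndarray | None = None,
) -> DataStreams:
    """Build the original/mixed stream pair over in-memory images."""
    return DataStreams(images, rng, lam=lam, lam_range=lam_range, band_mask=band_mask)


def load_split_images(
    manifest: DatasetManifest,
    split: str | None,
    target_size: int | None = None,
) -> list[ModalityImage]:
    records = (
        manifest.records
        if split is None
        else tuple(r for r in manifest.records if r.split == split)
    )
    return [load_image(r, target_size) for r in records]
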