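import numpy as np
import pytest

from mfnet import data_io, synthetic_phantom as sp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def cases_to_images(cases):
    """Flatten phantom cases into per-modality ModalityImage objects."""
    return [
        data_io.ModalityImage(
            pixels=img,
            mask=c.mask.astype(np.float64),
            case_id=c.case_id,
            modality_id=mod,
            domain_id=c.domain_id,
        )
        for c in cases
        for mod, img in c.images.items()
    ]


@pytest.fixture(scope="session")
def tiny_cases_a():
    return sp.generate_dataset(4, "A", master_seed=11, size=32)


@pytest.fixture(scope="session")
def tiny_cases_b():
    return sp.generate_dataset(4, "B", master_seed=11, size=32)


@pytest.fixture(scope="session")
def tiny_images_a(tiny_cases_a):
    return cases_to_images(tiny_cases_a)


@pytest.fixture(scope="session")
def disk_dataset(tmp_path_factory, tiny_cases_a, tiny_cases_b):
    """A phantom dataset written to disk with its manifest."""
    out = tmp_path_factory.mktemp("phantom")
    manifest = sp.write_dataset(list(tiny_cases_a) + list(tiny_cases_b), out)
    return manifest
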