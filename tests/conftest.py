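import numpy as np
import pytest

import hepaseg as hs


@pytest.fixture(scope="session")
def tiny_net_cfg() -> hs.NetworkConfig:
    """Two-level network small enough for forward/backward tests."""
    return hs.NetworkConfig(levels=2, base_features=2, max_features=4,
                            dropout=0.0, zconv_levels=(2,), zconvs_per_conv=1)


@pytest.fixture(scope="session")
def tiny_geometry(tiny_net_cfg) -> hs.PatchGeometry:
    return hs.compute_patch_geometry(tiny_net_cfg, (24, 24, 9))


@pytest.fixture(scope="session")
def phantom_case() -> tuple[hs.Volume, hs.MaskVolume, hs.MaskVolume]:
    """One deterministic three-lesion phantom (raw grid, not resampled)."""
    return hs.generate_phantom(hs.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def small_cases() -> list[hs.Case]:
    """A few small preprocessed phantom cases for training-loop tests."""
    cases = []
    for i, n in enumerate([1, 2, 0]):
        spec = hs.PhantomSpec(shape=(48, 48, 16), n_lesions=n,
                              lesion_radius_mm=(4.0, 7.0), seed=100 + i)
        v, liver, lesions = hs.generate_phantom(spec)
        img, lv, (ls,), _ = hs.preprocess_case(v, liver, [lesions])
        cases.append(hs.Case(name=f"case{i}", image=img, liver=lv, lesions=ls))
    return cases
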