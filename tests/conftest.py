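import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom():
    """One small-bodied phantom (image volume + named masks)."""
    import fishrad as fr

    spec = fr.PhantomSpec(seed=7).scaled(0.33)
    img, masks = fr.render_phantom(spec)
    volume = fr.ImageVolume(img.astype(float))
    named = {
        name: fr.NamedMask(m, name, volume.shape) for name, m in masks.items()
    }
    return volume, named


@pytest.fixture(scope="session")
def tiny_cohort_table(tmp_path_factory):
    """Extracted feature table for a 4-specimen phantom cohort."""
    import fishrad as fr
    from fishrad.features import extract_study

    root = tmp_path_factory.mktemp("tiny_cohort")
    cohort = fr.CohortSpec(n_high=2, n_low=2, seed=11,
                           base=fr.PhantomSpec().scaled(0.4))
    manifest = fr.generate_cohort(cohort, root)
    table = extract_study(manifest, fr.PreprocessSpec(mode="none", bin_count=64))
    return manifest, table
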