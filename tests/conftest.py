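import numpy as np
import pandas as pd
import pytest

from drs.deep_features import FeatureBank


def make_gaussian_bank(n_sources_per_class=20, n_features=10, n_informative=2,
                       separation=2.0, copies=1, seed=0,
                       nets=("net1-verydeep", "net2-deep", "net3-moderate")):
    """A feature bank of Gaussian draws with a few informative columns.

    Informative columns (the first ``n_informative``) shift their class means
    by ``separation``; ``copies`` emulates augmented near-duplicates of each
    source (copy noise sd 0.1).
    """
    rng = np.random.default_rng(seed)
    rows = []
    values = []
    for cls, prefix, shift in (("young", "Y", +separation / 2),
                               ("old", "O", -separation / 2)):
        for i in range(n_sources_per_class):
            base = rng.standard_normal(n_features)
            base[:n_informative] += shift
            for c in range(copies):
                values.append(base + 0.1 * rng.standard_normal(n_features))
                rows.append({"source_id": f"{prefix}{i:03d}", "group": cls,
                             "transform_tag": "original" if c == 0 else f"aug{c}",
                             "latent_age": f"{cls}-like"})
    prov = pd.DataFrame({"net": [nets[j % len(nets)] for j in range(n_features)],
                         "layer": 1, "channel": np.arange(n_features)})
    return FeatureBank(values=np.asarray(values), feature_provenance=prov,
                       sample_meta=pd.DataFrame(rows))


@pytest.fixture
def gaussian_bank():
    return make_gaussian_bank(seed=11)


@pytest.fixture(scope="session")
def small_cohort_images():
    """A 6+6+4 synthetic cohort, cropped and resized to 96 px, strong effect."""
    from drs import imaging
    from drs.synthetic_oocytes import (CohortSpec, MorphologyParams,
                                       default_class_params, generate_cohort)

    base = MorphologyParams(oocyte_radius_mean=55.0, zona_thickness=8.0,
                            perivitelline_gap=4.0, texture_corr_length=5.0)
    young, old = default_class_params(2.0, base=base)
    spec = CohortSpec(n_young=6, n_old=6, n_treated=4, effect_size=2.0,
                      image_side=192, seed=42)
    oocytes = generate_cohort(spec, young=young, old=old)
    images = [imaging.resize_to(imaging.crop_to_oocyte(im, 4), 96)
              for im in imaging.from_synthetic(oocytes)]
    return images
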