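import numpy as np
import pytest

from fstriage.synthetic import COHORT_MPP, DEFAULT_PHENOTYPES, generate_slide


@pytest.fixture(scope="session")
def ptc_slide():
    """One malignant-phenotype slide: 1–2 large irregular lesions."""
    return generate_slide(
        DEFAULT_PHENOTYPES["PTC"], (1024, 1024), seed=42, mpp=COHORT_MPP, slide_id="ptc_fix"
    )


@pytest.fixture(scope="session")
def tal_slide():
    """One intermediate-phenotype slide: small round nodules."""
    return generate_slide(
        DEFAULT_PHENOTYPES["TAL"], (1024, 1024), seed=43, mpp=COHORT_MPP, slide_id="tal_fix"
    )


@pytest.fixture(scope="session")
def ng_slide():
    """One common-benign slide: tissue and fibrotic bands, no lesions."""
    return generate_slide(
        DEFAULT_PHENOTYPES["NG"], (1024, 1024), seed=44, mpp=COHORT_MPP, slide_id="ng_fix"
    )


@pytest.fixture(scope="session")
def patch_bank(ptc_slide):
    """Separable training patches (dark lesion vs pink tissue) from PTC slides."""
    from fstriage.synthetic import generate_slide as gen
    from fstriage.tiling import sample_training_patches

    slides = [ptc_slide] + [
        gen(DEFAULT_PHENOTYPES["PTC"], (1024, 1024), seed=s, mpp=COHORT_MPP, slide_id=f"p{s}")
        for s in (45, 46, 47)
    ]
    images, masks = [], []
    for k, s in enumerate(slides):
        for p in sample_training_patches(s, n_total=50, ratio=3, seed=k, patch_size=64):
            images.append(p.image)
            masks.append(p.mask)
    return np.stack(images), np.stack(masks)
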