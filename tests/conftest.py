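import numpy as np
import pytest

import eoquant as eq


@pytest.fixture(scope="session")
def stain_model():
    return eq.default_stain_model()


def grid_section(seed: int, side_px: int = 300, mpp: float = 0.5,
                 area_range=(200.0, 1400.0)) -> eq.SectionSpec:
    """Four disjoint interior blobs on a 2x2 grid, random size/class.

    Blob radii stay below 45 px while grid centres are 150 px apart and
    75 px from the border, so objects never merge or touch the edge.
    """
    rng = np.random.default_rng(seed)
    classes = ("InsOnly", "InsGluc", "GlucOnly")
    fractions = {"InsOnly": (0.92, 0.0), "InsGluc": (0.55, 0.35),
                 "GlucOnly": (0.0, 0.92)}
    q = side_px // 4
    centers = [(q, q), (3 * q, q), (q, 3 * q), (3 * q, 3 * q)]
    eos = []
    for cx, cy in centers:
        cls = classes[rng.integers(0, 3)]
        fi, fg = fractions[cls]
        eos.append(eq.EOSpec(
            center=(float(cx), float(cy)),
            target_area=float(rng.uniform(*area_range)),
            ins_fraction=fi, gluc_fraction=fg,
            shape_irregularity=float(rng.uniform(0.0, 0.5))))
    return eq.SectionSpec(width_px=side_px, height_px=side_px,
                          microns_per_px=mpp, tissue_fraction=1.0,
                          eo_specs=eos, rng_seed=seed)


def detect_from_image(img: np.ndarray, model, mpp: float,
                      compute_morphology: bool = False):
    """Full image path: OD -> pixel assignment -> detect -> filter."""
    od = eq.to_optical_density(img, model.background_intensity)
    masks = eq.assign_pixels(od, model, microns_per_px=mpp)
    cands = eq.detect_eos(masks, compute_morphology=compute_morphology)
    return eq.filter_by_positivity(cands)


@pytest.fixture(scope="session")
def rendered_section(stain_model):
    """One mixed section rendered once for reuse: (spec, image, truth)."""
    spec = grid_section(seed=42)
    img, truth = eq.render_section(spec, stain_model)
    return spec, img, truth
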