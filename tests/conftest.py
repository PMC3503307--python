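import numpy as np
import pandas as pd
import pytest

from lungmorph.segmentation import LabeledAirspaceMap
from lungmorph.synthetic import Ellipse, SceneSpec, render_scene


def circle_label_map(
    diameters_px, pixel_size_um=1.0, margin=6
) -> LabeledAirspaceMap:
    """Rasterized circles laid out on one row, labeled 1..k, no walls drawn.

    Circles are placed away from the image border so every intercept run is
    wall-bounded. Used as a direct oracle input for the descriptor module.
    """
    diameters_px = list(diameters_px)
    radii = [d / 2.0 for d in diameters_px]
    height = int(2 * max(radii)) + 2 * margin + 3
    width = int(sum(2 * r + 2 * margin for r in radii)) + margin
    label_map = np.zeros((height, width), dtype=np.int32)
    rows = []
    col = 0.0
    for k, r in enumerate(radii, start=1):
        col += margin + r
        cr, cc = (height - 1) / 2.0, col
        rr, cc_ = np.mgrid[0:height, 0:width]
        mask = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= r * r
        label_map[mask] = k
        rows.append(
            {
                "label": k,
                "area_px": int(mask.sum()),
                "centroid_row": cr,
                "centroid_col": cc,
            }
        )
        col += r + margin
    return LabeledAirspaceMap(
        label_map=label_map, regions=pd.DataFrame(rows), pixel_size_um=pixel_size_um
    )


@pytest.fixture
def five_airspaces_one_vessel():
    """A deterministic scene: 5 circular airspaces and 1 thick-walled vessel."""
    airspaces = tuple(
        Ellipse(center, (18.0, 18.0), 0.0, 2.0)
        for center in [(60, 60), (60, 160), (160, 60), (160, 160), (110, 250)]
    )
    vessel = Ellipse((250, 250), (25.0, 25.0), 0.0, 12.0)
    spec = SceneSpec(image_size=(320, 320), pixel_size_um=1.0,
                     airspaces=airspaces, vessels=(vessel,), seed=7)
    image, truth = render_scene(spec)
    return spec, image, truth
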