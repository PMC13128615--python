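import json

import numpy as np
import pytest

from internode.io_formats import CalibrationProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def unit_calib():
    """No distortion, k = 0.5 mm/px (matching the synthetic default)."""
    return CalibrationProfile.identity(k=0.5)


@pytest.fixture
def labelme_file(tmp_path):
    """Write a minimal labelme JSON and return its path."""

    def _write(shapes, height=100, width=100, name="ann.json"):
        doc = {
            "version": "5.0.1",
            "imagePath": "img.png",
            "imageHeight": height,
            "imageWidth": width,
            "shapes": [
                {"label": str(label), "points": points, "shape_type": "polygon"}
                for label, points in shapes
            ],
        }
        path = tmp_path / name
        path.write_text(json.dumps(doc))
        return path

    return _write
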