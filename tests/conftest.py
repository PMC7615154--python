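import numpy as np
import pytest

from aceid.design import generate_design
from aceid.simulate import make_standard_fixture


@pytest.fixture(scope="session")
def default_design():
    return generate_design()


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard synthetic image fixture set (4 wells, SNR ~10)."""
    return make_standard_fixture(4, seed=0)


@pytest.fixture(scope="session")
def segmented_fixture(standard_fixture):
    """Fixture wells with nuclei/cell masks, zones and spots computed once."""
    from aceid.segmentation import (
        exclude_border_cells,
        partition_zones,
        segment_cells,
        segment_nuclei,
    )
    from aceid.spots import detect_spots

    out = []
    for images, truth, optics in standard_fixture:
        nuclei_raw = segment_nuclei(images.nuclei)
        cells = exclude_border_cells(
            segment_cells(nuclei_raw, images.marker, max_expansion_px=18.0)
        )
        nuclei = np.where(cells > 0, nuclei_raw, 0)
        zones = partition_zones(cells, nuclei)
        # scale range matched to the fixture's punctum size (sigma 1.5-2.5 px)
        spot_set = detect_spots(
            images.marker,
            cells,
            zones,
            pixel_size_um=images.pixel_size_um,
            sigma_range=(1.0, 3.0),
            n_scales=3,
        )
        out.append(
            {
                "images": images,
                "truth": truth,
                "optics": optics,
                "nuclei_raw": nuclei_raw,
                "nuclei": nuclei,
                "cells": cells,
                "zones": zones,
                "spots": spot_set,
            }
        )
    return out


def iou_matched(truth_mask: np.ndarray, pred_mask: np.ndarray) -> list:
    """Best-overlap IoU per ground-truth object."""
    ious = []
    for tid in range(1, int(truth_mask.max()) + 1):
        tm = truth_mask == tid
        labels = np.unique(pred_mask[tm])
        labels = labels[labels > 0]
        best = 0.0
        for lab in labels:
            pm = pred_mask == lab
            best = max(best, (tm & pm).sum() / (tm | pm).sum())
        ious.append(best)
    return ious
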