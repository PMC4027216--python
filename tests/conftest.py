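import numpy as np
import pytest

from hdrscreen import WellSpec, generate_field
from hdrscreen.features import measure_field
from hdrscreen.segmentation import segment_nuclei


@pytest.fixture(scope="session")
def healthy_field():
    """One default-noise field of healthy cells, all translocated."""
    spec = WellSpec(well_id="A1", n_cells=80, translocation_fraction=1.0,
                    apoptotic_fraction=0.0, dead_fraction=0.0,
                    true_hdr_fraction=0.1)
    image, truth = generate_field(spec, seed=11)
    return image, truth


@pytest.fixture(scope="session")
def measured_healthy_field(healthy_field):
    image, truth = healthy_field
    label_map = segment_nuclei(image.dapi)
    cells = measure_field(image.dapi, image.mcherry, image.gfp,
                          label_map=label_map)
    return image, truth, label_map, cells


def match_truth_to_labels(truth, labels):
    """Ground-truth cell -> segmentation label id (0 = unmatched), by
    reading the label under the true center."""
    out = []
    for t in truth.itertuples():
        out.append(int(labels[int(round(t.center_r)), int(round(t.center_c))]))
    return np.asarray(out)
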