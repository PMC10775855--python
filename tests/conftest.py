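import numpy as np
import pytest

import stereoscreen as ss
from stereoscreen.device import DeviceProfile


@pytest.fixture(scope="session")
def device():
    """Study-tablet geometry with a small dot field for fast rendering."""
    return DeviceProfile(screen_width_px=1920, screen_height_px=1200,
                         pixel_pitch_mm=0.1133, viewing_distance_cm=25.0)


@pytest.fixture(scope="session")
def default_cohort_frame():
    """One merged-session cohort at the default study structure (182 rows)."""
    return ss.generate_cohort(ss.CohortConfig(seed=0)).to_frame()


@pytest.fixture(scope="session")
def default_matrices(default_cohort_frame):
    from stereoscreen.observer import frame_to_matrices
    return frame_to_matrices(default_cohort_frame, positive="joint")


def orientation_cell_masks(spec, device, n_rows, n_cols):
    """Target masks for all four orientations of a stimulus."""
    from stereoscreen.stimgen import ORIENTATIONS, target_cell_mask
    return {o: target_cell_mask(spec.with_orientation(o), device,
                                n_rows, n_cols)
            for o in ORIENTATIONS}


def monocular_orientation_guess(channel_px, masks, cell_px):
    """Template detector on a single channel: highest mean dot activation
    inside an orientation's E mask wins."""
    best_score, best_o = -np.inf, None
    for o, m in masks.items():
        mpx = np.kron(m, np.ones((cell_px, cell_px), dtype=bool))
        mpx = mpx[:channel_px.shape[0], :channel_px.shape[1]]
        score = channel_px[mpx].mean()
        if score > best_score:
            best_score, best_o = score, o
    return best_o
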