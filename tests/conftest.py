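import numpy as np
import pytest

import devcortex as dc


@pytest.fixture(scope="session")
def small_widefield():
    """Short noiseless wide-field fixture with two injected events."""
    spec = dc.WidefieldSynthSpec(
        duration_s=60.0,
        noise_sd_dff=0.0,
        event_times_s={"V1": [10.0, 35.0]},
        seed=7,
    )
    movie, catalog = dc.generate_widefield_movie(spec)
    return spec, movie, catalog


@pytest.fixture(scope="session")
def roi_population():
    """Default ROI population with subtractive shift, one seed."""
    spec = dc.RoiSynthSpec(seed=11)
    traces, gt = dc.generate_roi_population(spec)
    return spec, traces, gt


def flood_fill_components(mask: np.ndarray, connectivity: str) -> list[set]:
    """Exhaustive BFS flood fill on a binarized (T, H, W) stack.

    Independent oracle for connected-component labeling.
    """
    if connectivity == "full":
        offsets = [
            (dt, dy, dx)
            for dt in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dt, dy, dx) != (0, 0, 0)
        ]
    else:
        offsets = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if all(0 <= w[i] < shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps
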