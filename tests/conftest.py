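import numpy as np
import pytest


def brute_force_count(data: np.ndarray, box_size: int, placement: str) -> int:
    """Triple-loop box-count oracle: scan every grid box, test emptiness.

    Independent of the package's counting path; grids anchored at index 0
    (aligned) or at -floor(s/2) per axis (offset), boxes clipped at the
    volume boundary.
    """
    s = int(box_size)
    anchor = 0 if placement == "aligned" else -(s // 2)
    nx, ny, nz = data.shape
    count = 0
    for x0 in range(anchor, nx, s):
        for y0 in range(anchor, ny, s):
            for z0 in range(anchor, nz, s):
                box = data[max(x0, 0) : x0 + s, max(y0, 0) : y0 + s, max(z0, 0) : z0 + s]
                if box.size and box.any():
                    count += 1
    return count


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
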