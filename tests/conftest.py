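import math

import numpy as np
import pytest

from capsheet.phantoms import (
    DiffractionPhantomSpec,
    SheetPhantomSpec,
    generate_diffraction_frame,
    generate_sheet_micrograph,
)

OCP_BAND = (2.85, 0.15, 40.0)  # d center (A), sigma_d (A), amplitude


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One noiseless 3-aggregate micrograph with exact ground truth."""
    spec = SheetPhantomSpec(n_aggregates=3, noise_sigma=0.0, seed=11)
    return generate_sheet_micrograph(spec)


@pytest.fixture(scope="session")
def diffraction_pair():
    """Noiseless (target, background) frames: both carry ice halos, the
    target additionally a band at d = 2.85 A; off-center beams."""
    target, t_truth = generate_diffraction_frame(
        DiffractionPhantomSpec(bands=(OCP_BAND,), center_offset_px=(3.0, -2.0), seed=1)
    )
    background, b_truth = generate_diffraction_frame(
        DiffractionPhantomSpec(center_offset_px=(-1.0, 2.0), seed=2)
    )
    return (target, t_truth), (background, b_truth)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-integer enumeration of the two-sided Fisher p-value.

    Sums, over the conditional (hypergeometric) distribution with the
    observed margins, the probabilities of all tables at most as probable
    as the observed one (with a 1e-7 relative tolerance at the boundary).
    Pure combinatorics via math.comb — independent of scipy.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = math.comb(r1, a) * math.comb(r2, c1 - a)
    numer = sum(w for w in weights if w <= observed + observed * 1e-7)
    return numer / math.comb(n, c1)


def brute_force_area(intensities: np.ndarray, mask: np.ndarray, k: float = 1.5) -> int:
    """Pixel-by-pixel re-application of the adaptive-threshold rule."""
    vals = [intensities[r, c] for r, c in zip(*np.nonzero(mask))]
    vmax, vmin = max(vals), min(vals)
    flipped = [vmax - v for v in vals]
    fmin = min(flipped)
    anchored = [f - fmin for f in flipped]
    mean = sum(anchored) / len(anchored)
    sigma = math.sqrt(sum((x - mean) ** 2 for x in anchored) / len(anchored))
    t = (max(anchored) - min(anchored)) - k * sigma
    return sum(1 for x in anchored if x >= t)
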