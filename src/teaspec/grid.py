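"""The shared wavelength grid and categorical vocabularies.

All spectra in the package live on a fixed 1-nm grid covering the visible /
red-edge window 400-889 nm (490 bands).  Reflectance beyond 890 nm is noisier
under field conditions and is excluded from the analysis.
"""

from __future__ import annotations

import numpy as np

GRID_START = 400
GRID_STOP = 889  # inclusive
GRID_STEP = 1
N_BANDS = GRID_STOP - GRID_START + 1  # 490

SEASONS = ("spring", "summer", "autumn")
STATES = ("fresh", "dried", "powder")
INDICATORS = ("polyphenols", "catechins")


def default_grid() -> np.ndarray:
    """Integer wavelength grid 400..889 nm, 490 points."""
    return np.arange(GRID_START, GRID_STOP + 1, GRID_STEP)


def check_grid(wavelengths: np.ndarray) -> None:
    """Raise ``ValueError`` unless *wavelengths* is a strictly ascending 1-nm grid."""
    wl = np.asarray(wavelengths)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength grid must be a 1-D array with >= 2 points")
    steps = np.diff(wl)
    if not np.all(steps == GRID_STEP):
        raise ValueError("wavelength grid must ascend in 1-nm steps")
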