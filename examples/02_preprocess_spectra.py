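"""Run the standard preprocessing chain and show what each stage does.

Trim to 400-2400 nm (2001 bands), Gaussian-resample to 5 nm (401 bands),
Savitzky-Golay smooth (order 2, window 11), then continuum-remove to
isolate absorption features.
"""

import numpy as np

from somvnir import generate_dataset
from somvnir.preprocess import (
    continuum_remove,
    gaussian_downsample,
    savgol_smooth,
    trim_wavelengths,
)

ds = generate_dataset(seed=1)
print(f"raw:          {ds.spectra.n_bands} bands")

trimmed = trim_wavelengths(ds.spectra, 400.0, 2400.0)
print(f"trimmed:      {trimmed.n_bands} bands (400-2400 nm)")

down = gaussian_downsample(trimmed, step=5.0)
print(f"downsampled:  {down.n_bands} bands (5 nm spacing)")

smooth = savgol_smooth(down)
resid = np.abs(smooth.reflectance - down.reflectance).mean()
print(f"smoothed:     mean |change| from smoothing = {resid:.5f} reflectance units")

cr = continuum_remove(smooth)
i2200 = cr.band_index(2200.0)
print(f"continuum removed: values in ({cr.reflectance.min():.3f}, {cr.reflectance.max():.0f}]")
print(f"mean CR depth at 2200 nm: {1 - cr.reflectance[:, i2200].mean():.3f}")
print()
print("Continuum removal divides each spectrum by its upper convex hull, so")
print("band depth below 1 measures absorption strength independent of albedo.")
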