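"""Core containers shared across the pipeline.

The pipeline moves two things around: a matrix of reflectance spectra on a
common wavelength grid (:class:`SpectraSet`) and the paired soil organic
matter (SOM) measurements (:class:`SoilDataset`).  Both are thin, validated
wrappers over numpy arrays; all heavy computation happens in the functional
modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpectraSet:
    """Reflectance spectra on a shared, strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : ndarray, shape (n_bands,)
        Wavelength grid in nm, strictly increasing.
    reflectance : ndarray, shape (n_samples, n_bands)
        Dimensionless reflectance in (0, 1].
    sample_ids : list of str
        Unique per-sample identifiers, one per row.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"reflectance has {self.reflectance.shape[1]} columns but "
                f"{self.wavelengths.size} wavelengths were given"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(self.reflectance.shape[0])]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.reflectance.shape[0]:
            raise ValueError("number of sample ids must match reflectance rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def band_index(self, wavelength: float) -> int:
        """Index of an exact grid wavelength; raises if off-grid."""
        idx = np.searchsorted(self.wavelengths, wavelength)
        if idx >= self.wavelengths.size or not np.isclose(
            self.wavelengths[idx], wavelength, rtol=0, atol=1e-9
        ):
            raise ValueError(f"wavelength {wavelength} nm is not on the grid")
        return int(idx)

    def subset(self, row_indices) -> "SpectraSet":
        """New SpectraSet restricted to the given sample rows (order kept)."""
        row_indices = np.asarray(row_indices, dtype=int)
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            reflectance=self.reflectance[row_indices].copy(),
            sample_ids=[self.sample_ids[i] for i in row_indices],
        )


@dataclass
class SoilDataset:
    """Paired SOM measurements (g kg^-1) and reflectance spectra."""

    som: np.ndarray
    spectra: SpectraSet

    def __post_init__(self):
        self.som = np.asarray(self.som, dtype=float).ravel()
        if self.som.size != self.spectra.n_samples:
            raise ValueError("SOM vector length must match number of spectra")
        if not np.all(np.isfinite(self.som)):
            raise ValueError("SOM values must be finite")
        if np.any(self.som <= 0):
            raise ValueError("SOM values must be strictly positive")

    @property
    def sample_ids(self) -> list:
        return self.spectra.sample_ids

    @property
    def n_samples(self) -> int:
        return self.som.size

    def subset(self, row_indices) -> "SoilDataset":
        row_indices = np.asarray(row_indices, dtype=int)
        return SoilDataset(som=self.som[row_indices].copy(), spectra=self.spectra.subset(row_indices))
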