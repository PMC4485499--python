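"""Core data containers exchanged between pipeline stages.

A :class:`Spectrum` is a single 1D NMR spectrum on a ppm axis; a
:class:`BinnedDataset` is the central sample x bin intensity matrix with
aligned per-sample factor metadata. Both validate their invariants on
construction so downstream code can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DISEASE_LEVELS = ("control", "GML")
EA_LEVELS = ("none", "SM", "GM")
BIOFLUIDS = ("serum", "urine")


@dataclass(frozen=True)
class SampleMetadata:
    """Factor labels for one sample in the two-way (disease x EA) design."""

    sample_id: str
    disease: str
    ea: str
    biofluid: str = "urine"

    def __post_init__(self) -> None:
        if self.disease not in DISEASE_LEVELS:
            raise ValueError(
                f"unknown disease level {self.disease!r}; expected one of {DISEASE_LEVELS}"
            )
        if self.ea not in EA_LEVELS:
            raise ValueError(f"unknown EA level {self.ea!r}; expected one of {EA_LEVELS}")
        if self.biofluid not in BIOFLUIDS:
            raise ValueError(f"unknown biofluid {self.biofluid!r}; expected one of {BIOFLUIDS}")

    @property
    def group(self) -> str:
        """Combined group label, e.g. ``control-none`` or ``GML-SM``."""
        return f"{self.disease}-{self.ea}"


@dataclass(frozen=True)
class Spectrum:
    """One 1D spectrum: strictly increasing ppm axis and matching intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", intensity)
        if ppm.ndim != 1 or intensity.ndim != 1 or ppm.shape != intensity.shape:
            raise ValueError(f"spectrum {self.sample_id!r}: ppm and intensity shapes differ")
        if ppm.size == 0:
            raise ValueError(f"spectrum {self.sample_id!r}: empty")
        if not np.all(np.diff(ppm) > 0):
            raise ValueError(f"spectrum {self.sample_id!r}: ppm axis not strictly increasing")
        if not (np.all(np.isfinite(ppm)) and np.all(np.isfinite(intensity))):
            raise ValueError(f"spectrum {self.sample_id!r}: non-finite values")

    def shifted(self, delta_ppm: float) -> "Spectrum":
        return replace(self, ppm=self.ppm + delta_ppm)


@dataclass
class BinnedDataset:
    """Sample x bin intensity matrix with bin centers and factor metadata."""

    matrix: np.ndarray
    bin_centers: np.ndarray
    bin_width: float
    metadata: list[SampleMetadata]
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x bins)")
        if self.matrix.shape[0] != len(self.metadata):
            raise ValueError(
                f"{self.matrix.shape[0]} matrix rows but {len(self.metadata)} metadata records"
            )
        if self.matrix.shape[1] != self.bin_centers.size:
            raise ValueError("bin_centers length does not match matrix columns")
        if self.bin_centers.size and not np.all(np.diff(self.bin_centers) > 0):
            raise ValueError("bin centers not strictly increasing")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite values")
        ids = [m.sample_id for m in self.metadata]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in metadata")
        for lo, hi in self.excluded_regions:
            inside = (self.bin_centers >= lo) & (self.bin_centers <= hi)
            if np.any(inside):
                raise ValueError(f"bin centers remain inside excluded region ({lo}, {hi})")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.metadata]

    def labels(self, factor: str) -> np.ndarray:
        """Per-sample level labels for ``disease``, ``ea``, ``group`` or ``biofluid``."""
        if factor not in ("disease", "ea", "biofluid", "group"):
            raise ValueError(f"unknown factor {factor!r}")
        return np.array([getattr(m, factor) for m in self.metadata])

    def subset(self, mask: np.ndarray) -> "BinnedDataset":
        """Row subset by boolean mask; columns and exclusions unchanged."""
        mask = np.asarray(mask, dtype=bool)
        meta = [m for m, keep in zip(self.metadata, mask) if keep]
        return BinnedDataset(
            matrix=self.matrix[mask],
            bin_centers=self.bin_centers.copy(),
            bin_width=self.bin_width,
            metadata=meta,
            excluded_regions=list(self.excluded_regions),
        )

    def with_matrix(self, matrix: np.ndarray) -> "BinnedDataset":
        return BinnedDataset(
            matrix=matrix,
            bin_centers=self.bin_centers.copy(),
            bin_width=self.bin_width,
            metadata=list(self.metadata),
            excluded_regions=list(self.excluded_regions),
        )
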