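"""Spectral preprocessing: referencing, fixed-width binning, region exclusion
and probabilistic quotient normalization (PQN).

The stage order mirrors standard 1H NMR workflow: spectra are referenced to a
known resonance (TSP at 0.0 ppm for urine, the lactate CH3 doublet at 1.33 ppm
for serum), bucketed into fixed-width chemical-shift bins, stripped of solvent
and urea windows, and PQN-normalized to remove per-sample dilution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasets import BinnedDataset, SampleMetadata, Spectrum

log = logging.getLogger(__name__)

#: Default exclusion windows (ppm). Water for serum; water + urea for urine.
DEFAULT_EXCLUSIONS = {
    "serum": [(4.5, 5.2)],
    "urine": [(4.5, 6.0)],
}

#: Default binning ranges per biofluid (ppm).
DEFAULT_PPM_RANGE = {
    "serum": (0.5, 9.0),
    "urine": (0.5, 10.0),
}

#: Integral-normalization target used as step 1 of PQN.
INTEGRAL_TARGET = 100.0


def reference_to_peak(
    spectrum: Spectrum,
    target_ppm: float,
    search_window: tuple[float, float],
) -> tuple[Spectrum, float]:
    """Shift the ppm axis so the tallest point in ``search_window`` sits at
    ``target_ppm``.

    Ties are broken toward the lower-ppm maximum. Returns the referenced
    spectrum and the applied shift (new minus old apex position).
    """
    lo, hi = search_window
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if not np.any(mask):
        raise ValueError(
            f"sample {spectrum.sample_id!r}: search window ({lo}, {hi}) does not "
            "intersect the ppm axis"
        )
    window_ppm = spectrum.ppm[mask]
    window_int = spectrum.intensity[mask]
    apex = window_ppm[int(np.argmax(window_int))]  # argmax -> first = lowest ppm
    shift = float(target_ppm - apex)
    return spectrum.shifted(shift), shift


def bin_spectra(
    spectra: list[Spectrum],
    bin_width: float,
    ppm_range: tuple[float, float],
    metadata: list[SampleMetadata],
) -> BinnedDataset:
    """Bucket spectra into fixed-width bins over ``ppm_range``.

    Bins are half-open ``[lo + k*w, lo + (k+1)*w)`` with the last bin closed
    at ``hi``; the bin value is the *sum* of point intensities falling in the
    bin (bucket integral). ``n_bins = floor((hi - lo) / w)``.
    """
    lo, hi = ppm_range
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not lo < hi:
        raise ValueError("ppm_range must satisfy lo < hi")
    if len(spectra) != len(metadata):
        raise ValueError("spectra and metadata lengths differ")
    n_bins = int(np.floor((hi - lo) / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("ppm_range narrower than one bin")
    edges_hi = lo + n_bins * bin_width
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width

    rows = np.zeros((len(spectra), n_bins))
    for i, (spec, meta) in enumerate(zip(spectra, metadata)):
        # covering = reaching into the first and last bin
        if spec.ppm[0] >= lo + bin_width or spec.ppm[-1] <= edges_hi - bin_width:
            raise ValueError(
                f"sample {meta.sample_id!r}: spectrum range "
                f"({spec.ppm[0]:.4g}, {spec.ppm[-1]:.4g}) does not cover "
                f"({lo}, {edges_hi:.4g})"
            )
        idx = np.floor((spec.ppm - lo) / bin_width).astype(int)
        # last bin closed: a point exactly at the upper edge joins bin n-1
        idx[np.isclose(spec.ppm, edges_hi)] = n_bins - 1
        inside = (idx >= 0) & (idx < n_bins)
        np.add.at(rows[i], idx[inside], spec.intensity[inside])

    return BinnedDataset(
        matrix=rows, bin_centers=centers, bin_width=bin_width, metadata=list(metadata)
    )


def exclude_regions(
    dataset: BinnedDataset, regions: list[tuple[float, float]]
) -> BinnedDataset:
    """Drop bins whose centers fall inside any ``(lo, hi)`` interval
    (endpoints inclusive); column order is otherwise preserved."""
    if not regions:
        return dataset
    drop = np.zeros(dataset.n_bins, dtype=bool)
    for lo, hi in regions:
        if lo > hi:
            raise ValueError(f"region ({lo}, {hi}) has lo > hi")
        drop |= (dataset.bin_centers >= lo) & (dataset.bin_centers <= hi)
    if drop.all():
        raise ValueError("exclusion regions cover every bin")
    keep = ~drop
    log.info("excluded %d of %d bins", int(drop.sum()), dataset.n_bins)
    return BinnedDataset(
        matrix=dataset.matrix[:, keep],
        bin_centers=dataset.bin_centers[keep],
        bin_width=dataset.bin_width,
        metadata=list(dataset.metadata),
        excluded_regions=list(dataset.excluded_regions) + [tuple(r) for r in regions],
    )


@dataclass
class NormalizationResult:
    """PQN output: normalized dataset plus the per-sample quotient divisors."""

    dataset: BinnedDataset
    quotients: np.ndarray
    reference_method: str
    row_totals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.quotients = np.asarray(self.quotients, dtype=float)
        if np.any(self.quotients <= 0):
            raise ValueError("PQN quotients must be positive")

    @property
    def dilution_estimates(self) -> np.ndarray:
        """Per-sample estimated dilution (arbitrary overall scale): the total
        divisor applied to the raw row, i.e. (row total / target) x quotient."""
        if self.row_totals is None:
            raise ValueError("row totals were not recorded")
        return self.row_totals * self.quotients / INTEGRAL_TARGET


def pqn_normalize(
    dataset: BinnedDataset,
    reference: str | int = "median",
    reference_group: str | None = None,
) -> NormalizationResult:
    """Probabilistic quotient normalization.

    Steps: (1) integral-normalize each row to total ``INTEGRAL_TARGET``;
    (2) build the reference spectrum — ``"median"`` = median over all rows,
    ``"group"`` = median over rows whose group label equals
    ``reference_group``, or an integer row index; (3) per-variable quotients
    row/reference over bins where the reference is positive; (4) per-sample
    quotient = median of those quotients; (5) divide each row by its quotient.
    """
    X = dataset.matrix
    if X.shape[0] < 2:
        raise ValueError("PQN needs at least 2 samples")
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        bad = dataset.sample_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has nonpositive total intensity")
    X = X * (INTEGRAL_TARGET / totals[:, None])

    if isinstance(reference, int) and not isinstance(reference, bool):
        ref = X[reference]
        method = f"index:{reference}"
    elif reference == "median":
        ref = np.median(X, axis=0)
        method = "median_all"
    elif reference == "group":
        if reference_group is None:
            raise ValueError("reference='group' requires reference_group")
        groups = dataset.labels("group")
        mask = groups == reference_group
        if not mask.any():
            raise ValueError(f"no samples in reference group {reference_group!r}")
        ref = np.median(X[mask], axis=0)
        method = f"median_group:{reference_group}"
    else:
        raise ValueError(f"unknown PQN reference {reference!r}")

    if not np.any(ref > 0):
        raise ValueError("PQN reference spectrum is identically zero")

    pos = ref > 0
    quotients = np.median(X[:, pos] / ref[pos], axis=1)
    if np.any(quotients <= 0):
        bad = dataset.sample_ids[int(np.argmax(quotients <= 0))]
        raise ValueError(f"sample {bad!r}: nonpositive PQN quotient")
    X = X / quotients[:, None]
    return NormalizationResult(
        dataset=dataset.with_matrix(X),
        quotients=quotients,
        reference_method=method,
        row_totals=totals,
    )
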