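"""Two-way ANOVA decomposition of a binned spectral matrix.

Splits the sample x bin matrix X into a grand-mean row plus cell-constant
effect submatrices for factor A (disease), factor B (electroacupuncture),
their interaction, and a residual, following the general linear model

    X = 1 mu' + X_A + X_B + X_AB + E        (exact, by construction)

with an unweighted cell-means parameterization so unbalanced cells (7 vs 8
animals) are treated symmetrically. Variance accounting reports each
component's sum of squares as a percentage of the four-component total, and
effect-filtered matrices (e.g. disease effect + residual) isolate one factor
for downstream multivariate modelling, in the ANOVA-PCA / ASCA tradition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import BinnedDataset

log = logging.getLogger(__name__)

COMPONENTS = ("A", "B", "AB", "residual")


@dataclass
class AnovaDecomposition:
    """Grand mean plus effect/residual submatrices of identical n x p shape."""

    grand_mean: np.ndarray  # (p,)
    effect_A: np.ndarray  # (n, p) cell-constant within each A level
    effect_B: np.ndarray
    effect_AB: np.ndarray
    residual: np.ndarray
    labels_A: np.ndarray
    labels_B: np.ndarray
    factor_A_name: str = "disease"
    factor_B_name: str = "ea"

    def __post_init__(self) -> None:
        n, p = self.effect_A.shape
        for name in ("effect_B", "effect_AB", "residual"):
            if getattr(self, name).shape != (n, p):
                raise ValueError(f"{name} shape differs from effect_A")
        if self.grand_mean.shape != (p,):
            raise ValueError("grand_mean must be a length-p row")
        if len(self.labels_A) != n or len(self.labels_B) != n:
            raise ValueError("label vectors must have one entry per sample")

    def reconstruct(self) -> np.ndarray:
        """grand mean + A + B + AB + residual (exactly the input matrix)."""
        return self.grand_mean[None, :] + self.effect_A + self.effect_B + self.effect_AB + self.residual

    def sums_of_squares(self) -> dict[str, float]:
        return {
            "A": float(np.sum(self.effect_A**2)),
            "B": float(np.sum(self.effect_B**2)),
            "AB": float(np.sum(self.effect_AB**2)),
            "residual": float(np.sum(self.residual**2)),
        }


def decompose_two_way(
    dataset: BinnedDataset,
    factor_A_name: str = "disease",
    factor_B_name: str = "ea",
) -> AnovaDecomposition:
    """Decompose the dataset matrix by the two named metadata factors.

    See :func:`decompose_arrays` for the parameterization.
    """
    return decompose_arrays(
        dataset.matrix,
        dataset.labels(factor_A_name),
        dataset.labels(factor_B_name),
        factor_A_name,
        factor_B_name,
    )


def decompose_arrays(
    X: np.ndarray,
    labels_A: np.ndarray,
    labels_B: np.ndarray,
    factor_A_name: str = "disease",
    factor_B_name: str = "ea",
) -> AnovaDecomposition:
    """Two-way decomposition from a raw matrix and two label vectors.

    Unweighted cell-means parameterization: the grand mean is the mean of
    cell means; the A effect at level a is the unweighted mean of cell means
    over B at that level minus the grand mean (B symmetric); the interaction
    is the cell mean minus the additive fit; the residual is the within-cell
    remainder. Requires every A x B cell to be nonempty.
    """
    X = np.asarray(X, dtype=float)
    a = np.asarray(labels_A)
    b = np.asarray(labels_B)
    if len(a) != X.shape[0] or len(b) != X.shape[0]:
        raise ValueError("label vectors must have one entry per sample")
    levels_a = sorted(set(a.tolist()))
    levels_b = sorted(set(b.tolist()))
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels present")

    missing = [
        (la, lb)
        for la in levels_a
        for lb in levels_b
        if not np.any((a == la) & (b == lb))
    ]
    if missing:
        raise ValueError(f"empty design cells: {missing}")

    cell_means = {
        (la, lb): X[(a == la) & (b == lb)].mean(axis=0)
        for la in levels_a
        for lb in levels_b
    }
    grand = np.mean([cell_means[c] for c in cell_means], axis=0)
    alpha = {
        la: np.mean([cell_means[(la, lb)] for lb in levels_b], axis=0) - grand
        for la in levels_a
    }
    beta = {
        lb: np.mean([cell_means[(la, lb)] for la in levels_a], axis=0) - grand
        for lb in levels_b
    }
    gamma = {
        (la, lb): cell_means[(la, lb)] - grand - alpha[la] - beta[lb]
        for la in levels_a
        for lb in levels_b
    }

    n = X.shape[0]
    effect_A = np.vstack([alpha[a[i]] for i in range(n)])
    effect_B = np.vstack([beta[b[i]] for i in range(n)])
    effect_AB = np.vstack([gamma[(a[i], b[i])] for i in range(n)])
    fitted = grand[None, :] + effect_A + effect_B + effect_AB
    residual = X - fitted

    return AnovaDecomposition(
        grand_mean=grand,
        effect_A=effect_A,
        effect_B=effect_B,
        effect_AB=effect_AB,
        residual=residual,
        labels_A=a,
        labels_B=b,
        factor_A_name=factor_A_name,
        factor_B_name=factor_B_name,
    )


def variance_table(decomposition: AnovaDecomposition) -> pd.DataFrame:
    """Percentage of data variation attributed to each component.

    SS(component) is the sum of squared entries of that submatrix; the
    denominator is the sum over the four components, so the total is exactly
    100.0 even for unbalanced designs. The grand mean carries level, not
    variation, and is excluded. Rows are ordered A, B, interaction, residual,
    total.
    """
    ss = decomposition.sums_of_squares()
    total = sum(ss.values())
    if total == 0:
        log.warning("constant matrix: all sums of squares are zero; "
                    "reporting residual = 100%%")
        pct = {"A": 0.0, "B": 0.0, "AB": 0.0, "residual": 100.0}
    else:
        pct = {k: 100.0 * v / total for k, v in ss.items()}
    a, b = decomposition.factor_A_name, decomposition.factor_B_name
    rows = [
        (a, pct["A"]),
        (b, pct["B"]),
        (f"{a}-{b} interaction", pct["AB"]),
        ("residual", pct["residual"]),
        ("total", sum(pct.values())),
    ]
    return pd.DataFrame(rows, columns=["component", "percentage"])


def effect_filtered_matrix(
    decomposition: AnovaDecomposition,
    keep: set[str],
    include_residual: bool = True,
    add_grand_mean: bool = True,
) -> np.ndarray:
    """Sum of the selected effect submatrices (plus residual / grand mean).

    ``keep`` is a subset of {"A", "B", "AB"}. With all three kept plus
    residual and grand mean, the original matrix is restored exactly. The
    typical use keeps one factor plus the residual, discarding the others, to
    build a factor-isolated dataset for OPLS-DA.
    """
    bad = keep - {"A", "B", "AB"}
    if bad:
        raise ValueError(f"unknown components {sorted(bad)}; expected subset of A, B, AB")
    if not keep and not include_residual:
        raise ValueError("nothing selected: keep is empty and residual excluded")
    out = np.zeros_like(decomposition.residual)
    if add_grand_mean:
        out = out + decomposition.grand_mean[None, :]
    if "A" in keep:
        out = out + decomposition.effect_A
    if "B" in keep:
        out = out + decomposition.effect_B
    if "AB" in keep:
        out = out + decomposition.effect_AB
    if include_residual:
        out = out + decomposition.residual
    return out
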