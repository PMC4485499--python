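"""End-to-end orchestration of the factorial NMR metabolomics analysis.

Runs, per biofluid: preprocessing (exclusion windows, PQN), two-way ANOVA
decomposition with variance accounting, an exploratory all-group PLS-DA, an
effect-filtered OPLS-DA for the disease contrast (control vs GML on the
disease + residual matrix), pairwise effect-filtered OPLS-DA models among the
GML treatment arms (none / SM / GM on the EA + residual matrix), each
validated by stratified eightfold cross-validation and label permutation, and
per-bin univariate t-tests for the four classical groups. Also owns the
on-disk formats: matrix/metadata CSV, TOML config, JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import BinnedDataset, SampleMetadata
from .decompose import (
    decompose_arrays,
    decompose_two_way,
    effect_filtered_matrix,
    variance_table,
)
from .multivariate import correlation_loadings, cross_validated_q2, fit_oplsda, fit_plsda
from .preprocess import DEFAULT_EXCLUSIONS, DEFAULT_PPM_RANGE, exclude_regions, pqn_normalize
from .synth import PAPER_GROUP_SIZES, default_effect_spec, generate_design, simulate_dataset
from .univariate import group_summary, unpaired_ttest

log = logging.getLogger(__name__)

#: The four groups of the classical univariate comparison.
UNIVARIATE_GROUPS = ("control-none", "GML-none", "GML-SM", "GML-GM")
UNIVARIATE_CONTRASTS = (
    ("GML-none", "control-none"),
    ("GML-SM", "GML-none"),
    ("GML-GM", "GML-none"),
)
EA_PAIRS = (("none", "SM"), ("none", "GM"), ("SM", "GM"))


@dataclass
class PipelineConfig:
    """Everything needed to re-run an analysis bit-identically."""

    # exactly one input source: simulate, or load matrix+metadata CSVs
    simulate: bool = True
    matrix_path: str | None = None
    metadata_path: str | None = None
    biofluid: str = "urine"
    bin_width: float = 0.002
    ppm_range: tuple[float, float] | None = None  # default per biofluid
    exclusion_regions: list[tuple[float, float]] | None = None  # default per biofluid
    pqn_reference: str = "median"  # "median" | "group" | "index:<i>"
    pqn_reference_group: str | None = None
    noise_regions: list[tuple[float, float]] = field(default_factory=list)
    n_components: int = 2
    n_orthogonal: int = 1
    scaling: str = "center"
    n_folds: int = 8
    n_permutations: int = 999
    alpha: float = 0.05
    ttest_variant: str = "student"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        has_paths = self.matrix_path is not None or self.metadata_path is not None
        if self.simulate and has_paths:
            raise ValueError("config must use either simulation or input paths, not both")
        if not self.simulate and (self.matrix_path is None or self.metadata_path is None):
            raise ValueError("non-simulation config needs both matrix_path and metadata_path")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["ppm_range"] = list(self.ppm_range) if self.ppm_range else None
        d["exclusion_regions"] = (
            [list(r) for r in self.exclusion_regions] if self.exclusion_regions else None
        )
        d["noise_regions"] = [list(r) for r in self.noise_regions]
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Read a TOML config file into a :class:`PipelineConfig`."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    for key in ("ppm_range", "exclusion_regions", "noise_regions"):
        if key in raw and raw[key] is not None:
            if key == "ppm_range":
                raw[key] = tuple(raw[key])
            else:
                raw[key] = [tuple(r) for r in raw[key]]
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------
# dataset serialization

def write_dataset(dataset: BinnedDataset, matrix_path: str | Path, metadata_path: str | Path) -> None:
    """Matrix CSV (row 1: ``sample_id,<bin center to 4 decimals>,...``) and
    metadata CSV (``sample_id,disease,ea,biofluid``)."""
    mat = pd.DataFrame(
        dataset.matrix,
        index=pd.Index(dataset.sample_ids, name="sample_id"),
        columns=[f"{c:.4f}" for c in dataset.bin_centers],
    )
    mat.to_csv(matrix_path)
    meta = pd.DataFrame(
        [
            {"sample_id": m.sample_id, "disease": m.disease, "ea": m.ea, "biofluid": m.biofluid}
            for m in dataset.metadata
        ]
    )
    meta.to_csv(metadata_path, index=False)


def load_dataset(
    matrix_path: str | Path,
    metadata_path: str | Path,
    bin_width: float | None = None,
) -> BinnedDataset:
    """Load matrix + metadata CSVs written by :func:`write_dataset`.

    Bin centers are parsed from the matrix header; sample ids must match the
    metadata 1:1. ``bin_width`` defaults to the median center spacing.
    """
    mat = pd.read_csv(matrix_path, index_col="sample_id")
    try:
        centers = np.array([float(c) for c in mat.columns])
    except ValueError as exc:
        raise ValueError(f"non-numeric bin-center header in {matrix_path}: {exc}") from exc
    if not np.all(np.diff(centers) > 0):
        raise ValueError("bin centers in matrix header are not strictly increasing")
    if mat.isna().any().any():
        r, c = np.argwhere(mat.isna().to_numpy())[0]
        raise ValueError(f"missing/non-numeric value at sample {mat.index[r]!r}, bin {mat.columns[c]}")

    meta_df = pd.read_csv(metadata_path)
    meta_ids = set(meta_df["sample_id"])
    mat_ids = set(mat.index)
    if meta_ids != mat_ids:
        missing = sorted(mat_ids - meta_ids)
        extra = sorted(meta_ids - mat_ids)
        raise ValueError(
            f"sample id mismatch: in matrix only {missing}; in metadata only {extra}"
        )
    meta_df = meta_df.set_index("sample_id").loc[mat.index].reset_index()
    metadata = [
        SampleMetadata(
            sample_id=row.sample_id,
            disease=row.disease,
            ea=row.ea,
            biofluid=getattr(row, "biofluid", "urine"),
        )
        for row in meta_df.itertuples(index=False)
    ]
    if bin_width is None:
        bin_width = float(np.median(np.diff(centers))) if centers.size > 1 else 1.0
    return BinnedDataset(
        matrix=mat.to_numpy(dtype=float),
        bin_centers=centers,
        bin_width=bin_width,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# report bundle

@dataclass
class ComparisonResult:
    """One two-group OPLS-DA comparison with validation and loadings."""

    name: str
    groups: tuple[str, str]
    r2x: float
    r2y: float
    q2: float
    p_r2y: float
    p_q2: float
    n_orthogonal: int
    loadings: pd.DataFrame
    scores: pd.DataFrame

    def summary(self) -> dict:
        return {
            "groups": list(self.groups),
            "r2x": self.r2x,
            "r2y": self.r2y,
            "q2": self.q2,
            "p_r2y": self.p_r2y,
            "p_q2": self.p_q2,
            "n_orthogonal": self.n_orthogonal,
        }


@dataclass
class ReportBundle:
    """All pipeline outputs for one run, JSON-serializable minus the tables."""

    variance_tables: dict[str, pd.DataFrame]
    exploratory: dict[str, dict]
    comparisons: dict[str, ComparisonResult]
    univariate: dict[str, pd.DataFrame]
    group_summaries: dict[str, pd.DataFrame]
    quotients: dict[str, np.ndarray]
    provenance: dict

    def to_jsonable(self, include_timestamp: bool = True) -> dict:
        prov = dict(self.provenance)
        if not include_timestamp:
            prov.pop("timestamp", None)
        return {
            "variance_tables": {
                k: v.to_dict(orient="records") for k, v in self.variance_tables.items()
            },
            "exploratory": self.exploratory,
            "comparisons": {k: v.summary() for k, v in self.comparisons.items()},
            "univariate_comparisons": sorted(self.univariate),
            "pqn_quotients": {k: v.tolist() for k, v in self.quotients.items()},
            "provenance": prov,
        }


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _permute_within_strata(
    rng: np.random.Generator, labels: np.ndarray, strata: np.ndarray
) -> np.ndarray:
    """Permute labels independently within each stratum (restricted
    permutation for a crossed design; preserves every cell count)."""
    out = labels.copy()
    for s in sorted(set(strata.tolist())):
        idx = np.nonzero(strata == s)[0]
        out[idx] = labels[idx[rng.permutation(len(idx))]]
    return out


def filtered_comparison(
    X: np.ndarray,
    disease: np.ndarray,
    ea: np.ndarray,
    factor: str,
    pair: tuple[str, str] | None = None,
    n_permutations: int = 999,
    n_components: int = 2,
    n_folds: int = 8,
    scaling: str = "center",
    seed: int = 0,
) -> tuple[float, float, float, float]:
    """Validate one effect-filtered two-group model honestly.

    The model is fit on the kept-effect + residual matrix; because that
    matrix is estimated *from* the tested labels, the permutation null must
    re-run the decomposition and filtering with the permuted labels — a
    post-filtering label shuffle would be badly anti-conservative. Labels of
    the tested factor are permuted within strata of the other factor, which
    preserves all cell counts. For ``factor="ea"``, ``pair`` names the two
    treatment levels compared among GML samples.

    Returns (r2y, q2, p_r2y, p_q2).
    """
    rng = np.random.default_rng(seed)

    def evaluate(d_lab: np.ndarray, e_lab: np.ndarray, cv_seed: int) -> tuple[float, float]:
        decomp = decompose_arrays(X, d_lab, e_lab)
        keep = "A" if factor == "disease" else "B"
        Xf = effect_filtered_matrix(decomp, keep={keep}, include_residual=True)
        if factor == "disease":
            mask = np.ones(len(d_lab), dtype=bool)
            labels = d_lab
        else:
            mask = (d_lab == "GML") & np.isin(e_lab, pair)
            labels = e_lab
        rep = cross_validated_q2(
            Xf[mask], labels[mask], n_components=n_components,
            n_folds=n_folds, scaling=scaling, seed=cv_seed,
        )
        return rep.r2y, rep.q2

    r2y, q2 = evaluate(disease, ea, seed)
    perm_r2y = np.empty(n_permutations)
    perm_q2 = np.empty(n_permutations)
    for i in range(n_permutations):
        cv_seed = int(rng.integers(0, 2**31 - 1))
        if factor == "disease":
            d_perm = _permute_within_strata(rng, disease, ea)
            perm_r2y[i], perm_q2[i] = evaluate(d_perm, ea, cv_seed)
        else:
            e_perm = _permute_within_strata(rng, ea, disease)
            perm_r2y[i], perm_q2[i] = evaluate(disease, e_perm, cv_seed)
    p_r2y = float((1 + np.sum(perm_r2y >= r2y)) / (1 + n_permutations))
    p_q2 = float((1 + np.sum(perm_q2 >= q2)) / (1 + n_permutations))
    return r2y, q2, p_r2y, p_q2


def _comparison(
    name: str,
    X_filtered: np.ndarray,
    mask: np.ndarray,
    labels: np.ndarray,
    validation: tuple[float, float, float, float],
    sample_ids: list[str],
    bin_centers: np.ndarray,
    config: PipelineConfig,
) -> ComparisonResult:
    X, labels = X_filtered[mask], labels[mask]
    ids = [s for s, m in zip(sample_ids, mask) if m]
    opls = fit_oplsda(X, labels, n_orthogonal=config.n_orthogonal, scaling=config.scaling)
    _r2y_pls, q2, p_r2y, p_q2 = validation
    loadings = correlation_loadings(X, labels, config.noise_regions or None, bin_centers)
    loadings.insert(1, "loading_pred", opls.p_pred)
    scores = pd.DataFrame(
        {
            "sample_id": ids,
            "label": labels,
            "t_pred": opls.t_pred,
            **{f"t_ortho{j + 1}": opls.T_ortho[:, j] for j in range(opls.n_orthogonal)},
        }
    )
    return ComparisonResult(
        name=name,
        groups=(str(sorted(set(labels))[0]), str(sorted(set(labels))[1])),
        r2x=opls.r2x,
        r2y=opls.r2y,
        q2=q2,
        p_r2y=p_r2y,
        p_q2=p_q2,
        n_orthogonal=opls.n_orthogonal,
        loadings=loadings,
        scores=scores,
    )


def _analyze_biofluid(
    dataset: BinnedDataset, config: PipelineConfig, rng: np.random.Generator, bundle_out: dict
) -> None:
    fluid = dataset.metadata[0].biofluid
    regions = (
        config.exclusion_regions
        if config.exclusion_regions is not None
        else DEFAULT_EXCLUSIONS[fluid]
    )
    dataset = exclude_regions(dataset, regions)
    ref = config.pqn_reference
    if ref.startswith("index:"):
        norm = pqn_normalize(dataset, int(ref.split(":", 1)[1]))
    else:
        norm = pqn_normalize(dataset, ref, config.pqn_reference_group)
    dataset = norm.dataset
    bundle_out["quotients"][fluid] = norm.quotients

    decomp = decompose_two_way(dataset, "disease", "ea")
    bundle_out["variance_tables"][fluid] = variance_table(decomp)

    # exploratory all-group PLS-DA (no validation gate; logged for inspection)
    groups = dataset.labels("group")
    k = min(3, dataset.n_samples - 1, dataset.n_bins)
    exploratory = fit_plsda(dataset.matrix, groups, n_components=k, scaling=config.scaling)
    bundle_out["exploratory"][fluid] = {
        "n_components": k,
        "r2x": exploratory.r2x,
        "r2y": exploratory.r2y,
    }
    log.info("%s exploratory PLS-DA: R2X=%.3f R2Y=%.3f", fluid, exploratory.r2x, exploratory.r2y)

    disease_labels = dataset.labels("disease")
    ea_labels = dataset.labels("ea")
    model_kw = dict(
        n_permutations=config.n_permutations,
        n_components=config.n_components,
        n_folds=config.n_folds,
        scaling=config.scaling,
    )

    # disease contrast on the disease-filtered matrix
    X_disease = effect_filtered_matrix(decomp, keep={"A"}, include_residual=True)
    validation = filtered_comparison(
        dataset.matrix, disease_labels, ea_labels, "disease",
        seed=_sub_seed(rng), **model_kw,
    )
    bundle_out["comparisons"][f"{fluid}:disease:GML-vs-control"] = _comparison(
        f"{fluid}:disease:GML-vs-control",
        X_disease,
        np.ones(dataset.n_samples, dtype=bool),
        disease_labels,
        validation,
        dataset.sample_ids,
        dataset.bin_centers,
        config,
    )

    # pairwise EA contrasts among GML animals on the EA-filtered matrix
    X_ea = effect_filtered_matrix(decomp, keep={"B"}, include_residual=True)
    gml = disease_labels == "GML"
    for a, b in EA_PAIRS:
        mask = gml & np.isin(ea_labels, [a, b])
        if len(set(ea_labels[mask])) < 2:
            log.warning("skipping EA pair %s vs %s: a group is missing", a, b)
            continue
        name = f"{fluid}:ea:{a}-vs-{b}"
        validation = filtered_comparison(
            dataset.matrix, disease_labels, ea_labels, "ea", pair=(a, b),
            seed=_sub_seed(rng), **model_kw,
        )
        bundle_out["comparisons"][name] = _comparison(
            name, X_ea, mask, ea_labels, validation,
            dataset.sample_ids, dataset.bin_centers, config,
        )

    # classical four-group univariate tables on the normalized data
    present = set(dataset.labels("group").tolist())
    groups_present = [g for g in UNIVARIATE_GROUPS if g in present]
    if groups_present:
        bundle_out["group_summaries"][fluid] = group_summary(dataset, groups_present)
    for a, b in UNIVARIATE_CONTRASTS:
        if a in present and b in present:
            res = unpaired_ttest(
                dataset, a, b, alpha=config.alpha, variant=config.ttest_variant
            )
            bundle_out["univariate"][f"{fluid}:{res.comparison}"] = res.table


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``; fully deterministic
    given ``config.seed``. Writes the report bundle to ``config.out_dir`` if
    set, and returns it."""
    rng = np.random.default_rng(config.seed)
    if config.simulate:
        ppm_range = config.ppm_range or DEFAULT_PPM_RANGE[config.biofluid]
        design = generate_design(PAPER_GROUP_SIZES, biofluid=config.biofluid, seed=config.seed)
        dataset, _truth = simulate_dataset(
            design,
            effect_spec=default_effect_spec(),
            ppm_range=ppm_range,
            bin_width=config.bin_width,
            seed=_sub_seed(rng),
        )
        log.info("simulated %d samples x %d bins", dataset.n_samples, dataset.n_bins)
    else:
        dataset = load_dataset(config.matrix_path, config.metadata_path, config.bin_width)
        log.info("loaded %d samples x %d bins", dataset.n_samples, dataset.n_bins)

    out: dict = {
        "variance_tables": {},
        "exploratory": {},
        "comparisons": {},
        "univariate": {},
        "group_summaries": {},
        "quotients": {},
    }
    fluids = dataset.labels("biofluid")
    for fluid in sorted(set(fluids.tolist())):
        _analyze_biofluid(dataset.subset(fluids == fluid), config, rng, out)

    bundle = ReportBundle(
        variance_tables=out["variance_tables"],
        exploratory=out["exploratory"],
        comparisons=out["comparisons"],
        univariate=out["univariate"],
        group_summaries=out["group_summaries"],
        quotients=out["quotients"],
        provenance={
            "config": config.to_jsonable(),
            "seed": config.seed,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write report.json plus per-table CSVs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(bundle.to_jsonable(), fh, indent=2)
    for fluid, table in bundle.variance_tables.items():
        table.to_csv(out / f"variance_table_{fluid}.csv", index=False)
    for name, comp in bundle.comparisons.items():
        stem = name.replace(":", "_").replace(" ", "")
        comp.loadings.to_csv(out / f"loadings_{stem}.csv", index=False)
        comp.scores.to_csv(out / f"scores_{stem}.csv", index=False)
    for name, table in bundle.univariate.items():
        stem = name.replace(":", "_").replace(" ", "_")
        table.to_csv(out / f"univariate_{stem}.csv", index=False)
    for fluid, table in bundle.group_summaries.items():
        table.to_csv(out / f"group_summary_{fluid}.csv", index=False)
    log.info("report bundle written to %s", out)
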