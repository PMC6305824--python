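"""Synthetic two-condition expression studies with known network ground truth.

The generator plants a sparse Gaussian graphical model per condition: a
precision matrix with unit diagonal, hub--spoke entries for designated hub
genes and a handful of background edges, with off-diagonal magnitudes chosen
on the *partial-correlation* scale so planted effect sizes are directly
interpretable.  Expression values are multivariate-normal draws from the
inverse precision, shifted per gene for the planted differentially expressed
genes.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

__all__ = [
    "PrecisionModel",
    "SyntheticTruth",
    "ExpressionStudy",
    "SimulationParams",
    "make_precision_model",
    "partial_corr_from_precision",
    "simulate_condition",
    "make_two_condition_study",
    "make_multi_dataset",
    "write_study",
    "write_truth",
]

#: minimum eigenvalue enforced on every generated precision matrix
EIGENVALUE_FLOOR = 0.05

NORMAL = "normal"
CANCER = "cancer"


def _pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered gene pair (sorted)."""
    return (a, b) if a <= b else (b, a)


def default_gene_ids(n_genes: int) -> tuple[str, ...]:
    width = max(3, len(str(n_genes)))
    return tuple(f"g{i:0{width}d}" for i in range(1, n_genes + 1))


@dataclass(frozen=True)
class PrecisionModel:
    """A planted sparse precision matrix with recorded edge support and hubs."""

    gene_ids: tuple[str, ...]
    precision: np.ndarray
    support: frozenset[tuple[str, str]]
    hub_genes: frozenset[str]
    hub_degree: int = 0

    def __post_init__(self) -> None:
        p = self.precision
        if p.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ParameterError("precision shape does not match gene_ids")
        if not np.allclose(p, p.T):
            raise ParameterError("precision matrix must be symmetric")
        if np.linalg.eigvalsh(p).min() <= 0:
            raise ParameterError("precision matrix must be positive definite")

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def partial_correlations(self) -> np.ndarray:
        return partial_corr_from_precision(self.precision)

    def degree_of(self, gene: str) -> int:
        return sum(1 for pair in self.support if gene in pair)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one two-condition simulated study."""

    normal_model: PrecisionModel
    cancer_model: PrecisionModel
    de_genes: dict[str, float]
    cancer_specific_hubs: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        expected = self.cancer_model.hub_genes - self.normal_model.hub_genes
        object.__setattr__(self, "cancer_specific_hubs", frozenset(expected))
        for gene, shift in self.de_genes.items():
            if abs(shift) < 1.0:
                raise ParameterError(
                    f"planted shift for {gene} is {shift}; |shift| must be >= 1 "
                    "log2 unit so the effect clears a fold-change-2 threshold"
                )


@dataclass(frozen=True)
class ExpressionStudy:
    """Gene-by-sample log2 expression matrix with per-sample condition labels."""

    values: pd.DataFrame  # genes x samples, log2 scale
    condition: pd.Series  # sample -> condition label
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.condition.index):
            raise DataError("condition labels must cover exactly the sample columns")
        if self.values.isna().any().any():
            raise DataError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.condition))

    def samples_in(self, label: str) -> list[str]:
        return [s for s, c in self.condition.items() if c == label]

    def slice_condition(self, label: str) -> pd.DataFrame:
        """Genes x samples sub-matrix for one condition."""
        cols = self.samples_in(label)
        if not cols:
            raise DataError(f"no samples labelled {label!r}")
        return self.values[cols]


def partial_corr_from_precision(precision: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a precision matrix.

    rho_ij = -omega_ij / sqrt(omega_ii * omega_jj), diagonal set to 1.
    """
    d = np.sqrt(np.diag(precision))
    rho = -precision / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def make_precision_model(
    n_genes: int,
    n_hubs: int = 0,
    hub_degree: int = 0,
    background_edges: int = 0,
    partial_corr_magnitude: float = 0.3,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
    hub_ids: Sequence[str] | None = None,
    exclude_ids: Sequence[str] | None = None,
) -> PrecisionModel:
    """Build a sparse positive-definite precision matrix with planted hubs.

    The matrix starts as the identity; each hub gets ``hub_degree`` spoke
    entries to distinct non-hub partners and ``background_edges`` extra random
    pairs are added, with off-diagonals set so the implied partial correlation
    is ``+/- partial_corr_magnitude`` (random signs).  Genes named in
    ``exclude_ids`` receive no edges at all (they stay exact isolates, which
    keeps "hub in the other condition only" an unambiguous ground-truth
    label when two models share one gene universe).  If the minimum
    eigenvalue falls below :data:`EIGENVALUE_FLOOR` the diagonal is inflated;
    support is recorded before inflation, which rescales but never zeroes the
    planted partial correlations.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if not 0 < partial_corr_magnitude <= 0.5:
        raise ParameterError("partial_corr_magnitude must lie in (0, 0.5]")
    max_pairs = n_genes * (n_genes - 1) // 2
    if n_hubs * hub_degree + 2 * background_edges > max_pairs:
        raise ParameterError(
            f"edge budget infeasible: {n_hubs} hubs x degree {hub_degree} "
            f"+ 2 x {background_edges} background exceeds {max_pairs} pairs"
        )
    if n_hubs > 0 and hub_degree > n_genes - n_hubs:
        raise ParameterError(
            "hub_degree exceeds the number of available non-hub partners"
        )

    genes = tuple(gene_ids) if gene_ids is not None else default_gene_ids(n_genes)
    if len(genes) != n_genes:
        raise ParameterError("gene_ids length must equal n_genes")
    index = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    if hub_ids is not None:
        hubs = list(hub_ids)
        if len(hubs) != n_hubs or any(g not in index for g in hubs):
            raise ParameterError("hub_ids must name n_hubs genes from gene_ids")
    else:
        hubs = [genes[i] for i in sorted(rng.choice(n_genes, size=n_hubs, replace=False))]

    excluded = set(exclude_ids or ())
    if unknown := excluded - set(genes):
        raise ParameterError(f"exclude_ids not in gene_ids: {sorted(unknown)}")
    if excluded & set(hubs):
        raise ParameterError("a gene cannot be both hub and excluded")

    non_hubs = [g for g in genes if g not in set(hubs) and g not in excluded]
    if n_hubs > 0 and hub_degree > len(non_hubs):
        raise ParameterError("hub_degree exceeds available (non-excluded) partners")
    support: set[tuple[str, str]] = set()
    for hub in hubs:
        partners = rng.choice(len(non_hubs), size=hub_degree, replace=False)
        for j in partners:
            support.add(_pair(hub, non_hubs[j]))

    # background edges among any non-excluded pair not already planted
    eligible = [g for g in genes if g not in excluded]
    attempts = 0
    planted = set(support)
    while len(support) < len(planted) + background_edges:
        i, j = rng.choice(len(eligible), size=2, replace=False)
        pair = _pair(eligible[i], eligible[j])
        if pair not in support:
            support.add(pair)
        attempts += 1
        if attempts > 1000 * (background_edges + 1):
            raise ParameterError("could not place background edges; budget too tight")

    omega = np.eye(n_genes)
    for a, b in sorted(support):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        # unit diagonal => precision off-diagonal -rho yields partial corr rho
        omega[index[a], index[b]] = omega[index[b], index[a]] = -sign * partial_corr_magnitude

    min_eig = np.linalg.eigvalsh(omega).min()
    if min_eig < EIGENVALUE_FLOOR:
        omega += (EIGENVALUE_FLOOR - min_eig + 1e-9) * np.eye(n_genes)
        if np.linalg.eigvalsh(omega).min() < EIGENVALUE_FLOOR - 1e-12:
            raise RuntimeError("diagonal inflation failed to reach eigenvalue floor")

    return PrecisionModel(
        gene_ids=genes,
        precision=omega,
        support=frozenset(support),
        hub_genes=frozenset(hubs),
        hub_degree=hub_degree,
    )


def simulate_condition(
    model: PrecisionModel,
    n_samples: int,
    mean_shift: Mapping[str, float] | None = None,
    baseline_mean: float = 8.0,
    seed: int = 0,
    condition: str = NORMAL,
    dataset_id: str = "dataset",
    gene_sd: Mapping[str, float] | None = None,
) -> ExpressionStudy:
    """Draw one condition's samples from N(mean, inverse(precision)).

    Returns a genes x samples study whose per-gene mean is
    ``baseline_mean + mean_shift[gene]``.  ``gene_sd`` optionally rescales
    per-gene noise (heterogeneous variances; off by default), which leaves all
    correlation structure untouched.
    """
    if n_samples < 3:
        raise ParameterError("n_samples must be >= 3 (per-gene variance estimability)")
    mean_shift = dict(mean_shift or {})
    unknown = set(mean_shift) - set(model.gene_ids)
    if unknown:
        raise ParameterError(f"mean_shift names unknown genes: {sorted(unknown)}")

    cov = model.covariance
    rng = np.random.default_rng(seed)
    try:
        draws = rng.multivariate_normal(
            np.zeros(len(model.gene_ids)), cov, size=n_samples, method="cholesky"
        )
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by model PD check
        raise DataError(f"covariance not factorizable: {exc}") from exc

    values = draws.T  # genes x samples
    if gene_sd is not None:
        scale = np.array([gene_sd.get(g, 1.0) for g in model.gene_ids])
        values = values * scale[:, None]
    means = baseline_mean + np.array([mean_shift.get(g, 0.0) for g in model.gene_ids])
    values = values + means[:, None]

    sample_ids = [f"{dataset_id}_{condition}_{i + 1:04d}" for i in range(n_samples)]
    frame = pd.DataFrame(values, index=list(model.gene_ids), columns=sample_ids)
    labels = pd.Series(condition, index=sample_ids, name="condition")
    return ExpressionStudy(values=frame, condition=labels, dataset_id=dataset_id)


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings for a two-condition study with planted truth.

    Defaults follow typical microarray conventions: log2 baseline 8.0, unit
    per-gene noise variance, 84 normal vs 210 cancer samples.
    """

    n_genes: int = 60
    n_cancer_hubs: int = 1
    n_normal_hubs: int = 0
    n_shared_hubs: int = 1
    hub_degree: int = 6
    background_edges: int = 30
    partial_corr_magnitude: float = 0.3
    n_de_genes: int = 0
    de_shift: float = 2.0
    de_up_fraction: float = 0.5
    n_normal: int = 84
    n_cancer: int = 210
    baseline_mean: float = 8.0
    identical_models: bool = False  # null setting: reuse the normal model for cancer
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de_genes > self.n_genes:
            raise ParameterError("n_de_genes cannot exceed n_genes")
        if self.n_de_genes > 0 and abs(self.de_shift) < 1.0:
            raise ParameterError("de_shift must be >= 1 log2 unit in magnitude")
        if min(self.n_normal, self.n_cancer) < 3:
            raise ParameterError("each condition needs >= 3 samples")


def _stage_seed(seed: int, stage: int) -> int:
    """Derive a stage-specific integer seed from the global seed.

    Uses a SeedSequence over (seed, stage) so stages are independently
    reproducible without hand-maintained offsets.
    """
    return int(np.random.SeedSequence((seed, stage)).generate_state(1)[0])


def plan_truth(params: SimulationParams) -> SyntheticTruth:
    """Construct the per-condition precision models and planted DE shifts."""
    genes = default_gene_ids(params.n_genes)
    rng = np.random.default_rng(_stage_seed(params.seed, 0))

    n_hub_total = params.n_shared_hubs + params.n_cancer_hubs + params.n_normal_hubs
    if n_hub_total > params.n_genes:
        raise ParameterError("more hubs requested than genes")
    chosen = rng.choice(params.n_genes, size=n_hub_total, replace=False)
    shared = [genes[i] for i in chosen[: params.n_shared_hubs]]
    cancer_only = [genes[i] for i in chosen[params.n_shared_hubs : params.n_shared_hubs + params.n_cancer_hubs]]
    normal_only = [genes[i] for i in chosen[params.n_shared_hubs + params.n_cancer_hubs :]]

    normal_hubs = shared + normal_only
    cancer_hubs = shared + cancer_only
    normal_model = make_precision_model(
        params.n_genes,
        n_hubs=len(normal_hubs),
        hub_degree=params.hub_degree,
        background_edges=params.background_edges,
        partial_corr_magnitude=params.partial_corr_magnitude,
        seed=_stage_seed(params.seed, 1),
        gene_ids=genes,
        hub_ids=normal_hubs,
        exclude_ids=cancer_only,
    )
    if params.identical_models:
        if params.n_cancer_hubs or params.n_normal_hubs:
            raise ParameterError(
                "identical_models is incompatible with condition-specific hubs"
            )
        cancer_model = normal_model
    else:
        cancer_model = make_precision_model(
        params.n_genes,
        n_hubs=len(cancer_hubs),
        hub_degree=params.hub_degree,
        background_edges=params.background_edges,
        partial_corr_magnitude=params.partial_corr_magnitude,
            seed=_stage_seed(params.seed, 2),
            gene_ids=genes,
            hub_ids=cancer_hubs,
            exclude_ids=normal_only,
        )

    de_genes: dict[str, float] = {}
    if params.n_de_genes:
        picked = rng.choice(params.n_genes, size=params.n_de_genes, replace=False)
        for i in sorted(picked):
            up = rng.random() < params.de_up_fraction
            de_genes[genes[i]] = abs(params.de_shift) if up else -abs(params.de_shift)

    return SyntheticTruth(
        normal_model=normal_model, cancer_model=cancer_model, de_genes=de_genes
    )


def make_two_condition_study(
    params: SimulationParams,
    truth: SyntheticTruth | None = None,
    dataset_id: str = "dataset",
    seed: int | None = None,
) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Simulate a full normal+cancer study and return it with its ground truth.

    The normal condition is drawn from ``truth.normal_model`` without shifts;
    the cancer condition from ``truth.cancer_model`` with the planted
    ``de_genes`` shifts applied.
    """
    if truth is None:
        truth = plan_truth(params)
    base_seed = params.seed if seed is None else seed
    normal = simulate_condition(
        truth.normal_model,
        params.n_normal,
        mean_shift=None,
        baseline_mean=params.baseline_mean,
        seed=_stage_seed(base_seed, 10),
        condition=NORMAL,
        dataset_id=dataset_id,
    )
    cancer = simulate_condition(
        truth.cancer_model,
        params.n_cancer,
        mean_shift=truth.de_genes,
        baseline_mean=params.baseline_mean,
        seed=_stage_seed(base_seed, 11),
        condition=CANCER,
        dataset_id=dataset_id,
    )
    values = pd.concat([normal.values, cancer.values], axis=1)
    condition = pd.concat([normal.condition, cancer.condition])
    study = ExpressionStudy(values=values, condition=condition, dataset_id=dataset_id)
    return study, truth


def make_multi_dataset(
    truth: SyntheticTruth,
    params: SimulationParams,
    per_dataset_sizes: Sequence[tuple[int, int]],
    seeds: Sequence[int],
) -> list[ExpressionStudy]:
    """Independent studies sharing one truth, differing in size and noise only."""
    if len(per_dataset_sizes) != len(seeds):
        raise ParameterError("per_dataset_sizes and seeds must have equal length")
    studies = []
    for d, ((n_norm, n_canc), seed) in enumerate(zip(per_dataset_sizes, seeds), start=1):
        p = dataclasses.replace(params, n_normal=n_norm, n_cancer=n_canc)
        study, _ = make_two_condition_study(
            p, truth=truth, dataset_id=f"sim{d}", seed=seed
        )
        studies.append(study)
    return studies


# ---------------------------------------------------------------------------
# writers

def write_study(study: ExpressionStudy, expression_path, annotation_path) -> None:
    """Write expression TSV (first column gene id) and sample annotation TSV."""
    frame = study.values.copy()
    frame.insert(0, "gene", frame.index)
    frame.to_csv(expression_path, sep="\t", index=False, float_format="%.6g")
    ann = pd.DataFrame(
        {
            "sample_id": list(study.sample_ids),
            "condition": [study.condition[s] for s in study.sample_ids],
            "dataset_id": study.dataset_id,
        }
    )
    ann.to_csv(annotation_path, sep="\t", index=False)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Persist the planted support pairs, hubs and shifts as JSON."""
    payload = {
        "normal": {
            "support": sorted(map(list, truth.normal_model.support)),
            "hubs": sorted(truth.normal_model.hub_genes),
        },
        "cancer": {
            "support": sorted(map(list, truth.cancer_model.support)),
            "hubs": sorted(truth.cancer_model.hub_genes),
        },
        "de_genes": dict(sorted(truth.de_genes.items())),
        "cancer_specific_hubs": sorted(truth.cancer_specific_hubs),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
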