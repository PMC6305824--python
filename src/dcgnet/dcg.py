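"""Differential-connectivity selection and the end-to-end pipeline.

Per condition, the top ``floor(q * N)`` genes of the betweenness ranking over
the shared N-gene universe form the "top set" (q defaults to 0.40, so a
154-gene universe yields 61).  Genes present in both conditions' top sets are
removed; what remains of the cancer top set is the differentially connected
gene (DCG) set — condition-specific hubs.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .centrality import GeneNetwork, betweenness, build_graph, centrality_table, rank_nodes
from .diffexpr import ALPHA, FC_HI, FC_LO, MutualDegSet, de_table, mutual_degs
from .errors import ParameterError, PipelineError
from .ggm import TOP_EDGES_DEFAULT, PartialCorrelationModel, fit_ggm, top_k_edges
from .simulate import CANCER, NORMAL, ExpressionStudy

__all__ = ["DcgResult", "PipelineConfig", "PipelineResult", "select_top_fraction", "dcg_set", "run_pipeline"]

logger = logging.getLogger(__name__)

FRACTION_DEFAULT = 0.40


@dataclass(frozen=True)
class DcgResult:
    """Top-fraction hub sets per condition, their overlap, and the DCG set."""

    cancer_top: frozenset[str]
    normal_top: frozenset[str]
    overlap: frozenset[str]
    dcgs: frozenset[str]
    fraction: float = FRACTION_DEFAULT

    def __post_init__(self) -> None:
        if self.overlap != self.cancer_top & self.normal_top:
            raise ParameterError("overlap must equal the top-set intersection")
        if self.dcgs != self.cancer_top - self.overlap:
            raise ParameterError("dcgs must equal cancer_top minus the overlap")

    @property
    def normal_specific(self) -> frozenset[str]:
        """The complement set: normal-top genes absent from the cancer top."""
        return self.normal_top - self.overlap


def select_top_fraction(
    ranked_nodes: Sequence[str], q: float = FRACTION_DEFAULT
) -> list[str]:
    """First ``floor(q * N)`` nodes of a ranked universe of size N.

    Deterministic given the ranking's tie-break; an empty selection is never
    intended and raises.
    """
    if not 0 < q <= 1:
        raise ParameterError("q must lie in (0, 1]")
    n_select = math.floor(q * len(ranked_nodes))
    if n_select == 0:
        raise ParameterError(
            f"floor({q} * {len(ranked_nodes)}) = 0 genes selected; widen q or the universe"
        )
    return list(ranked_nodes[:n_select])


def dcg_set(
    cancer_top: Sequence[str] | frozenset[str],
    normal_top: Sequence[str] | frozenset[str],
    fraction: float = FRACTION_DEFAULT,
) -> DcgResult:
    """Remove the cross-network overlap from the cancer top set."""
    ctop, ntop = frozenset(cancer_top), frozenset(normal_top)
    overlap = ctop & ntop
    return DcgResult(
        cancer_top=ctop,
        normal_top=ntop,
        overlap=overlap,
        dcgs=ctop - overlap,
        fraction=fraction,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and cuts for an end-to-end run; defaults match the printed
    pipeline parameters (fold-change 2.0 / 0.5, adjusted p 0.01, 1500 edges,
    top 40%)."""

    fc_hi: float = FC_HI
    fc_lo: float = FC_LO
    alpha: float = ALPHA
    top_edges: int = TOP_EDGES_DEFAULT
    fraction: float = FRACTION_DEFAULT
    cancer_label: str = CANCER
    normal_label: str = NORMAL
    network_genes: str = "mutual"  # "mutual": restrict GGMs to mutual DEGs; "all": full universe
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fc_lo < 1 < self.fc_hi):
            raise ParameterError("thresholds must satisfy 0 < fc_lo < 1 < fc_hi")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.top_edges < 1:
            raise ParameterError("top_edges must be >= 1")
        if not 0 < self.fraction <= 1:
            raise ParameterError("fraction must lie in (0, 1]")
        if self.network_genes not in ("mutual", "all"):
            raise ParameterError("network_genes must be 'mutual' or 'all'")


@dataclass
class PipelineResult:
    """Everything an end-to-end run produces, plus run metadata."""

    de_tables: dict[str, pd.DataFrame]
    mutual: MutualDegSet
    models: dict[str, PartialCorrelationModel]
    networks: dict[str, GeneNetwork]
    centralities: dict[str, pd.DataFrame]
    dcg: DcgResult
    config: PipelineConfig
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def report(self) -> dict:
        """Machine-readable run report with mutually consistent cardinalities."""
        report = {
            "tool_version": __version__,
            "config": {
                "fc_hi": self.config.fc_hi,
                "fc_lo": self.config.fc_lo,
                "alpha": self.config.alpha,
                "top_edges": self.config.top_edges,
                "fraction": self.config.fraction,
                "network_genes": self.config.network_genes,
                "seed": self.config.seed,
            },
            "degs_per_dataset": dict(self.mutual.per_dataset_counts),
            "n_mutual_degs": len(self.mutual.genes),
            "lambda": {c: m.lambda_star for c, m in self.models.items()},
            "n_edges": {c: net.n_edges for c, net in self.networks.items()},
            "top_set_size": {
                self.config.cancer_label: len(self.dcg.cancer_top),
                self.config.normal_label: len(self.dcg.normal_top),
            },
            "n_overlap": len(self.dcg.overlap),
            "n_dcgs": len(self.dcg.dcgs),
            "dcgs": sorted(self.dcg.dcgs),
            "overlap": sorted(self.dcg.overlap),
            "normal_specific": sorted(self.dcg.normal_specific),
            "stage_seconds": dict(self.stage_seconds),
        }
        if report["n_dcgs"] != len(self.dcg.cancer_top) - report["n_overlap"]:
            raise RuntimeError("report cardinalities inconsistent: DCG != top - overlap")
        return report


def run_pipeline(
    studies: Sequence[ExpressionStudy], config: PipelineConfig | None = None
) -> PipelineResult:
    """DEG calling -> intersection -> per-condition GGM -> top-k edges ->
    betweenness -> top-fraction cut -> DCG extraction.

    Each condition's network is fit on that condition's samples pooled across
    studies, restricted to the mutual-DEG universe (or all genes when
    ``network_genes='all'``).
    """
    config = config or PipelineConfig()
    if not studies:
        raise PipelineError("input", "at least one study is required")
    timings: dict[str, float] = {}

    def timed(stage: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %-12s done in %.2fs", stage, timings[stage])
        return out

    de_tables = timed(
        "deg",
        lambda: {
            s.dataset_id: de_table(
                s, fc_hi=config.fc_hi, fc_lo=config.fc_lo, alpha=config.alpha,
                cancer=config.cancer_label, normal=config.normal_label,
            )
            for s in studies
        },
    )
    mutual = timed(
        "intersect", mutual_degs, list(de_tables.values()), list(de_tables.keys())
    )
    logger.info("DEGs per dataset: %s; mutual: %d", mutual.per_dataset_counts, len(mutual.genes))

    if config.network_genes == "mutual":
        universe = sorted(mutual.genes)
        if not universe:
            raise PipelineError("intersect", "mutual DEG set is empty; nothing to network")
    else:
        universe = sorted(studies[0].gene_ids)

    models: dict[str, PartialCorrelationModel] = {}
    networks: dict[str, GeneNetwork] = {}
    centralities: dict[str, pd.DataFrame] = {}
    tops: dict[str, list[str]] = {}
    for label in (config.cancer_label, config.normal_label):
        pooled = pd.concat(
            [s.slice_condition(label).loc[universe] for s in studies], axis=1
        )
        model = timed(f"ggm[{label}]", fit_ggm, pooled)
        kept = top_k_edges(model.edges, config.top_edges)
        network = build_graph(
            zip(kept["gene_i"], kept["gene_j"]), universe, condition=label
        )
        scores = timed(f"betweenness[{label}]", betweenness, network)
        table = centrality_table(scores)
        tops[label] = select_top_fraction(rank_nodes(scores), config.fraction)
        models[label], networks[label], centralities[label] = model, network, table
        logger.info(
            "%s: lambda=%.4f, %d edges kept, top set %d genes",
            label, model.lambda_star, network.n_edges, len(tops[label]),
        )

    result = dcg_set(
        tops[config.cancer_label], tops[config.normal_label], fraction=config.fraction
    )
    logger.info(
        "top=%d overlap=%d dcgs=%d",
        len(result.cancer_top), len(result.overlap), len(result.dcgs),
    )
    return PipelineResult(
        de_tables=de_tables,
        mutual=mutual,
        models=models,
        networks=networks,
        centralities=centralities,
        dcg=result,
        config=config,
        stage_seconds=timings,
    )
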