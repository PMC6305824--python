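"""Run configuration: YAML parsing, validation, and report emission."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dcg import PipelineConfig, PipelineResult
from .errors import ParameterError

__all__ = ["RunConfig", "load_config", "dump_config", "emit_report"]

_THRESHOLD_KEYS = {"fc_hi", "fc_lo", "alpha", "top_edges", "fraction"}
_OTHER_KEYS = {"cancer_label", "normal_label", "network_genes", "seed", "datasets", "simulate", "out_dir"}
_KNOWN_KEYS = _THRESHOLD_KEYS | _OTHER_KEYS


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for an end-to-end run.

    ``datasets`` is a list of {expression, annotation} path pairs; when empty,
    ``simulate`` holds generator parameters for a synthetic run.
    """

    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    datasets: tuple[dict, ...] = ()
    simulate: dict = field(default_factory=dict)
    out_dir: str = "."


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config file; unknown keys are errors.

    An empty file yields all defaults (2.0, 0.5, 0.01, 1500, 0.40).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: config must be a key-value mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ParameterError(f"{path}: unknown config key(s): {sorted(unknown)}")

    pipeline_kwargs = {
        k: raw[k]
        for k in ("fc_hi", "fc_lo", "alpha", "top_edges", "fraction",
                  "cancer_label", "normal_label", "network_genes", "seed")
        if k in raw
    }
    try:
        pipeline = PipelineConfig(**pipeline_kwargs)
    except ParameterError as exc:
        raise ParameterError(f"{path}: {exc}") from exc

    datasets = raw.get("datasets") or []
    for entry in datasets:
        if not isinstance(entry, dict) or not {"expression", "annotation"} <= set(entry):
            raise ParameterError(
                f"{path}: each dataset entry needs 'expression' and 'annotation' paths"
            )
    return RunConfig(
        pipeline=pipeline,
        datasets=tuple(datasets),
        simulate=dict(raw.get("simulate") or {}),
        out_dir=str(raw.get("out_dir", ".")),
    )


def dump_config(config: RunConfig, path) -> None:
    payload = dataclasses.asdict(config.pipeline)
    payload.update(
        {"datasets": list(config.datasets), "simulate": config.simulate, "out_dir": config.out_dir}
    )
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def emit_report(result: PipelineResult, json_path=None, text_path=None) -> tuple[dict, str]:
    """JSON report plus a plain-text summary mirroring it exactly.

    The timestamp lives in a single field so two identical runs differ in at
    most that field.
    """
    report = result.report()
    report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    lines = ["differential-connectivity run summary", "=" * 38]
    lines.append(f"tool version       : {report['tool_version']}")
    for key, value in report["config"].items():
        lines.append(f"config {key:<12}: {value}")
    for dataset, count in report["degs_per_dataset"].items():
        lines.append(f"DEGs [{dataset}]     : {count}")
    lines.append(f"mutual DEGs        : {report['n_mutual_degs']}")
    for cond, lam in report["lambda"].items():
        lines.append(f"lambda [{cond}]    : {lam:.6f}")
    for cond, n_edges in report["n_edges"].items():
        lines.append(f"edges [{cond}]     : {n_edges}")
    for cond, size in report["top_set_size"].items():
        lines.append(f"top set [{cond}]   : {size}")
    lines.append(f"overlap            : {report['n_overlap']}")
    lines.append(f"DCGs               : {report['n_dcgs']}")
    lines.append(f"DCG genes          : {', '.join(report['dcgs'])}")
    text = "\n".join(lines) + "\n"

    if json_path is not None:
        Path(json_path).write_text(json.dumps(report, indent=2) + "\n")
    if text_path is not None:
        Path(text_path).write_text(text)
    return report, text
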