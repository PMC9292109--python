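"""End-to-end analysis assembly and reproducible JSON reporting.

``run_analysis`` chains the full pipeline on one cohort table:
standardize/orient -> implied-independence tests -> effect table (total,
direct, bivariate per exposure) -> per-unit predictive model -> k-fold
cross-validation, and returns a plain dict ready for JSON serialization.
Reports embed a :class:`RunManifest`; with the timestamp excluded, the same
manifest and inputs serialize byte-identically.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import math
from dataclasses import dataclass
from importlib import metadata
from typing import Optional

from .data import VariableTable, standardize_and_orient
from .estimate import (
    cross_validate,
    effect_table,
    predictive_model,
    test_implied_independencies,
)
from .identify import implied_independencies
from .model import ModelConfig

__all__ = ["RunManifest", "run_analysis", "round_floats", "dump_report"]


def _version() -> str:
    try:
        return metadata.version("cpcausal")
    except metadata.PackageNotFoundError:  # running from a checkout
        return "0.0.0+local"


@dataclass
class RunManifest:
    """Provenance block embedded in every report."""

    command: str
    model: str
    input_digest: Optional[str] = None
    seed: Optional[int] = None
    version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.version:
            self.version = _version()
        if not self.timestamp:
            self.timestamp = (
                datetime.datetime.now(datetime.timezone.utc).isoformat()
            )

    @staticmethod
    def digest_file(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        return h.hexdigest()

    def to_dict(self) -> dict:
        return {
            "command": self.command, "model": self.model,
            "input_digest": self.input_digest, "seed": self.seed,
            "version": self.version, "timestamp": self.timestamp,
        }


def round_floats(obj, sig: int = 6):
    """Round every float in a nested structure to ``sig`` significant digits.

    Keeps report files deterministic across platforms and readable; 6
    significant digits is far below estimation noise for every quantity
    reported.
    """
    if isinstance(obj, float):
        if obj == 0 or not math.isfinite(obj):
            return obj
        return round(obj, sig - 1 - int(math.floor(math.log10(abs(obj)))))
    if isinstance(obj, dict):
        return {k: round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, sig) for v in obj]
    return obj


def run_analysis(
    raw: VariableTable,
    config: ModelConfig,
    alpha: float = 0.05,
    k: int = 10,
    seed: int = 0,
    manifest: Optional[RunManifest] = None,
) -> dict:
    """Full pipeline on one cohort; returns a JSON-ready report dict."""
    statements = implied_independencies(config.graph)
    std = standardize_and_orient(raw, config)
    ci_results = test_implied_independencies(std, statements, alpha=alpha)
    estimates, over, failures = effect_table(std, config)
    pred = predictive_model(raw, config)
    cv = cross_validate(raw, config, k=k, seed=seed)
    report = {
        "model": config.name,
        "n_subjects": raw.n,
        "alpha": alpha,
        "implied_independencies": [s.to_dict() for s in statements],
        "ci_tests": [r.to_dict() for r in ci_results],
        "n_rejected": sum(r.rejected for r in ci_results),
        "effects": [e.to_dict() for e in estimates],
        "bivariate_overestimation": over,
        "effect_failures": failures,
        "predictive_model": pred.to_dict(),
        "cross_validation": cv.to_dict(),
    }
    if manifest is not None:
        report["manifest"] = manifest.to_dict()
    return report


def dump_report(report: dict, path=None) -> str:
    """Serialize a report with sorted keys and 6-significant-digit floats."""
    text = json.dumps(round_floats(report), indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text
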