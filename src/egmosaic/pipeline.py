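"""Workflow composition and run manifests.

Wires the stage functions into the published order (homolog filter →
alignment filter → tree classification → bin summary) with a manifest
recording the count funnel, the effective configuration and its hash, so
a run is reproducible and every stage's inputs reconcile with its
retained + excluded outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import ancestry
from .ancestry import (AncestryCall, BinSummary, SupportTree, TaxonGroupMap,
                       classify_trees, summarize_bins)

logger = logging.getLogger(__name__)

#: Every tunable threshold with its published default.
DEFAULT_CONFIG: dict = {
    "evalue_max": 1e-2,
    "min_hits": 3,
    "min_alignment_length": 74,
    "support_min": 75.0,
    "mito_score_min": 0.9,
    "chlorop_max_len": 200,
    "min_contig": 10_000,
}


def effective_config(overrides: Mapping | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if overrides:
        unknown = set(overrides) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(overrides)
    return cfg


def config_hash(cfg: Mapping) -> str:
    payload = json.dumps(dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    tool_version: str
    config: dict
    config_hash: str
    seed: int | None
    counts: dict[str, int] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)

    def reconcile(self) -> None:
        """Check inputs = retained + excluded at every recorded stage."""
        c = self.counts
        checks = [
            ("n_proteins_input", "n_homolog_retained", "n_homolog_excluded"),
            ("n_homolog_retained", "n_alignment_retained", "n_alignment_excluded"),
            ("n_trees", "n_classified_or_flagged", "n_unclassified"),
        ]
        for total, kept, dropped in checks:
            if total in c and kept in c and dropped in c:
                if c[total] != c[kept] + c[dropped]:
                    raise ValueError(
                        f"manifest mismatch: {total}={c[total]} != "
                        f"{kept}+{dropped}={c[kept] + c[dropped]}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_ancestry_workflow(
    trees: Sequence[SupportTree],
    taxmap: TaxonGroupMap,
    homolog_table: pd.DataFrame | None = None,
    alignment_meta: pd.DataFrame | None = None,
    config: Mapping | None = None,
    seed: int | None = None,
    rollups: Mapping[str, list[str]] | None = None,
) -> tuple[list[AncestryCall], BinSummary, RunManifest]:
    """Prefilters then classification then summary, with a count manifest.

    Trees whose protein identifier fails a prefilter are reported with
    status ``excluded_prefilter`` rather than silently dropped. Prefilter
    tables are optional: a missing table skips that stage.
    """
    cfg = effective_config(config)
    counts: dict[str, int] = {}

    retained: set[str] | None = None
    if homolog_table is not None:
        counts["n_proteins_input"] = int(homolog_table["protein_id"].nunique())
        retained = ancestry.filter_homologs(
            homolog_table, cfg["evalue_max"], cfg["min_hits"])
        counts["n_homolog_retained"] = len(retained)
        counts["n_homolog_excluded"] = counts["n_proteins_input"] - len(retained)
    if alignment_meta is not None:
        pool = retained if retained is not None else \
            set(alignment_meta["protein_id"])
        counts.setdefault("n_homolog_retained", len(pool))
        aln_ok = ancestry.filter_alignments(
            alignment_meta, cfg["min_alignment_length"])
        retained = pool & aln_ok
        counts["n_alignment_retained"] = len(retained)
        counts["n_alignment_excluded"] = \
            counts["n_homolog_retained"] - len(retained)

    to_classify, calls = [], []
    for t in trees:
        if retained is not None and t.name not in retained:
            calls.append(AncestryCall(t.name, "excluded_prefilter"))
        else:
            to_classify.append(t)
    calls.extend(classify_trees(to_classify, taxmap, cfg["support_min"]))

    summary = summarize_bins(calls, rollups=rollups)
    counts["n_trees"] = len(trees)
    counts["n_excluded_prefilter"] = len(trees) - len(to_classify)
    counts["n_classified"] = summary.n_classified
    counts["n_classified_or_flagged"] = summary.n_classified + summary.n_flagged
    counts["n_unclassified"] = summary.n_unclassified + \
        counts["n_excluded_prefilter"]
    counts["n_flagged"] = summary.n_flagged

    manifest = RunManifest(
        tool_version=_version(),
        config=cfg,
        config_hash=config_hash(cfg),
        seed=seed,
        counts=counts,
    )
    # n_trees splits into classified/flagged + (unclassified + prefilter-excluded)
    manifest.reconcile()
    return calls, summary, manifest


def _version() -> str:
    try:
        return _pkg_version("egmosaic")
    except Exception:
        return "0+unknown"


# ---------------------------------------------------------------------------
# consolidated report
# ---------------------------------------------------------------------------

REPORT_SECTIONS = ("ancestry", "organelle", "omics", "genome", "manifest")


def run_report(sections: Mapping[str, dict | None],
               path: str | Path | None = None) -> dict:
    """Consolidate module outputs into one strict-schema JSON report.

    Only the known section names are accepted; absent sections appear as
    explicit nulls. At least one section must be present.
    """
    unknown = set(sections) - set(REPORT_SECTIONS)
    if unknown:
        raise ValueError(f"unknown report sections: {sorted(unknown)}")
    report = {name: sections.get(name) for name in REPORT_SECTIONS}
    if all(v is None for v in report.values()):
        raise ValueError("at least one module output is required")
    for name, section in report.items():
        if section is not None and not isinstance(section, dict):
            raise ValueError(f"section {name!r} must be a JSON object")
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
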