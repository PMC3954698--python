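"""End-to-end workflows: signature derivation and cohort classification.

Each workflow reads validated inputs, runs the pipeline stages in order,
writes every result table plus a JSON run manifest (config snapshot, input
checksums, per-stage record counts, version, timestamps) so a run can be
replayed from its manifest alone. A single global seed fans out to
per-stage seeds by fixed offsets, keeping each stage reproducible
independently of stage order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .classify import (
    ClassificationCriteria,
    classify_cohort,
    summarize_representation,
)
from .gsea import GseaConfig
from .homology import map_to_human
from .io import (
    ExpressionTable,
    GeneSet,
    GeneSetCollection,
    read_expression_table,
    read_gene_sets,
    read_homolog_table,
    write_gene_sets,
)
from .pathways import ClusteringConfig
from .sage import (
    DeCriteria,
    SignatureGeneSet,
    de_test_replicated,
    de_test_unreplicated,
    intersect_models,
    normalize_tpm,
    select_deregulated,
)

log = logging.getLogger(__name__)

_STAGE_SEED_OFFSETS = {"simulate": 11, "gsea": 23, "classify": 37, "cluster": 53}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the run's global seed."""
    return (global_seed * 1009 + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class SignatureRunConfig:
    """Inputs for the signature-derivation workflow.

    ``models`` maps model name -> dict with keys ``counts`` (path to a
    tag-count TSV), ``tumor_samples``, ``control_samples`` (lists of
    column names). Models with one tumor sample use the one-sample ratio
    t-test; models with >= 2 use the replicated two-sample test.
    """

    models: dict[str, dict]
    out_dir: str
    criteria: DeCriteria = field(default_factory=DeCriteria)
    homolog_table: str | None = None
    seed: int = 0


@dataclass
class ClassificationRunConfig:
    """Inputs for the cohort classification workflow."""

    cohorts: dict[str, str]  # dataset id -> expression TSV path
    signatures_gmt: str
    out_dir: str
    gsea: GseaConfig = field(default_factory=GseaConfig)
    criteria: ClassificationCriteria = field(default_factory=ClassificationCriteria)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    seed: int = 0


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_manifest(
    out_dir: Path,
    config,
    input_paths: Sequence[str | Path],
    counts: Mapping[str, int],
    status: str = "ok",
) -> Path:
    manifest = {
        "version": __version__,
        "status": status,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": _jsonable(config),
        "inputs": {str(p): _sha256(p) for p in input_paths},
        "record_counts": dict(counts),
    }
    path = out_dir / "manifest.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(path)  # atomic publish
    return path


def run_signature_workflow(config: SignatureRunConfig) -> dict:
    """Derive per-model signatures and their three-model intersection.

    Writes per-model DE tables (TSV), up/down signature GMTs (zebrafish
    identifiers, plus human identifiers when a homolog table is given), a
    Venn region report (JSON) and the run manifest. Returns a dict with
    the in-memory results.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    inputs: list[str] = []
    up_sets: dict[str, SignatureGeneSet] = {}
    down_sets: dict[str, SignatureGeneSet] = {}
    de_tables: dict[str, pd.DataFrame] = {}
    for model, spec in config.models.items():
        try:
            counts_table = read_expression_table(spec["counts"], "tag_count")
            inputs.append(spec["counts"])
            tpm = normalize_tpm(counts_table)
            tumor = list(spec["tumor_samples"])
            controls = list(spec["control_samples"])
            if len(tumor) == 1:
                de = de_test_unreplicated(tpm, tumor[0], controls, config.criteria)
            else:
                de = de_test_replicated(tpm, tumor, controls, config.criteria)
        except Exception as exc:
            raise RuntimeError(f"[stage derive:{model}] {exc}") from exc
        de_tables[model] = de
        de.to_csv(out_dir / f"de_{model}.tsv", sep="\t", index=False)
        counts[f"de_{model}"] = len(de)
        up, down = select_deregulated(de, config.criteria, name=model)
        if up is None or down is None:
            raise RuntimeError(
                f"[stage select:{model}] no genes selected in one direction"
            )
        up_sets[model] = up
        down_sets[model] = down
        counts[f"up_{model}"] = len(up)
        counts[f"down_{model}"] = len(down)
        log.info("model %s: %d up, %d down selected", model, len(up), len(down))

    if len(config.models) == 3:
        venn = intersect_models(up_sets, down_sets)
        counts["common_up"] = len(venn.common_up)
        counts["common_down"] = len(venn.common_down)
        venn_report = {
            "up": {"+".join(k): len(v) for k, v in venn.up.regions.items()},
            "down": {"+".join(k): len(v) for k, v in venn.down.regions.items()},
            "common_up_genes": sorted(venn.common_up),
            "common_down_genes": sorted(venn.common_down),
        }
        (out_dir / "venn.json").write_text(json.dumps(venn_report, indent=2))
    else:
        venn = None

    entries = []
    for model in config.models:
        entries.append(GeneSet(up_sets[model].name, f"{model} up", up_sets[model].members))
        entries.append(
            GeneSet(down_sets[model].name, f"{model} down", down_sets[model].members)
        )
    write_gene_sets(GeneSetCollection(entries), out_dir / "signatures.gmt")

    mapped = None
    if config.homolog_table:
        homologs = read_homolog_table(config.homolog_table)
        inputs.append(config.homolog_table)
        mapped = {m: map_to_human(up_sets[m], homologs) for m in config.models}
        human_entries = [
            GeneSet(f"{m}_human", f"{m} signature (human ids)", ms.human_members)
            for m, ms in mapped.items()
            if ms.human_members
        ]
        if human_entries:
            write_gene_sets(
                GeneSetCollection(human_entries), out_dir / "signatures_human.gmt"
            )
        for m, ms in mapped.items():
            counts[f"human_{m}"] = len(ms.human_members)

    _write_manifest(out_dir, config, inputs, counts)
    return {
        "de": de_tables,
        "up": up_sets,
        "down": down_sets,
        "venn": venn,
        "mapped": mapped,
        "counts": counts,
    }


def run_classification_workflow(config: ClassificationRunConfig) -> dict:
    """Classify every cohort sample against every signature and summarize.

    Writes the per-(sample, signature) classification table (TSV), the
    representation summary (JSON), a heatmap-ready NES matrix (TSV) and
    the manifest. Summary invariants (pct_any >= each per-signature
    percentage, triple <= each pairwise) are asserted before anything is
    published; on failure the partial outputs stay on disk next to a
    manifest marked failed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gene_sets = read_gene_sets(config.signatures_gmt)
    if len(gene_sets) == 0:
        raise RuntimeError("[stage classify] no signatures in GMT")
    signatures = [(gs.name, gs.members) for gs in gene_sets]
    gsea_cfg = dataclasses.replace(
        config.gsea, rng_seed=stage_seed(config.seed, "classify")
    )
    tables = []
    inputs = [config.signatures_gmt]
    for dataset_id, path in config.cohorts.items():
        expr = read_expression_table(path, "intensity")
        inputs.append(path)
        tables.append(
            classify_cohort(expr, signatures, gsea_cfg, config.criteria, dataset_id)
        )
    table = pd.concat(tables, ignore_index=True)
    counts = {"classification_rows": len(table)}
    try:
        summary = summarize_representation(table)
    except AssertionError as exc:
        table.to_csv(out_dir / "classification.tsv", sep="\t", index=False)
        _write_manifest(out_dir, config, inputs, counts, status="failed")
        raise RuntimeError(f"[stage summarize] invariant violated: {exc}") from exc
    table.to_csv(out_dir / "classification.tsv", sep="\t", index=False)
    nes = table.pivot_table(
        index="sample_id", columns="signature", values="nes", aggfunc="first"
    )
    nes.to_csv(out_dir / "nes_matrix.tsv", sep="\t")
    (out_dir / "representation.json").write_text(
        json.dumps(
            {
                "overall": summary.overall,
                "per_dataset": summary.per_dataset.to_dict(orient="index"),
                "n_samples": summary.n_samples,
            },
            indent=2,
        )
    )
    counts["flagged_rows"] = int(table["correlated"].sum())
    _write_manifest(out_dir, config, inputs, counts)
    return {"table": table, "summary": summary, "counts": counts}
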