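"""End-to-end orchestration: encode -> affinity -> graph -> sample -> train -> evaluate.

Every run writes its artifacts plus a manifest (config hash, seed, library
versions) so a rerun with the same config hash reproduces the reports
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .core_io import (
    NamedMatrix,
    read_association_table,
    read_fasta,
    read_named_matrix,
    write_named_matrix,
)
from .evaluation import METRIC_NAMES, EvalReport, run_cv
from .features import build_disease_views, build_site_views
from .multiview import learn_affinity

log = logging.getLogger("pathorm")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            log.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("load")
def load_inputs(config: RunConfig):
    inp = config.inputs
    records = read_fasta(inp.fasta, inp.window)
    assoc = read_association_table(inp.associations)
    site_sem = read_named_matrix(inp.site_semantic)
    disease_sem = read_named_matrix(inp.disease_semantic)
    go = read_named_matrix(inp.disease_go)
    return records, assoc, site_sem, disease_sem, go


def validate_inputs(config: RunConfig) -> list[str]:
    """Cross-file id alignment check; returns a list of problems (empty = ok)."""
    problems = []
    try:
        records, assoc, site_sem, disease_sem, go = load_inputs(config)
    except Exception as e:
        return [str(e)]
    rec_ids = {r.site_id for r in records}
    missing = set(assoc.site_index) - rec_ids
    if missing:
        problems.append(f"sites without sequences: {sorted(missing)[:5]}")
    missing = set(assoc.site_index) - set(site_sem.row_ids)
    if missing:
        problems.append(f"sites without semantic rows: {sorted(missing)[:5]}")
    for name, mat in (("semantic", disease_sem), ("GO", go)):
        missing = set(assoc.disease_index) - set(mat.row_ids)
        if missing:
            problems.append(f"diseases without {name} rows: {sorted(missing)[:5]}")
    return problems


@_stage("affinity")
def affinity_stage(config: RunConfig, site_views, disease_views):
    C_ss, trace_s = learn_affinity(site_views, config.multiview)
    C_dd, trace_d = learn_affinity(disease_views, config.multiview)
    return C_ss, C_dd, trace_s, trace_d


@_stage("evaluate")
def evaluate_stage(config, assoc, C_ss, C_dd, site_sem, disease_sem) -> EvalReport:
    return run_cv(
        assoc,
        C_ss,
        C_dd,
        site_sem,
        disease_sem,
        config.graph,
        enc=config.encoder,
        adv=config.adversarial,
        tr=config.training,
        sampler=config.sampling,
        k=config.evaluation.folds,
        seed=stage_cv_seed(config),
    )


def stage_cv_seed(config: RunConfig) -> int:
    from .config import stage_seed

    return stage_seed(config.seed, "evaluation")


def report_to_dict(report: EvalReport) -> dict:
    return {
        "per_fold": report.per_fold,
        "mean": {m: report.mean(m) for m in METRIC_NAMES},
        "sd": {m: report.sd(m) for m in METRIC_NAMES},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order, writing artifacts and a manifest to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, assoc, site_sem, disease_sem, go = load_inputs(config)

    site_views = build_site_views(records, site_sem, use_alt=config.features.use_alt)
    disease_views = build_disease_views(go, disease_sem)
    # the candidate universe is every sequenced site and every featured disease,
    # not only those appearing in a validated pair
    assoc = assoc.with_indices(site_views.entity_ids, disease_views.entity_ids)
    # restrict view row order to the association indices
    site_sem = site_sem.reorder(assoc.site_index)
    disease_sem = disease_sem.reorder(assoc.disease_index)

    C_ss, C_dd, trace_s, trace_d = affinity_stage(config, site_views, disease_views)
    C_ss = C_ss.reorder(assoc.site_index)
    C_dd = C_dd.reorder(assoc.disease_index)
    write_named_matrix(NamedMatrix(C_ss.entity_ids, C_ss.values), outdir / "C_ss.tsv")
    write_named_matrix(NamedMatrix(C_dd.entity_ids, C_dd.values), outdir / "C_dd.tsv")

    report = evaluate_stage(config, assoc, C_ss, C_dd, site_sem, disease_sem)
    result = report_to_dict(report)
    with open(outdir / "cv_report.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "pathorm_version": __version__,
        "numpy_version": np.__version__,
        "n_sites": assoc.m,
        "n_diseases": assoc.n,
        "n_positives": len(assoc.positives),
        "solver_converged": [trace_s.converged, trace_d.converged],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result


def write_bundle(bundle, outdir: str | Path) -> None:
    """Serialize a synthetic bundle as the FASTA/TSV files the pipeline reads."""
    from .core_io import write_association_table, write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.records, outdir / "sites.fa")
    write_association_table(bundle.associations, outdir / "associations.tsv")
    write_named_matrix(bundle.site_semantic, outdir / "site_semantic.tsv")
    write_named_matrix(bundle.disease_semantic, outdir / "disease_semantic.tsv")
    write_named_matrix(bundle.disease_go, outdir / "disease_go.tsv")
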