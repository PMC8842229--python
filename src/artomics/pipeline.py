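"""End-to-end workflow: simulate -> extract -> select -> train -> compare.

One :class:`RunConfig` (JSON-serialisable) determines a run completely:
identical config and seed reproduce identical feature tables and model
reports.  Every artefact is written alongside a provenance record with
the config hash and master seed.

The full model roster is the four single-omics Ridge models (R, M, D, C),
the four multi-kernel multi-omics models (RM, RD, RC, RMDC) and the
radiomics model retrained with MKL (R_MKL).  Comparisons are paired
t-tests on identical split plans: R against each other single-omics model,
RMDC against the other multi-omics models, and R_MKL against all four
multi-omics models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .contouromics import assemble_contouromics
from .datamodel import FeatureTable, PatientRecord
from .dosiomics import assemble_dosiomics
from .feature_selection import FSCombination, decision_graph_select
from .modeling import (
    ModelReport,
    build_model,
    compare_models,
    evaluate_combinations,
    make_split_plan,
)
from .radiomics import ExtractionConfig, assemble_morphology, assemble_radiomics
from .synthetic import SyntheticConfig, resolve_laterality

log = logging.getLogger(__name__)

SINGLE_OMICS = ("R", "M", "D", "C")
MULTI_OMICS = ("RM", "RD", "RC", "RMDC")

#: the paired comparisons reported by the pipeline
COMPARISONS: Tuple[Tuple[str, str], ...] = (
    ("R", "M"), ("R", "C"), ("R", "D"),
    ("RMDC", "RM"), ("RMDC", "RD"), ("RMDC", "RC"),
    ("R_MKL", "RM"), ("R_MKL", "RD"), ("R_MKL", "RC"), ("R_MKL", "RMDC"),
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialisable to JSON."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    fs_supervised: str = "fisher"
    fs_unsupervised: str = "variance"
    fs_search: bool = False
    k_sup: int = 100
    k_final: int = 30
    models: Tuple[str, ...] = SINGLE_OMICS + MULTI_OMICS + ("R_MKL",)
    eliminate: bool = True
    seed: int = 0
    output_dir: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)

    @staticmethod
    def from_json(text: str) -> "RunConfig":
        raw = json.loads(text)
        raw["synthetic"] = SyntheticConfig(**{
            **raw["synthetic"],
            "grid": tuple(raw["synthetic"]["grid"]),
            "spacing": tuple(raw["synthetic"]["spacing"]),
        })
        raw["extraction"] = ExtractionConfig(**{
            **raw["extraction"],
            "log_sigmas_mm": tuple(raw["extraction"]["log_sigmas_mm"]),
        })
        raw["models"] = tuple(raw["models"])
        return RunConfig(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def extract_all_families(
    records: Sequence[PatientRecord], extraction: ExtractionConfig
) -> Dict[str, FeatureTable]:
    """The four per-family feature tables for a laterality-resolved cohort."""
    return {
        "R": assemble_radiomics(records, extraction),
        "M": assemble_morphology(records),
        "D": assemble_dosiomics(records, extraction),
        "C": assemble_contouromics(records),
    }


def cohort_feature_tables(
    synthetic: SyntheticConfig, extraction: ExtractionConfig
) -> Tuple[Dict[str, FeatureTable], np.ndarray]:
    """Generate a synthetic cohort and extract all four families, streaming.

    Patients are generated, extracted and discarded one at a time, so the
    memory footprint is one patient's volumes plus the feature tables.
    """
    from .synthetic import draw_labels, generate_patient

    labels = draw_labels(synthetic)
    rows: Dict[str, List[np.ndarray]] = {f: [] for f in SINGLE_OMICS}
    columns: Dict[str, list] = {}
    ids: List[str] = []
    for i in range(synthetic.n_patients):
        rec = resolve_laterality(generate_patient(synthetic, i, int(labels[i])))
        ids.append(rec.patient_id)
        for fam, table in extract_all_families([rec], extraction).items():
            rows[fam].append(table.matrix[0])
            columns[fam] = table.columns
    tables = {
        fam: FeatureTable(np.vstack(rows[fam]), columns[fam], ids)
        for fam in SINGLE_OMICS
    }
    return tables, labels


def _table_for_model(name: str, tables: Dict[str, FeatureTable]) -> FeatureTable:
    fams = [c for c in (name.replace("_MKL", "")) if c in SINGLE_OMICS]
    if len(fams) == 1:
        return tables[fams[0]]
    return FeatureTable.concat([tables[f] for f in fams])


@dataclass
class PipelineResult:
    reports: Dict[str, ModelReport]
    comparisons: "object"  # pandas.DataFrame
    fs_choices: Dict[str, str]
    config_hash: str
    seed: int
    timings: Dict[str, float] = field(default_factory=dict)


def run_pipeline(
    config: RunConfig,
    records: Optional[List[PatientRecord]] = None,
    tables: Optional[Dict[str, FeatureTable]] = None,
    labels: Optional[np.ndarray] = None,
) -> PipelineResult:
    """Execute the full workflow; stages may be injected for reuse.

    If ``tables``/``labels`` are given the simulate/extract stages are
    skipped (e.g. features loaded from disk); otherwise a synthetic cohort
    is generated from ``config.synthetic``.
    """
    import pandas as pd

    timings: Dict[str, float] = {}
    t0 = time.time()
    if tables is None or labels is None:
        if records is None:
            tables, labels = cohort_feature_tables(config.synthetic, config.extraction)
        else:
            records = [resolve_laterality(r) for r in records]
            labels = np.array([r.label for r in records], dtype=int)
            tables = extract_all_families(records, config.extraction)
        timings["simulate+extract"] = time.time() - t0

    plan = make_split_plan(labels, config.seed)

    t0 = time.time()
    fs_choices: Dict[str, str] = {}
    combos: Dict[str, FSCombination] = {}
    model_names = list(config.models)
    for name in model_names:
        table = _table_for_model(name, tables)
        if config.fs_search:
            evals = evaluate_combinations(
                table, labels, plan, k_sup=config.k_sup, k_final=config.k_final
            )
            combos[name] = decision_graph_select(evals)
        else:
            combos[name] = FSCombination(config.fs_supervised, config.fs_unsupervised)
        fs_choices[name] = str(combos[name])
    timings["select"] = time.time() - t0

    t0 = time.time()
    reports: Dict[str, ModelReport] = {}
    for name in model_names:
        table = _table_for_model(name, tables)
        kind = "ridge" if name in SINGLE_OMICS else "mkl"
        reports[name] = build_model(
            table, labels, plan, combos[name], name, model=kind,
            k_sup=config.k_sup, k_final=config.k_final, eliminate=config.eliminate,
        )
        log.info(
            "model %s: hold-out AUC %.3f (train %.3f)",
            name, reports[name].test_summary["mean"], reports[name].train_summary["mean"],
        )
    timings["train"] = time.time() - t0

    rows = []
    for a, b in COMPARISONS:
        if a not in reports or b not in reports:
            continue
        rows.append({
            "model_a": a,
            "model_b": b,
            "p_train": compare_models(reports[a].train_aucs, reports[b].train_aucs),
            "p_holdout": compare_models(reports[a].test_aucs, reports[b].test_aucs),
        })
    comparisons = pd.DataFrame(rows)

    result = PipelineResult(reports, comparisons, fs_choices, config.config_hash(), config.seed, timings)
    if config.output_dir:
        write_outputs(result, config, tables)
    return result


def write_outputs(
    result: PipelineResult, config: RunConfig, tables: Dict[str, FeatureTable]
) -> None:
    """Persist feature tables, reports and comparisons with provenance."""
    from . import __version__
    from .io import write_feature_table

    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    provenance = {
        "config_hash": result.config_hash,
        "seed": result.seed,
        "version": __version__,
        "config": json.loads(config.to_json()),
    }
    with open(os.path.join(out, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2)
    for fam, table in tables.items():
        write_feature_table(table, os.path.join(out, f"features_{fam}.csv"))
    serializable = {
        name: {
            "feature_keys": r.feature_keys,
            "train_aucs": r.train_aucs,
            "test_aucs": r.test_aucs,
            "train_summary": r.train_summary,
            "test_summary": r.test_summary,
            "family_shares": r.family_shares,
            "trajectory": r.trajectory,
            "config_hash": result.config_hash,
        }
        for name, r in result.reports.items()
    }
    with open(os.path.join(out, "model_reports.json"), "w") as fh:
        json.dump(serializable, fh, indent=2)
    result.comparisons.to_csv(os.path.join(out, "comparisons.csv"), index=False)
    with open(os.path.join(out, "fs_choices.json"), "w") as fh:
        json.dump(result.fs_choices, fh, indent=2)
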