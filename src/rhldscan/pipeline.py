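"""End-to-end orchestration: select -> filter -> burden/calibrate -> set load.

A run is described by a YAML/dict configuration naming either input files
(phenotype TSV, variant table, gene sets) or a synthetic-generation block,
plus stage parameters.  Every stage that runs is recorded in the run
report with its record counts, so filter attrition is auditable; the
report is a plain dict serialized to JSON.  Given identical inputs, config
and seed, a run is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import yaml

from . import burden as burden_mod
from . import filtering, geneset, selection, simulate
from .cohort import (
    GeneMutationMatrix,
    read_cohort,
    read_gene_sets,
    read_variants,
    write_matrix,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _round_p(p: float, sig: int = 4) -> float:
    """Display rounding to a few significant figures; storage is full precision."""
    if p == 0:
        return 0.0
    from math import floor, log10
    return round(p, -int(floor(log10(abs(p)))) + sig - 1)


def run_pipeline(
    config: str | Path | dict, out_dir: str | Path | None = None
) -> dict[str, Any]:
    """Execute the configured stages and return the run report.

    ``config`` is a path to a YAML file or an equivalent dict.  Output
    tables (matrices, burden and load results, report JSON) are written
    under ``out_dir`` (or ``config["out_dir"]``) when given.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out_dir = Path(out_dir or config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {"config": config, "stages": [], "warnings": []}

    # -- inputs ------------------------------------------------------------
    cohort, variants, gene_sets = _load_inputs(config, report, out_dir)
    report["stages"].append("inputs")
    report["inputs"] = {
        "n_subjects": len(cohort),
        "n_cases": sum(1 for s in cohort if s.group == "case"),
        "n_controls": sum(1 for s in cohort if s.group == "control"),
        "n_variants": len(variants),
        "n_gene_sets": len(gene_sets),
    }

    # -- phenotype selection ----------------------------------------------
    sel_cfg = config.get("selection", {})
    rule = selection.SelectionRule(
        production_cutoff=sel_cfg.get("production_cutoff", -50.0),
        all_task_cutoff=sel_cfg.get("all_task_cutoff", -15.0),
    )
    labels = _run_selection(cohort, rule)
    report["stages"].append("selection")
    report["selection"] = {
        "rule": dataclasses.asdict(rule),
        "counts": {
            label: sum(1 for v in labels.values() if v == label)
            for label in sorted(set(labels.values()))
        },
    }
    report["laterality_summary"] = selection.summarize_laterality(cohort)

    # -- variant filtering and matrices -------------------------------------
    fcfg_dict = config.get("filter", {})
    fcfg = filtering.FilterConfig(
        cohort_presence_max=fcfg_dict.get("cohort_presence_max", 19),
        recessive_maf_max=fcfg_dict.get("recessive_maf_max", 0.10),
        dominant_maf_max=fcfg_dict.get("dominant_maf_max", 0.01),
    )
    models = config.get("models", ["dominant", "recessive"])
    filtered, filter_counts = _run_filters(variants, cohort, fcfg)
    report["stages"].append("filtering")
    report["filtering"] = {"config": dataclasses.asdict(fcfg), **filter_counts}

    alpha = config.get("alpha", 0.05)
    matrices: dict[str, GeneMutationMatrix] = {}
    report["burden"] = {}
    for model in models:
        matrix = _build_matrix(cohort, filtered, model, fcfg)
        matrices[model] = matrix
        write_matrix(matrix, out_dir / f"matrix_{model}.tsv")
        per_subject = list(matrix.genes_per_subject().values())
        qc = burden_mod.qc_count_comparison(matrix, cohort)
        results = burden_mod.burden_scan(matrix, cohort)
        calib = burden_mod.calibrate(matrix, cohort, alpha=alpha)
        _write_burden(results, out_dir / f"burden_{model}.tsv")
        report["stages"].append(f"burden:{model}")
        report["burden"][model] = {
            "n_genes": len(matrix.genes),
            "mean_genes_per_subject": (
                sum(per_subject) / len(per_subject) if per_subject else 0.0
            ),
            "qc_count_t": qc.t,
            "qc_count_p": qc.p,
            "n_genes_tested": len(results),
            "top": [
                {
                    "gene": r.gene, "a": r.a, "c": r.c,
                    "p": _round_p(r.p_one_tailed),
                    "any_control_carrier": r.any_control_carrier,
                }
                for r in results[:10]
            ],
            "calibration": {
                "alpha": alpha,
                "min_x_nominal": calib.min_x_nominal,
                "min_x_bonferroni": calib.min_x_bonferroni,
            },
        }

    # -- gene-set load -------------------------------------------------------
    if gene_sets:
        load_cfg = config.get("load", {})
        model = load_cfg.get("model", "dominant")
        contrasts = load_cfg.get("contrasts", [{}])
        load_tables = []
        for spec in contrasts:
            contrast = geneset.Contrast(**spec)
            results = geneset.load_scan(
                matrices[model], gene_sets, cohort, contrast
            )
            load_tables.append(
                {
                    "contrast": dataclasses.asdict(contrast),
                    "results": [
                        {
                            "set": r.name, "size": r.set_size,
                            "k_test": r.k_test, "n_total": r.n_total,
                            "p0": round(r.p0, 4),
                            "p": _round_p(r.p_binomial),
                        }
                        for r in results
                    ],
                }
            )
        _write_load(load_tables, out_dir / "load.tsv")
        report["stages"].append(f"load:{model}")
        report["load"] = {"model": model, "tables": load_tables}
    else:
        report["warnings"].append("no gene sets supplied; load stage skipped")

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


@_stage("inputs")
def _load_inputs(config, report, out_dir):
    if "simulate" in config:
        sim_spec = config["simulate"]
        sim_cfg = simulate.SimConfig(seed=config.get("seed", 0))
        for key, value in sim_spec.items():
            if key in ("out_dir",):
                continue
            sim_cfg = dataclasses.replace(sim_cfg, **{key: value})
        out = simulate.generate(sim_cfg, sim_spec.get("out_dir"))
        return out.subjects, out.variants, out.gene_sets
    inputs = config.get("inputs", {})
    if "cohort" not in inputs or "variants" not in inputs:
        raise PipelineError(
            "stage 'inputs' failed: config needs either a 'simulate' block "
            "or 'inputs' naming cohort and variants files"
        )
    cohort = read_cohort(inputs["cohort"])
    variants = read_variants(
        inputs["variants"], dialect=inputs.get("dialect", "flat_tsv"),
        cohort=cohort,
    )
    gene_sets = []
    if "gene_sets" in inputs:
        gene_sets = read_gene_sets(
            inputs["gene_sets"], format=inputs.get("gene_sets_format", "gmt")
        )
    return cohort, variants, gene_sets


@_stage("selection")
def _run_selection(cohort, rule):
    labels = {}
    for s in cohort:
        if s.hfli_production is None:
            labels[s.subject_id] = "unclassified"
        else:
            labels[s.subject_id] = selection.classify_rhld(s, rule)
    return labels


@_stage("filtering")
def _run_filters(variants, cohort, fcfg):
    n_in = len(variants)
    after_severity = filtering.severity_filter(variants)
    batch_map = {s.subject_id: s.batch for s in cohort}
    after_presence = filtering.cohort_presence_filter(
        after_severity, batch_map, fcfg
    )
    counts = {
        "variants_in": n_in,
        "after_severity": len(after_severity),
        "after_cohort_presence": len(after_presence),
    }
    return after_presence, counts


@_stage("matrix")
def _build_matrix(cohort, filtered, model, fcfg):
    return filtering.build_matrix(cohort, filtered, model, fcfg)


def _write_burden(results, path):
    with open(path, "w") as fh:
        fh.write("gene\ta\tb\tc\td\tp_one_tailed\tany_control_carrier\n")
        for r in results:
            fh.write(
                f"{r.gene}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t"
                f"{r.p_one_tailed!r}\t{int(r.any_control_carrier)}\n"
            )


def _write_load(load_tables, path):
    with open(path, "w") as fh:
        fh.write(
            "contrast\tset\tset_size\tk_test\tn_total\tp0\tp_binomial\n"
        )
        for table in load_tables:
            c = table["contrast"]
            tag = "{}_vs_{}{}{}".format(
                c["test_group"], c["comparison_group"],
                f"_{c['comparison_handedness']}" if c["comparison_handedness"] else "",
                f"_{c['batch']}" if c["batch"] else "",
            )
            for r in table["results"]:
                fh.write(
                    f"{tag}\t{r['set']}\t{r['size']}\t{r['k_test']}\t"
                    f"{r['n_total']}\t{r['p0']}\t{r['p']!r}\n"
                )
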