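"""End-to-end orchestration: filter -> burden -> signatures -> BRCA ->
metagene -> pathways -> survival, with per-stage TSV outputs and a JSON
summary.

Every tunable threshold is a named config key with the pipeline's default
value; outputs contain no timestamps, so identical configs and seeds give
byte-identical results.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as bd
from . import filtering as flt
from . import io as tio
from . import metagene as mg
from . import pathways as pw
from . import signatures as sg
from . import stats as st
from . import brca as brca_mod

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "min_ratio": 5.0,
    "germline_band": [0.45, 0.55],
    "normal_maf_floor": 0.01,
    "min_deleterious_votes": 3,
    "math_min_maf": 0.075,
    "clonal_max_maf": 0.6,
    "clonal_min_depth": 10,
    "k_max": 6,
    "n_restarts": 10,
    "covered_bases_10x": 30_000_000,
    "methylation_cutoff": 0.2,
    "de_p_cutoff": 0.002,
    "low_expression_fraction": 0.25,
    "n_boot": 100,
    "n_perm": 1000,
}

DEFAULT_STAGES = (
    "filter",
    "burden",
    "signatures",
    "brca",
    "metagene",
    "pathways",
    "survival",
)


class PipelineError(RuntimeError):
    pass


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _require_input(config: dict, key: str, stage: str) -> Path:
    inputs = config.get("inputs", {})
    if key not in inputs or not Path(inputs[key]).exists():
        raise PipelineError(f"stage {stage!r}: missing required input {key!r}")
    return Path(inputs[key])


def _write(df: pd.DataFrame, path: Path, created: list[Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
    created.append(path)


def run_pipeline(config, outdir=None) -> dict:
    """Run the configured stages; returns the summary dict.

    ``config`` is a YAML path or a dict with keys ``inputs`` (file paths),
    ``stages`` (list; default all), ``params`` (threshold overrides) and
    ``seed``. Partial outputs are removed if a stage fails.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    stages = list(config.get("stages", DEFAULT_STAGES))
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("out", "pipeline_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    summary: dict = {"seed": seed, "params": params, "stages": stages}
    try:
        _run_stages(config, params, stages, seed, outdir, created, summary)
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        raise
    tio.write_json(summary, outdir / "summary.json")
    with open(outdir / "run.log", "w", encoding="utf-8") as fh:
        fh.write(f"seed={seed}\nstages={','.join(stages)}\n")
        for k in sorted(params):
            fh.write(f"param {k}={params[k]}\n")
    return summary


def _run_stages(config, params, stages, seed, outdir, created, summary) -> None:
    mutations = filtered = None
    clinical = None
    expression = methylation = None

    if "filter" in stages or "burden" in stages or "signatures" in stages or \
            "brca" in stages or "pathways" in stages:
        mutations = tio.read_mutation_table(
            _require_input(config, "mutations", "filter")
        )
    if "inputs" in config and "clinical" in config["inputs"]:
        clinical = tio.read_clinical_table(config["inputs"]["clinical"])
    if "inputs" in config and "expression" in config["inputs"] and \
            Path(config["inputs"]["expression"]).exists():
        expression = tio.read_expression_matrix(config["inputs"]["expression"])
    if "inputs" in config and "methylation" in config["inputs"] and \
            Path(config["inputs"]["methylation"]).exists():
        methylation = tio.read_methylation_table(config["inputs"]["methylation"])

    if "filter" in stages:
        filtered = {}
        rows = []
        for sample_id, records in mutations.items():
            kept, decisions = flt.filter_mutations(
                records,
                min_ratio=params["min_ratio"],
                germline_band=tuple(params["germline_band"]),
                normal_maf_floor=params["normal_maf_floor"],
            )
            filtered[sample_id] = kept
            for d in decisions:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "chrom": d.record.chrom,
                        "pos": d.record.pos,
                        "gene": d.record.gene,
                        "kept": int(d.kept),
                        "reasons": ";".join(r.value for r in d.reasons),
                    }
                )
        _write(pd.DataFrame(rows), outdir / "filter_decisions.tsv", created)
        summary["filter"] = {
            "n_input": sum(len(v) for v in mutations.values()),
            "n_kept": sum(len(v) for v in filtered.values()),
        }
    else:
        filtered = mutations

    burden_frame = None
    if "burden" in stages:
        metrics = []
        assign_rows = []
        sample_ids = sorted(filtered)
        for i, sample_id in enumerate(sample_ids):
            recs = filtered[sample_id]
            b = bd.burden_metrics(
                sample_id, recs, params["covered_bases_10x"],
                min_maf=params["math_min_maf"],
            )
            k = avg_mpc = None
            try:
                decomp = bd.decompose_clones(
                    recs,
                    min_depth=params["clonal_min_depth"],
                    max_maf=params["clonal_max_maf"],
                    k_max=params["k_max"],
                    n_restarts=params["n_restarts"],
                    seed=seed + i,
                )
                k, avg_mpc = decomp.k, decomp.avg_mutations_per_clone
                used = [
                    m for m in recs
                    if m.depth >= params["clonal_min_depth"]
                    and m.maf < params["clonal_max_maf"]
                ]
                for m, a in zip(used, decomp.assignments):
                    assign_rows.append(
                        {
                            "sample_id": sample_id,
                            "chrom": m.chrom,
                            "pos": m.pos,
                            "maf": m.maf,
                            "clone": a,
                        }
                    )
            except bd.DecompositionUnavailableError as exc:
                logger.info("%s: %s", sample_id, exc)
            metrics.append((b, k, avg_mpc))
        bd.assign_cmb([m[0] for m in metrics])
        burden_frame = pd.DataFrame(
            [
                {
                    "sample_id": b.sample_id,
                    "n_mutations": len(filtered[b.sample_id]),
                    "mutation_rate": b.mutation_rate,
                    "math_score": "." if b.math_score is None else b.math_score,
                    "k": "." if k is None else k,
                    "avg_mutations_per_clone": "." if a is None else a,
                    "cmb": b.cmb.value if b.cmb else ".",
                }
                for b, k, a in metrics
            ]
        )
        _write(burden_frame, outdir / "burden.tsv", created)
        _write(pd.DataFrame(assign_rows), outdir / "clone_assignments.tsv", created)
        summary["burden"] = {
            "n_samples": len(metrics),
            "cmb_counts": burden_frame["cmb"].value_counts().to_dict(),
        }

    if "signatures" in stages:
        ref_path = _require_input(config, "signature_reference", "signatures")
        reference = tio.read_signature_reference(ref_path)
        fits = []
        for sample_id in sorted(filtered):
            counts = sg.context_counts(filtered[sample_id])
            if counts.sum() == 0:
                continue
            fits.append(sg.fit_signatures(counts, reference, sample_id=sample_id))
        sig_frame = sg.fit_table(fits)
        _write(sig_frame, outdir / "signatures.tsv", created)
        summary["signatures"] = {
            "n_fitted": len(fits),
            "dominant_counts": sig_frame["dominant"].value_counts().to_dict()
            if len(fits)
            else {},
        }

    brca_calls = None
    if "brca" in stages:
        if methylation is None:
            logger.warning(
                "brca stage: no methylation input; methylation evidence omitted"
            )
        if expression is None:
            logger.warning(
                "brca stage: no expression input; calls restricted to "
                "mutation evidence (expression rule skipped)"
            )
            calls = [
                brca_mod.BrcaCall(
                    sample_id=s,
                    brca1_deficient=any(
                        m.gene == "BRCA1" and brca_mod.is_deleterious_brca_mutation(m)
                        for m in recs
                    ),
                    brca2_deficient=any(
                        m.gene == "BRCA2" and brca_mod.is_deleterious_brca_mutation(m)
                        for m in recs
                    ),
                    brca_deficient=any(
                        m.gene in brca_mod.BRCA_GENES
                        and brca_mod.is_deleterious_brca_mutation(m)
                        for m in recs
                    ),
                    threshold_brca1=None,
                    threshold_brca2=None,
                    rationale={},
                )
                for s, recs in sorted(filtered.items())
            ]
            thresholds = {"BRCA1": None, "BRCA2": None}
        else:
            calls, thresholds = brca_mod.call_cohort(filtered, expression, methylation)
        brca_calls = pd.Series(
            {c.sample_id: c.brca_deficient for c in calls}, name="brca_deficient"
        )
        _write(
            pd.DataFrame(
                [
                    {
                        "sample_id": c.sample_id,
                        "brca1_deficient": int(c.brca1_deficient),
                        "brca2_deficient": int(c.brca2_deficient),
                        "brca_deficient": int(c.brca_deficient),
                        "rationale_brca1": ";".join(c.rationale.get("BRCA1", [])) or ".",
                        "rationale_brca2": ";".join(c.rationale.get("BRCA2", [])) or ".",
                    }
                    for c in calls
                ]
            ),
            outdir / "brca_calls.tsv",
            created,
        )
        summary["brca"] = {
            "n_deficient": int(brca_calls.sum()),
            "n_samples": int(len(brca_calls)),
            "thresholds": {k: v for k, v in thresholds.items()},
        }

    metagene_calls = None
    if "metagene" in stages and expression is None:
        logger.warning("metagene stage skipped: no expression input")
        stages = [s for s in stages if s != "metagene"]
    if "metagene" in stages:
        if brca_calls is None:
            raise PipelineError("stage 'metagene': requires the brca stage")
        signature = mg.differential_expression(
            expression,
            brca_calls.astype(int),
            p_cutoff=params["de_p_cutoff"],
            low_expression_fraction=params["low_expression_fraction"],
        )
        sig_rows = [
            {"gene": g, "direction": "up", "p": signature.p_values.get(g)}
            for g in sorted(signature.up_genes)
        ] + [
            {"gene": g, "direction": "down", "p": signature.p_values.get(g)}
            for g in sorted(signature.down_genes)
        ]
        _write(pd.DataFrame(sig_rows), outdir / "metagene_signature.tsv", created)
        if signature.up_genes and signature.down_genes:
            scores = mg.metagene_score(expression, signature)
            metagene_calls = scores.calls == "high"
            perf = mg.classifier_performance(metagene_calls, brca_calls)
            _write(
                pd.DataFrame(
                    {
                        "sample_id": scores.scores.index,
                        "score": scores.scores.values,
                        "call": scores.calls.values,
                    }
                ),
                outdir / "metagene_scores.tsv",
                created,
            )
            summary["metagene"] = {
                "n_up": len(signature.up_genes),
                "n_down": len(signature.down_genes),
                "sensitivity_vs_brca": perf[0],
                "specificity_vs_brca": perf[1],
            }
        else:
            logger.warning("metagene: empty up or down gene set; scoring skipped")
            summary["metagene"] = {
                "n_up": len(signature.up_genes),
                "n_down": len(signature.down_genes),
            }

    if "pathways" in stages:
        gmt_path = _require_input(config, "pathways", "pathways")
        if clinical is None:
            raise PipelineError("stage 'pathways': missing required input 'clinical'")
        collection = tio.read_gene_sets(gmt_path)
        high_impact = {
            s: flt.select_high_impact(
                recs, min_deleterious_votes=params["min_deleterious_votes"]
            )
            for s, recs in filtered.items()
        }
        matrix = pw.pathway_mutation_matrix(high_impact, collection)
        response = pd.Series(
            {
                s: clinical[s].response.value == "pCR"
                for s in matrix.index
                if s in clinical and clinical[s].response is not None
            }
        )
        matrix = matrix.loc[response.index]
        results = pw.associate_response(matrix, response)
        boot = pw.bootstrap_robustness(
            matrix, response, n_boot=params["n_boot"], seed=seed
        )
        perm = pw.permutation_significance(
            matrix, response, n_perm=params["n_perm"], seed=seed
        )
        for r in results:
            r.bootstrap_frequency = float(boot[r.pathway])
            r.p_permutation = float(perm.loc[r.pathway, "p_permutation"])
            r.p_permutation_fwer = float(perm.loc[r.pathway, "p_permutation_fwer"])
            r.n_boot, r.n_perm, r.seed = params["n_boot"], params["n_perm"], seed
        table = pw.association_table(results)
        _write(table, outdir / "pathway_associations.tsv", created)
        summary["pathways"] = {
            "n_pathways": len(results),
            "n_nominal": int((table["p_fisher"] < 0.05).sum()),
        }

    if "survival" in stages:
        if clinical is None:
            raise PipelineError("stage 'survival': missing required input 'clinical'")
        surv = {}
        groups = {}
        if brca_calls is not None:
            groups["brca_deficient"] = brca_calls
        if metagene_calls is not None:
            groups["metagene_high"] = metagene_calls
        for name, labels in groups.items():
            ids = [
                s for s in labels.index
                if s in clinical and clinical[s].os_time is not None
            ]
            times = np.array([clinical[s].os_time for s in ids])
            events = np.array([bool(clinical[s].os_event) for s in ids])
            lab = labels.loc[ids].to_numpy(dtype=bool)
            if lab.any() and not lab.all():
                chi2, p = st.logrank_test(lab, times, events)
                surv[name] = {"chi2": chi2, "p": p, "n": len(ids)}
        summary["survival"] = surv


def summary_path(outdir) -> Path:
    return Path(outdir) / "summary.json"
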