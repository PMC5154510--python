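"""Readers and writers for the tab-delimited formats the pipeline consumes.

All files are UTF-8, tab-delimited with a header row first; lines starting
with ``#`` are comments (the synthetic-cohort writers use one to embed the
generating seed). Numeric fields accept plain decimal notation only, so
parsing is locale-independent.

Mutation tables follow a MAF-like column dictionary (see
``docs/formats.md``): required columns ``sample_id, chrom, pos, ref_allele,
alt_allele, gene, variant_class, alt_count, ref_count``; optional columns
``maf`` (computed from counts when absent), ``trinucleotide_context``, one
ternary column per impact predictor (``phylop, sift, polyphen2,
mutationtaster, lrt`` with values D/T/.), population-database flags
(``dbsnp, esp, thousand_genomes, exac`` as 0/1), ``cosmic_recurrence``,
``clinvar_flag``, ``pooled_normal_maf``, ``rna_maf``.
"""

from __future__ import annotations

import json
from importlib.resources import files
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    IMPACT_PREDICTORS,
    POPULATION_DBS,
    ClinicalRecord,
    ExpressionMatrix,
    FormatError,
    ImpactCall,
    MethylationTable,
    MutationRecord,
    PathwayCollection,
    Response,
    SignatureReference,
    VariantClass,
)
from .contexts import CONTEXTS_96

MUTATION_REQUIRED_COLUMNS = (
    "sample_id",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "gene",
    "variant_class",
    "alt_count",
    "ref_count",
)

_MISSING = {"", ".", "NA", "nan"}


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False, **kwargs
    )


def _opt_float(value: str) -> float | None:
    return None if value in _MISSING else float(value)


def read_mutation_table(path, dialect: str = "maf_like") -> dict[str, list[MutationRecord]]:
    """Read a MAF-like mutation TSV, returning records grouped per sample.

    MAF is computed from the read counts when the column is absent or
    blank. Optional annotation columns default to missing.
    """
    if dialect != "maf_like":
        raise FormatError(f"unknown mutation-table dialect: {dialect!r}")
    path = Path(path)
    df = _read_tsv(path)
    missing = [c for c in MUTATION_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    by_sample: dict[str, list[MutationRecord]] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            alt_count = int(row["alt_count"])
            ref_count = int(row["ref_count"])
            pos = int(row["pos"])
        except ValueError as exc:
            raise FormatError(
                f"{path.name}, line {line_no}: non-integer count/position ({exc})"
            ) from None
        maf_str = str(row.get("maf", ""))
        if maf_str in _MISSING:
            depth = alt_count + ref_count
            maf = alt_count / depth if depth > 0 else 0.0
        else:
            maf = float(maf_str)
        impact_calls = {
            p: ImpactCall(row[p]) if row.get(p, ".") not in _MISSING else ImpactCall.MISSING
            for p in IMPACT_PREDICTORS
            if p in df.columns
        }
        population_flags = {
            db: row[db] in ("1", "True", "true")
            for db in POPULATION_DBS
            if db in df.columns
        }
        context = row.get("trinucleotide_context", "")
        record = MutationRecord(
            sample_id=row["sample_id"],
            chrom=row["chrom"],
            pos=pos,
            ref_allele=row["ref_allele"],
            alt_allele=row["alt_allele"],
            gene=row["gene"],
            variant_class=VariantClass(row["variant_class"]),
            alt_count=alt_count,
            ref_count=ref_count,
            maf=maf,
            trinucleotide_context=None if context in _MISSING else context,
            impact_calls=impact_calls,
            population_flags=population_flags,
            cosmic_recurrence=int(row["cosmic_recurrence"])
            if row.get("cosmic_recurrence", "") not in _MISSING
            else 0,
            clinvar_flag=row.get("clinvar_flag", "0") in ("1", "True", "true"),
            pooled_normal_maf=_opt_float(str(row.get("pooled_normal_maf", ""))),
            rna_maf=_opt_float(str(row.get("rna_maf", ""))),
        )
        by_sample.setdefault(record.sample_id, []).append(record)
    return by_sample


def write_mutation_table(records, path, seed: int | None = None) -> None:
    """Write mutation records (iterable or per-sample dict) as MAF-like TSV."""
    if isinstance(records, dict):
        records = [r for recs in records.values() for r in recs]
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref_allele": r.ref_allele,
            "alt_allele": r.alt_allele,
            "gene": r.gene,
            "variant_class": r.variant_class.value,
            "alt_count": r.alt_count,
            "ref_count": r.ref_count,
            "maf": f"{r.maf:.6g}",
            "trinucleotide_context": r.trinucleotide_context or ".",
            "cosmic_recurrence": r.cosmic_recurrence,
            "clinvar_flag": int(r.clinvar_flag),
            "pooled_normal_maf": "."
            if r.pooled_normal_maf is None
            else f"{r.pooled_normal_maf:.6g}",
            "rna_maf": "." if r.rna_maf is None else f"{r.rna_maf:.6g}",
        }
        for p in IMPACT_PREDICTORS:
            row[p] = r.impact_calls.get(p, ImpactCall.MISSING).value
        for db in POPULATION_DBS:
            row[db] = int(r.population_flags.get(db, False))
        rows.append(row)
    columns = (
        list(MUTATION_REQUIRED_COLUMNS)
        + ["maf", "trinucleotide_context"]
        + list(IMPACT_PREDICTORS)
        + list(POPULATION_DBS)
        + ["cosmic_recurrence", "clinvar_flag", "pooled_normal_maf", "rna_maf"]
    )
    df = pd.DataFrame(rows, columns=columns)
    _write_with_seed(df, path, seed, index=False)


def _write_with_seed(df: pd.DataFrame, path, seed, index: bool, index_label=None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label,
                  float_format="%.10g", lineterminator="\n")


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene symbols)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError("expression matrix needs a gene column and >= 1 sample")
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from None
    return ExpressionMatrix(values)


def write_expression_matrix(matrix: ExpressionMatrix, path, seed=None) -> None:
    _write_with_seed(matrix.values, path, seed, index=True, index_label="gene")


def read_methylation_table(path) -> MethylationTable:
    df = _read_tsv(path)
    probe_col = df.columns[0]
    df = df.set_index(probe_col)
    df = df.replace(list(_MISSING), np.nan)
    try:
        betas = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric beta value: {exc}") from None
    return MethylationTable(betas)


def write_methylation_table(table: MethylationTable, path, seed=None) -> None:
    _write_with_seed(table.betas, path, seed, index=True, index_label="probe")


def read_clinical_table(path) -> dict[str, ClinicalRecord]:
    """Read the clinical TSV (sample_id, response, optional survival columns).

    ``response`` may be a binary class (pCR/RD) or a residual-cancer-burden
    class; any non-pCR class binarizes to RD.
    """
    df = _read_tsv(path)
    if "sample_id" not in df.columns or "response" not in df.columns:
        raise FormatError("clinical table requires sample_id and response columns")
    records: dict[str, ClinicalRecord] = {}
    for _, row in df.iterrows():
        raw = row["response"]
        rcb = raw if raw in ("pCR", "RCB-I", "RCB-II", "RCB-III", "RD") else None
        response = None
        if raw not in _MISSING:
            response = Response.PCR if raw == "pCR" else Response.RD
        os_time = _opt_float(str(row.get("os_time", "")))
        os_event_raw = str(row.get("os_event", ""))
        os_event = None if os_event_raw in _MISSING else os_event_raw in ("1", "True", "true")
        records[row["sample_id"]] = ClinicalRecord(
            sample_id=row["sample_id"],
            response=response,
            rcb_class=rcb,
            os_time=os_time,
            os_event=os_event,
            stage=row.get("stage") or None,
            grade=row.get("grade") or None,
        )
    return records


def write_clinical_table(records, path, seed=None) -> None:
    if isinstance(records, dict):
        records = list(records.values())
    rows = [
        {
            "sample_id": r.sample_id,
            "response": r.rcb_class or (r.response.value if r.response else "."),
            "os_time": "." if r.os_time is None else f"{r.os_time:.6g}",
            "os_event": "." if r.os_event is None else int(r.os_event),
            "stage": r.stage or ".",
            "grade": r.grade or ".",
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    _write_with_seed(df, path, seed, index=False)


def read_gene_sets(path) -> PathwayCollection:
    """Read a GMT file: name, description, then gene symbols."""
    mapping: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {line_no}: expected >= 3 tab-separated fields"
                )
            name, _desc, *genes = fields
            mapping[name] = {g for g in genes if g}
    return PathwayCollection(mapping)


def write_gene_sets(collection: PathwayCollection, path, seed=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for name in collection:
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_signature_reference(path) -> SignatureReference:
    """Read a 96-row signature loading TSV (first column context labels)."""
    df = _read_tsv(path)
    context_col = df.columns[0]
    df = df.set_index(context_col)
    if df.shape[0] != 96:
        raise FormatError(
            f"signature reference must have 96 context rows, got {df.shape[0]}"
        )
    try:
        loadings = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric signature loading: {exc}") from None
    if set(loadings.index) != set(CONTEXTS_96):
        raise FormatError("signature reference rows must be the canonical 96 contexts")
    return SignatureReference(loadings)


def write_signature_reference(reference: SignatureReference, path, seed=None) -> None:
    _write_with_seed(reference.loadings, path, seed, index=True, index_label="context")


def mdacc_clinical_path() -> Path:
    """Bundled discovery-cohort clinical table (29 samples, RCB classes)."""
    return Path(str(files("tnbcsens").joinpath("data/mdacc_clinical.tsv")))


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            obj, fh, indent=2, sort_keys=True,
            default=lambda o: o.item() if hasattr(o, "item") else str(o),
        )
        fh.write("\n")
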