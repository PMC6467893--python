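"""Readers and writers for the standard formats the pipeline consumes.

Formats: GMT gene sets (with a category sidecar TSV), FPKM expression TSV,
per-caller VCF, SEG segmented copy number, clinical TSV, fusion-candidate
TSV and fusion knowledge TSVs. Every writer round-trips exactly through the
matching reader.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CLINICAL_COLUMNS,
    SEG_COLUMNS,
    ClinicalTable,
    ExpressionMatrix,
    FusionCandidate,
    FusionKnowledge,
    SegmentTable,
    SignatureCollection,
    ValidationError,
    VariantCall,
    normalize_stage,
)

logger = logging.getLogger("tmeprofiler")


# ---------------------------------------------------------------- gene sets

def read_gene_sets(path, categories: Optional[dict[str, str] | str | Path] = None) -> SignatureCollection:
    """Parse a GMT file (name TAB description TAB gene ...) into a collection.

    ``categories`` maps signature name -> adaptive/innate/other, either as a
    dict or as a path to a two-column TSV sidecar. Signatures absent from the
    mapping default to category "other".
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT line needs name, description and >=1 gene"
                )
            name = parts[0]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ValidationError(f"{path}: line {lineno}: signature {name!r} has no genes")
            if name in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate signature name {name!r}")
            sets[name] = genes
    if categories is None:
        cat = {name: "other" for name in sets}
    elif isinstance(categories, dict):
        cat = {name: categories.get(name, "other") for name in sets}
    else:
        side = pd.read_csv(categories, sep="\t", header=None, names=["name", "category"])
        mapping = dict(zip(side["name"], side["category"]))
        cat = {name: mapping.get(name, "other") for name in sets}
    return SignatureCollection(signatures=sets, category=cat)


def write_gene_sets(collection: SignatureCollection, gmt_path, categories_path=None) -> None:
    with open(gmt_path, "w") as fh:
        for name, genes in collection.signatures.items():
            fh.write("\t".join([name, "na"] + sorted(genes)) + "\n")
    if categories_path is not None:
        with open(categories_path, "w") as fh:
            for name in collection.signatures:
                fh.write(f"{name}\t{collection.category[name]}\n")


# --------------------------------------------------------------- expression

def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV with gene ids in the first column and sample-id header.

    Duplicate gene rows are collapsed by per-sample maximum (logged);
    non-numeric cells and negative values are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell {df.iloc[g, s]!r} at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    if numeric.index.duplicated().any():
        dups = numeric.index[numeric.index.duplicated()].unique().tolist()
        logger.warning("collapsing %d duplicated gene id(s) by max: %s", len(dups), dups[:5])
        numeric = numeric.groupby(level=0, sort=False).max()
    numeric.index.name = None  # canonical in-memory form: unnamed axes
    numeric.columns.name = None
    return ExpressionMatrix(values=numeric)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


# --------------------------------------------------------------------- VCF

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID={effect_key},Number=1,Type=String,Description="Variant effect class">
##INFO=<ID={popdb_key},Number=.,Type=String,Description="Population databases listing this variant">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID={depth_key},Number=R,Type=Integer,Description="Allelic depths (ref, alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_variant_calls(
    calls: Sequence[VariantCall],
    path,
    *,
    depth_key: str = "AD",
    effect_key: str = "EFF",
    popdb_key: str = "PDB",
) -> None:
    """Write one caller's calls for one sample as a minimal VCF 4.2 file."""
    samples = {c.sample_id for c in calls}
    if len(samples) != 1:
        raise ValidationError(f"one VCF per sample expected, got samples {sorted(samples)}")
    sample = samples.pop()
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(
            effect_key=effect_key, popdb_key=popdb_key, depth_key=depth_key, sample=sample,
        ))
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
            info = f"{effect_key}={c.effect_class}"
            if c.popdb_flags:
                info += f";{popdb_key}={','.join(sorted(c.popdb_flags))}"
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t.\t{info}\t"
                f"GT:{depth_key}\t0/1:{max(0, 30 - c.supporting_reads)},{c.supporting_reads}\n"
            )


def read_variant_calls(
    paths_by_caller: dict[str, str | Path],
    *,
    depth_key: str = "AD",
    effect_key: str = "EFF",
    popdb_key: str = "PDB",
) -> list[VariantCall]:
    """Read one VCF per caller into a flat list of VariantCall records.

    Supporting reads come from the ALT entry of the ``depth_key`` FORMAT
    field (falling back to an INFO field of the same name); records lacking
    it are kept with 0 supporting reads and a warning so the downstream
    minimum-reads filter removes them deterministically.
    """
    from cyvcf2 import VCF

    calls: list[VariantCall] = []
    for caller_id, path in paths_by_caller.items():
        vcf = VCF(str(path))
        if len(vcf.samples) != 1:
            raise ValidationError(f"{path}: expected exactly one sample column")
        sample = vcf.samples[0]
        for rec in vcf:
            for alt in rec.ALT:
                reads = _extract_alt_depth(rec, depth_key)
                if reads is None:
                    logger.warning(
                        "%s: %s:%s lacks depth key %r; supporting_reads set to 0",
                        path, rec.CHROM, rec.POS, depth_key,
                    )
                    reads = 0
                effect = rec.INFO.get(effect_key) or "other"
                popdb_raw = rec.INFO.get(popdb_key)
                popdb = frozenset(popdb_raw.split(",")) if popdb_raw else frozenset()
                calls.append(VariantCall(
                    sample_id=sample, chrom=rec.CHROM, pos=rec.POS,
                    ref=rec.REF, alt=alt, caller_id=caller_id,
                    supporting_reads=int(reads), effect_class=effect,
                    popdb_flags=popdb,
                ))
        vcf.close()
    return calls


def _extract_alt_depth(rec, depth_key: str) -> Optional[int]:
    try:
        fmt = rec.format(depth_key)
    except KeyError:
        fmt = None
    if fmt is not None:
        arr = np.asarray(fmt)[0]
        if arr.size >= 2 and arr[1] >= 0:
            return int(arr[1])
    val = rec.INFO.get(depth_key)
    if val is not None:
        return int(val)
    return None


# --------------------------------------------------------------------- SEG

def read_seg(path) -> SegmentTable:
    df = pd.read_csv(path, sep="\t", header=0)
    if list(df.columns) != SEG_COLUMNS:
        raise ValidationError(f"{path}: expected SEG columns {SEG_COLUMNS}, got {list(df.columns)}")
    df = df.astype({"sample": str, "chrom": str, "start": int, "end": int,
                    "log2_ratio": float, "n_probes": int})
    return SegmentTable(table=df)


def write_seg(segments: SegmentTable, path) -> None:
    segments.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- clinical

def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: clinical table missing columns {missing}")
    df = df[CLINICAL_COLUMNS].copy()
    df["stage"] = df["stage"].map(normalize_stage)
    df = df.astype({"sample": str, "histology": str, "age": float, "sex": str,
                    "smoking": str, "os_days": float, "os_event": int, "treatment": str})
    return ClinicalTable(table=df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- fusions

FUSION_COLUMNS = ["sample", "gene5", "gene3", "junction_reads", "spanning_mates", "callers"]


def read_fusion_candidates(path) -> list[FusionCandidate]:
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in FUSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: fusion table missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(FusionCandidate(
            sample_id=str(row.sample), gene5=str(row.gene5), gene3=str(row.gene3),
            junction_reads=int(row.junction_reads), spanning_mates=int(row.spanning_mates),
            callers=frozenset(str(row.callers).split(",")),
        ))
    return out


def write_fusion_candidates(candidates: Iterable[FusionCandidate], path) -> None:
    rows = [{
        "sample": c.sample_id, "gene5": c.gene5, "gene3": c.gene3,
        "junction_reads": c.junction_reads, "spanning_mates": c.spanning_mates,
        "callers": ",".join(sorted(c.callers)),
    } for c in candidates]
    pd.DataFrame(rows, columns=FUSION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fusion_knowledge(canonical_path=None, census_path=None) -> FusionKnowledge:
    """Canonical pairs from a two-column TSV; census genes one per line."""
    canonical = frozenset()
    census = frozenset()
    if canonical_path is not None:
        df = pd.read_csv(canonical_path, sep="\t", header=None, names=["geneA", "geneB"])
        canonical = frozenset(frozenset((a, b)) for a, b in zip(df["geneA"], df["geneB"]))
    if census_path is not None:
        with open(census_path) as fh:
            census = frozenset(line.strip() for line in fh if line.strip())
    return FusionKnowledge(canonical_fusions=canonical, census_genes=census)


# ------------------------------------------------------------ cohort dump


def write_cohort(cohort, outdir) -> None:
    """Write a synthetic cohort to standard-format files under ``outdir``.

    Layout: expression.tsv, signatures.gmt (+ signature_categories.tsv),
    clinical.tsv, segments.seg, fusions.tsv, canonical_fusions.tsv,
    census_genes.txt, germline_keys.tsv, pon_keys.tsv, truth.tsv,
    enrichment_truth.tsv and per-sample, per-caller VCFs under vcf/.
    """
    from collections import defaultdict

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(cohort.expression, out / "expression.tsv")
    write_gene_sets(cohort.signatures, out / "signatures.gmt",
                    out / "signature_categories.tsv")
    write_clinical(cohort.clinical, out / "clinical.tsv")
    write_seg(cohort.segments, out / "segments.seg")
    write_fusion_candidates(cohort.fusion_candidates, out / "fusions.tsv")
    with open(out / "canonical_fusions.tsv", "w") as fh:
        for pair in sorted(tuple(sorted(p)) for p in cohort.knowledge.canonical_fusions):
            fh.write("\t".join(pair) + "\n")
    with open(out / "census_genes.txt", "w") as fh:
        for g in sorted(cohort.knowledge.census_genes):
            fh.write(g + "\n")
    write_variant_keys(cohort.germline_keys, out / "germline_keys.tsv")
    write_variant_keys(cohort.pon_keys, out / "pon_keys.tsv")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    cohort.enrichment_truth.to_csv(out / "enrichment_truth.tsv", sep="\t",
                                   index_label="sample")
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    by_file: dict[tuple[str, str], list] = defaultdict(list)
    for c in cohort.variant_calls:
        by_file[(c.sample_id, c.caller_id)].append(c)
    for (sample, caller), calls in sorted(by_file.items()):
        write_variant_calls(calls, vcf_dir / f"{sample}.{caller}.vcf")


# --------------------------------------------------------- key lists (TSV)

def read_variant_keys(path, with_sample: bool = True) -> frozenset:
    """Read a variant key TSV: [sample] chrom pos ref alt."""
    names = (["sample"] if with_sample else []) + ["chrom", "pos", "ref", "alt"]
    df = pd.read_csv(path, sep="\t", header=None, names=names)
    if with_sample:
        return frozenset(
            (str(r.sample), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in df.itertuples(index=False)
        )
    return frozenset(
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)) for r in df.itertuples(index=False)
    )


def write_variant_keys(keys: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        for key in sorted(keys):
            fh.write("\t".join(str(x) for x in key) + "\n")
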