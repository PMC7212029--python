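"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are tab-separated UTF-8 with Unix newlines.  ``#``
prefixed lines are comments, except the mandatory ``#space=`` declaration
at the top of an expression matrix.  Gene symbols are matched
case-sensitively after whitespace trimming; no alias resolution is done
for genes.  Variant-class tokens, by contrast, pass through an alias
table covering the common MAF spellings so real MAF extracts load
without preprocessing.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohort import (
    EXPRESSION_SPACES,
    CohortBundle,
    ExpressionMatrix,
    FastqRead,
    GeneSetCollection,
    MethylationMatrix,
    MutationRecord,
    SampleAnnotation,
)
from .errors import FormatError

# Common MAF spellings -> closed variant-class vocabulary.
VARIANT_CLASS_ALIASES = {
    "missense": "missense",
    "missense_mutation": "missense",
    "nonsense": "nonsense",
    "nonsense_mutation": "nonsense",
    "frameshift": "frameshift",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "frameshift_deletion": "frameshift",
    "frameshift_insertion": "frameshift",
    "splice_site": "splice_site",
    "splice_region": "splice_site",
    "inframe": "inframe",
    "in_frame_del": "inframe",
    "in_frame_ins": "inframe",
    "silent": "silent",
    "synonymous": "silent",
    "other": "other",
}

_FLOAT_FMT = "%.12g"  # 12 significant digits: exact for counts, round-trip safe


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a gene x sample TSV whose first comment block declares the
    expression space (``#space=counts|log_cpm|log_arbitrary``)."""
    path = Path(path)
    space: Optional[str] = None
    data_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if stripped.startswith("space="):
                    space = stripped.split("=", 1)[1].strip()
                continue
            data_lines.append(line)
    if space is None:
        raise FormatError(f"{path}: missing required '#space=' declaration")
    if space not in EXPRESSION_SPACES:
        raise FormatError(f"{path}: unknown expression space {space!r}")

    frame = pd.read_csv(
        _io.StringIO("".join(data_lines)), sep="\t", index_col=0, dtype=str
    )
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = frame.columns.astype(str).str.strip()
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if converted.isna().any():
            gene = frame.index[converted.isna()][0]
            raise FormatError(
                f"{path}: non-numeric value {frame.loc[gene, col]!r} "
                f"at gene {gene!r}, sample {col!r}"
            )
        numeric[col] = converted
    numeric.index.name = None
    numeric.columns.name = None
    if space == "counts":
        arr = numeric.to_numpy()
        if (arr < 0).any() or not np.array_equal(arr, np.round(arr)):
            raise FormatError(f"{path}: counts must be nonnegative integers")
        numeric = numeric.astype(np.int64)
    return ExpressionMatrix(values=numeric, space=space)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#space={matrix.space}\n")
        matrix.values.to_csv(
            fh, sep="\t", index_label="gene", float_format=_FLOAT_FMT,
            lineterminator="\n",
        )


# ---------------------------------------------------------------------------
# mutation tables

def read_mutations_tsv(path) -> list[MutationRecord]:
    """Read a minimal MAF-like table with columns sample_id, gene,
    variant_class, protein_position (position may be empty)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["sample_id", "gene", "variant_class", "protein_position"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    records: list[MutationRecord] = []
    for row in frame.itertuples(index=False):
        token = str(row.variant_class).strip().lower()
        if token not in VARIANT_CLASS_ALIASES:
            raise FormatError(
                f"{path}: unknown variant_class {row.variant_class!r} "
                f"for sample {row.sample_id!r}"
            )
        pos_raw = row.protein_position
        position: Optional[int] = None
        if pos_raw is not None and str(pos_raw).strip() not in ("", "nan"):
            try:
                position = int(float(pos_raw))
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer protein_position {pos_raw!r}"
                ) from None
        records.append(
            MutationRecord(
                sample_id=str(row.sample_id).strip(),
                gene=str(row.gene).strip(),
                variant_class=VARIANT_CLASS_ALIASES[token],
                protein_position=position,
            )
        )
    return records


def write_mutations_tsv(records: Iterable[MutationRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "gene": r.gene,
            "variant_class": r.variant_class,
            "protein_position": "" if r.protein_position is None else r.protein_position,
        }
        for r in records
    ]
    frame = pd.DataFrame(
        rows, columns=["sample_id", "gene", "variant_class", "protein_position"]
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# annotation

def read_annotation_tsv(path) -> list[SampleAnnotation]:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("unknown")
    required = ["sample_id", "cohort", "cimp_status", "cms"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out = []
    for row in frame.itertuples(index=False):
        try:
            out.append(
                SampleAnnotation(
                    sample_id=row.sample_id.strip(),
                    cohort=row.cohort.strip(),
                    cimp_status=row.cimp_status.strip(),
                    cms=row.cms.strip(),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return out


def write_annotation_tsv(annotation: Iterable[SampleAnnotation], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "sample_id": a.sample_id,
                "cohort": a.cohort,
                "cimp_status": a.cimp_status,
                "cms": a.cms,
            }
            for a in annotation
        ],
        columns=["sample_id", "cohort", "cimp_status", "cms"],
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# methylation

def read_methylation(beta_path, probe_map_path) -> MethylationMatrix:
    beta = pd.read_csv(beta_path, sep="\t", comment="#", index_col=0)
    beta.index = beta.index.astype(str).str.strip()
    arr = beta.to_numpy()
    if ((arr < 0) | (arr > 1)).any():
        probe = beta.index[((beta < 0) | (beta > 1)).any(axis=1)][0]
        raise FormatError(f"{beta_path}: beta out of [0,1] at probe {probe!r}")
    pm = pd.read_csv(probe_map_path, sep="\t", comment="#", dtype=str)
    if not {"probe", "gene"}.issubset(pm.columns):
        raise FormatError(f"{probe_map_path}: need columns probe, gene")
    probe_map = pd.Series(
        pm["gene"].str.strip().to_numpy(), index=pm["probe"].str.strip(), name="gene"
    )
    return MethylationMatrix(beta=beta, probe_map=probe_map)


def write_methylation(meth: MethylationMatrix, beta_path, probe_map_path) -> None:
    with Path(beta_path).open("w", encoding="utf-8", newline="\n") as fh:
        meth.beta.to_csv(
            fh, sep="\t", index_label="probe", float_format=_FLOAT_FMT,
            lineterminator="\n",
        )
    frame = pd.DataFrame(
        {"probe": meth.probe_map.index, "gene": meth.probe_map.values}
    )
    frame.to_csv(probe_map_path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, name TAB description TAB genes."""
    path = Path(path)
    collection = GeneSetCollection()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, description = fields[0].strip(), fields[1].strip()
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            try:
                collection.add(name, description, genes)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for name in collection:
            description, genes = collection.sets[name]
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# reads (FASTQ) and junction libraries (FASTA)

def read_fastq(path) -> list[FastqRead]:
    reads = []
    for record in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in record.letter_annotations["phred_quality"]
        )
        reads.append(FastqRead(record.id, str(record.seq), qual))
    return reads


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.quality]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_junction_fasta(library, path) -> None:
    """Write a junction library as FASTA with ``breakpoint=<offset>`` and
    ``gene=<symbol>`` tags in the description."""
    records = [
        SeqRecord(
            Seq(j.sequence),
            id=fusion_id,
            description=f"gene={j.gene} breakpoint={j.breakpoint_offset}",
        )
        for fusion_id, j in library.junctions.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# whole-cohort directory

def write_cohort(bundle: CohortBundle, out_dir, truth=None, library=None) -> Path:
    """Materialise a cohort as the standard directory layout:
    annotation.tsv, mutations.tsv, expression.tsv, beta.tsv + probe_map.tsv,
    reads/<sample>.fastq, junctions.fa, truth.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_annotation_tsv(bundle.annotation, out_dir / "annotation.tsv")
    write_mutations_tsv(bundle.mutations, out_dir / "mutations.tsv")
    write_expression_tsv(bundle.expression, out_dir / "expression.tsv")
    if bundle.methylation is not None:
        write_methylation(
            bundle.methylation, out_dir / "beta.tsv", out_dir / "probe_map.tsv"
        )
    if bundle.reads:
        reads_dir = out_dir / "reads"
        reads_dir.mkdir(exist_ok=True)
        for sid in sorted(bundle.reads):
            write_fastq(bundle.reads[sid], reads_dir / f"{sid}.fastq")
    if library is not None:
        write_junction_fasta(library, out_dir / "junctions.fa")
    if truth is not None:
        truth.to_frame().to_csv(out_dir / "truth.tsv", sep="\t", index=False,
                                lineterminator="\n")
    return out_dir


def read_cohort(in_dir) -> CohortBundle:
    """Load a cohort directory written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    annotation = read_annotation_tsv(in_dir / "annotation.tsv")
    mutations = read_mutations_tsv(in_dir / "mutations.tsv")
    expression = read_expression_tsv(in_dir / "expression.tsv")
    methylation = None
    if (in_dir / "beta.tsv").exists():
        methylation = read_methylation(in_dir / "beta.tsv", in_dir / "probe_map.tsv")
    reads = None
    reads_dir = in_dir / "reads"
    if reads_dir.is_dir():
        reads = {
            p.stem: read_fastq(p) for p in sorted(reads_dir.glob("*.fastq"))
        }
    return CohortBundle(
        annotation=annotation,
        mutations=mutations,
        expression=expression,
        methylation=methylation,
        reads=reads,
    )
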