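"""Readers and writers for the tabular and sequence formats the pipeline touches.

All tables are tab-delimited UTF-8 with a header row; writers emit a
deterministic column order so that reader/writer pairs are lossless round
trips on valid data.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import ValidationError
from .model import (
    AnnotationTable,
    ExpressionMatrix,
    GeneAnnotation,
    MutationRecord,
    MutationTable,
    ProteinAlignment,
    PsiTable,
    SampleTable,
    parse_protein_change,
)

_CORE_SAMPLE_COLS = ("sample_id", "cancer_type", "tissue_class")


def _read_rows(path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        return header, [row for row in reader]


def read_expression_matrix(path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a genes x samples TPM matrix from TSV.

    First column holds gene ids; the header row holds sample ids.  The
    result is flagged ``normalized=False``; negative, non-numeric or
    duplicate entries are rejected.
    """
    if orientation != "genes_in_rows":
        raise ValidationError(f"unsupported orientation {orientation!r}")
    header, rows = _read_rows(path)
    sample_ids = header[1:]
    gene_ids = []
    values = np.empty((len(rows), len(sample_ids)), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise ValidationError(f"{path}: row {i + 2} has {len(row)} fields, "
                                  f"expected {len(header)}")
        gene_ids.append(row[0])
        for j, cell in enumerate(row[1:]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric expression value {cell!r} for gene "
                    f"{row[0]!r}, sample {sample_ids[j]!r}"
                ) from None
    return ExpressionMatrix(gene_ids, sample_ids, values, normalized=False)


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", *expr.sample_ids])
        for g, row in zip(expr.gene_ids, expr.values):
            w.writerow([g, *(repr(float(v)) for v in row)])


def read_sample_table(path) -> SampleTable:
    header, rows = _read_rows(path)
    for col in _CORE_SAMPLE_COLS:
        if col not in header:
            raise ValidationError(f"{path}: missing column {col!r}")
    idx = {c: header.index(c) for c in header}
    extra_cols = [c for c in header if c not in _CORE_SAMPLE_COLS]
    sample_ids, cancer_types, tissue_classes = [], [], []
    extra: dict[str, dict[str, str]] = {}
    for row in rows:
        sid = row[idx["sample_id"]]
        sample_ids.append(sid)
        cancer_types.append(row[idx["cancer_type"]])
        tissue_classes.append(row[idx["tissue_class"]])
        labels = {c: row[idx[c]] for c in extra_cols if row[idx[c]] != ""}
        if labels:
            extra[sid] = labels
    return SampleTable(sample_ids, cancer_types, tissue_classes, extra)


def write_sample_table(samples: SampleTable, path) -> None:
    df = samples.to_frame()
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotation(path) -> AnnotationTable:
    header, rows = _read_rows(path)
    required = ["gene_id", "symbol", "chromosome", "start", "end", "strand", "categories"]
    for col in required:
        if col not in header:
            raise ValidationError(f"{path}: missing column {col!r}")
    idx = {c: header.index(c) for c in header}
    genes = []
    for row in rows:
        cats = frozenset(c for c in row[idx["categories"]].split(";") if c)
        paralogue = row[idx["paralogue"]] if "paralogue" in idx else ""
        genes.append(
            GeneAnnotation(
                gene_id=row[idx["gene_id"]],
                symbol=row[idx["symbol"]],
                chromosome=row[idx["chromosome"]],
                start=int(row[idx["start"]]),
                end=int(row[idx["end"]]),
                strand=row[idx["strand"]],
                categories=cats,
                paralogue=paralogue or None,
            )
        )
    return AnnotationTable(genes)


def write_annotation(annotation: AnnotationTable, path) -> None:
    annotation.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_psi_table(path) -> PsiTable:
    """Read a per-event Psi table.

    Layout: ``event_id``, ``event_class``, then one Psi column per sample.
    An empty cell means the event was not measured in that sample (missing,
    not zero).
    """
    header, rows = _read_rows(path)
    if len(header) < 2 or header[0] != "event_id" or header[1] != "event_class":
        raise ValidationError(
            f"{path}: expected columns event_id, event_class, <samples...>"
        )
    sample_ids = header[2:]
    event_ids, event_classes = [], []
    values = np.full((len(rows), len(sample_ids)), np.nan)
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise ValidationError(f"{path}: row {i + 2} has {len(row)} fields")
        event_ids.append(row[0])
        event_classes.append(row[1])
        for j, cell in enumerate(row[2:]):
            if cell == "":
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric psi {cell!r} in row {i + 2}"
                ) from None
            if math.isnan(v):
                raise ValidationError(f"{path}: literal NaN psi in row {i + 2}; "
                                      "use an empty cell for missing")
            values[i, j] = v
    return PsiTable(event_ids, event_classes, sample_ids, values)


def write_psi_table(psi: PsiTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["event_id", "event_class", *psi.sample_ids])
        for e, c, row in zip(psi.event_ids, psi.event_classes, psi.values):
            w.writerow([e, c, *("" if math.isnan(v) else repr(float(v)) for v in row)])


def read_mutation_table(path) -> MutationTable:
    """Read a minimal-MAF mutation table.

    Required columns: ``sample_id``, ``gene_symbol``, ``protein_change``,
    ``cancer_type``.  Extra columns are ignored, not errors.
    """
    header, rows = _read_rows(path)
    required = ["sample_id", "gene_symbol", "protein_change", "cancer_type"]
    for col in required:
        if col not in header:
            raise ValidationError(f"{path}: missing column {col!r}")
    idx = {c: header.index(c) for c in required}
    records = []
    for i, row in enumerate(rows):
        change = row[idx["protein_change"]]
        try:
            parse_protein_change(change)
        except ValidationError as e:
            raise ValidationError(f"{path}: row {i + 2}: {e}") from None
        records.append(
            MutationRecord(
                sample_id=row[idx["sample_id"]],
                gene_symbol=row[idx["gene_symbol"]],
                protein_change=change,
                cancer_type=row[idx["cancer_type"]],
            )
        )
    return MutationTable(records)


def write_mutation_table(muts: MutationTable, path) -> None:
    muts.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_alignment_fasta(path, canonical_name: str) -> ProteinAlignment:
    """Read an equal-length gapped protein FASTA as a :class:`ProteinAlignment`."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    return ProteinAlignment(records, canonical_name)


def write_alignment_fasta(aln: ProteinAlignment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in aln.records:
            fh.write(f">{name}\n{seq}\n")


def sha256_of(path) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
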