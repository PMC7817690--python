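"""Domain types for the expression / splicing / mutation pipeline.

Conventions
-----------
* Gene identity is keyed on ``gene_id``; ``symbol`` is display-only.
* Genomic coordinates are 1-based inclusive (GTF convention) and are never
  converted implicitly.
* Missing Psi is encoded as NaN / an empty TSV field, never 0 — a Psi of 0
  is a valid biological value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

TISSUE_CLASSES = frozenset({"tumor", "adjacent_normal", "cell_line"})

EVENT_CLASSES = frozenset(
    {"SE", "RI", "A3SS", "A5SS", "MXE", "TandemUTR", "AFE", "ALE", "constitutive"}
)

#: Closed category vocabulary for gene annotations.  ``marker_panel:<name>``
#: is matched as a prefix pattern.
GENE_CATEGORIES = frozenset(
    {"sH2A_paralogue", "CTA", "canonical_histone_H2A", "canonical_histone_H2B", "coding"}
)

SH2A_PARALOGUE_NAMES = ("H2AFB1", "H2AFB2", "H2AFB3", "HYPM", "H2A.Q")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_PROTEIN_CHANGE_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Parse a short-form protein change like ``E121Q`` into (ref, pos, alt).

    Positions are 1-based on the ungapped canonical protein sequence.
    """
    m = _PROTEIN_CHANGE_RE.match(text.strip())
    if m is None:
        raise ValidationError(f"unparseable protein change: {text!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if ref not in AMINO_ACIDS or (alt not in AMINO_ACIDS and alt != "*"):
        raise ValidationError(f"protein change uses unknown residue: {text!r}")
    if pos < 1:
        raise ValidationError(f"protein change position must be >= 1: {text!r}")
    return ref, pos, alt


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


def valid_category(cat: str) -> bool:
    return cat in GENE_CATEGORIES or cat.startswith("marker_panel:")


@dataclass
class ExpressionMatrix:
    """TPM values for genes x samples.

    ``values`` has shape ``(len(gene_ids), len(sample_ids))``; all entries
    are finite and non-negative.  ``normalized`` distinguishes raw TPM from
    TMM-adjusted values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression value for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise ValidationError(f"gene {gene_id!r} not in matrix") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise ValidationError(f"sample {sample_id!r} not in matrix") from None

    def sample_columns(self, sample_ids) -> np.ndarray:
        idx = [self.sample_index(s) for s in sample_ids]
        return self.values[:, idx]

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id), :]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.sample_ids), self.values[idx, :], self.normalized
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def __eq__(self, other) -> bool:  # value equality for round-trip tests
        return (
            isinstance(other, ExpressionMatrix)
            and self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.normalized == other.normalized
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SampleTable:
    """Per-sample metadata: cancer type, tissue class, open extra labels."""

    sample_ids: list[str]
    cancer_types: list[str]
    tissue_classes: list[str]
    extra_labels: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.cancer_types = list(self.cancer_types)
        self.tissue_classes = list(self.tissue_classes)
        if not (len(self.sample_ids) == len(self.cancer_types) == len(self.tissue_classes)):
            raise ValidationError("sample table columns have unequal lengths")
        _check_unique(self.sample_ids, "sample id")
        for s, tc in zip(self.sample_ids, self.tissue_classes):
            if tc not in TISSUE_CLASSES:
                raise ValidationError(
                    f"sample {s!r}: tissue_class {tc!r} not in {sorted(TISSUE_CLASSES)}"
                )
        self._row = {s: i for i, s in enumerate(self.sample_ids)}

    def __len__(self) -> int:
        return len(self.sample_ids)

    def cancer_type_of(self, sample_id: str) -> str:
        try:
            return self.cancer_types[self._row[sample_id]]
        except KeyError:
            raise ValidationError(f"sample {sample_id!r} not in sample table") from None

    def tissue_class_of(self, sample_id: str) -> str:
        return self.tissue_classes[self._row[sample_id]]

    def samples_of_type(self, cancer_type: str, tissue_class: str | None = None) -> list[str]:
        out = []
        for s, ct, tc in zip(self.sample_ids, self.cancer_types, self.tissue_classes):
            if ct == cancer_type and (tissue_class is None or tc == tissue_class):
                out.append(s)
        return out

    def cancer_type_list(self) -> list[str]:
        """Cancer types in first-appearance order."""
        seen: dict[str, None] = {}
        for ct in self.cancer_types:
            seen.setdefault(ct)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        extra_keys = sorted({k for d in self.extra_labels.values() for k in d})
        data = {
            "sample_id": self.sample_ids,
            "cancer_type": self.cancer_types,
            "tissue_class": self.tissue_classes,
        }
        for k in extra_keys:
            data[k] = [self.extra_labels.get(s, {}).get(k, "") for s in self.sample_ids]
        return pd.DataFrame(data)


@dataclass
class GeneAnnotation:
    """Annotation record for a single gene (1-based inclusive coordinates)."""

    gene_id: str
    symbol: str
    chromosome: str
    start: int
    end: int
    strand: str
    categories: frozenset[str] = frozenset()
    paralogue: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id!r}: strand must be + or -")
        self.categories = frozenset(self.categories)
        for c in self.categories:
            if not valid_category(c):
                raise ValidationError(f"gene {self.gene_id!r}: unknown category {c!r}")
        if "sH2A_paralogue" in self.categories and not self.paralogue:
            raise ValidationError(
                f"gene {self.gene_id!r}: sH2A_paralogue genes must carry a paralogue name"
            )


class AnnotationTable:
    """Collection of :class:`GeneAnnotation` keyed by gene_id."""

    def __init__(self, genes: list[GeneAnnotation]):
        _check_unique([g.gene_id for g in genes], "gene id")
        self.genes = list(genes)
        self._by_id = {g.gene_id: g for g in genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def get(self, gene_id: str) -> GeneAnnotation:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise ValidationError(f"gene {gene_id!r} not in annotation") from None

    def with_category(self, category: str) -> list[GeneAnnotation]:
        return [g for g in self.genes if category in g.categories]

    def marker_panel(self, name: str) -> list[GeneAnnotation]:
        return self.with_category(f"marker_panel:{name}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "symbol": [g.symbol for g in self.genes],
                "chromosome": [g.chromosome for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "categories": [";".join(sorted(g.categories)) for g in self.genes],
                "paralogue": [g.paralogue or "" for g in self.genes],
            }
        )


@dataclass
class PsiTable:
    """Per-event, per-sample inclusion fractions with event-class labels.

    ``values`` is events x samples; NaN marks missing measurements.
    """

    event_ids: list[str]
    event_classes: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.event_ids = list(self.event_ids)
        self.event_classes = list(self.event_classes)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.event_ids), len(self.sample_ids)):
            raise ValidationError("psi matrix shape does not match id lists")
        if len(self.event_classes) != len(self.event_ids):
            raise ValidationError("event_classes length does not match event_ids")
        _check_unique(self.event_ids, "event id")
        _check_unique(self.sample_ids, "sample id")
        for e, c in zip(self.event_ids, self.event_classes):
            if c not in EVENT_CLASSES:
                raise ValidationError(
                    f"event {e!r}: unknown event class {c!r} "
                    f"(expected one of {sorted(EVENT_CLASSES)})"
                )
        finite = self.values[~np.isnan(self.values)]
        if np.any((finite < 0) | (finite > 1)):
            bad = np.argwhere((self.values < 0) | (self.values > 1))[0]
            raise ValidationError(
                f"psi out of [0,1] for event {self.event_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        self._event_index = {e: i for i, e in enumerate(self.event_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_events(self) -> int:
        return len(self.event_ids)

    def event_values(self, event_id: str, sample_ids) -> np.ndarray:
        row = self.values[self._event_index[event_id], :]
        return np.array([row[self._sample_index[s]] for s in sample_ids])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.event_ids, columns=self.sample_ids)
        df.insert(0, "event_class", self.event_classes)
        return df

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PsiTable)
            and self.event_ids == other.event_ids
            and self.event_classes == other.event_classes
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class MutationRecord:
    sample_id: str
    gene_symbol: str
    protein_change: str
    cancer_type: str

    @property
    def parsed(self) -> tuple[str, int, str]:
        return parse_protein_change(self.protein_change)


class MutationTable:
    """Per-sample somatic protein-changing calls (minimal MAF dialect)."""

    def __init__(self, records: list[MutationRecord]):
        for r in records:
            parse_protein_change(r.protein_change)  # validates
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, MutationTable) and self.records == other.records

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "gene_symbol": [r.gene_symbol for r in self.records],
                "protein_change": [r.protein_change for r in self.records],
                "cancer_type": [r.cancer_type for r in self.records],
            }
        )


class ProteinAlignment:
    """Gapped protein records of equal length with a named canonical reference."""

    GAP = "-"

    def __init__(self, records: list[tuple[str, str]], canonical_name: str):
        if not records:
            raise ValidationError("alignment has no records")
        names = [n for n, _ in records]
        _check_unique(names, "alignment record name")
        width = len(records[0][1])
        for name, seq in records:
            if len(seq) != width:
                raise ValidationError(
                    f"ragged alignment: record {name!r} has length {len(seq)}, "
                    f"expected {width}"
                )
            for ch in seq:
                if ch != self.GAP and ch not in AMINO_ACIDS:
                    raise ValidationError(
                        f"record {name!r}: unexpected alignment character {ch!r}"
                    )
        if canonical_name not in names:
            raise ValidationError(
                f"canonical record {canonical_name!r} absent from alignment"
            )
        self.records = [(n, s) for n, s in records]
        self.canonical_name = canonical_name
        self._by_name = dict(self.records)

    @property
    def width(self) -> int:
        return len(self.records[0][1])

    def sequence(self, name: str) -> str:
        try:
            return self._by_name[name]
        except KeyError:
            raise ValidationError(f"record {name!r} not in alignment") from None

    def ungapped(self, name: str) -> str:
        return self.sequence(name).replace(self.GAP, "")

    def ungapped_to_gapped(self, name: str) -> list[int]:
        """0-based column index of each ungapped residue of ``name``."""
        return [i for i, ch in enumerate(self.sequence(name)) if ch != self.GAP]

    def gapped_to_ungapped(self, name: str) -> dict[int, int]:
        """Inverse map: alignment column -> 0-based ungapped position."""
        return {col: j for j, col in enumerate(self.ungapped_to_gapped(name))}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProteinAlignment)
            and self.records == other.records
            and self.canonical_name == other.canonical_name
        )
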