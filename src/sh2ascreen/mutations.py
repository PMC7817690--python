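"""Histone-mutation collation, subtype co-occurrence, and alignment-based
mapping of recurrent oncohistone sites onto variant sequences.

Protein positions are 1-based on the ungapped canonical sequence (standard
histone numbering, e.g. E121, R29).  Gene panels ship as editable TSV
resources — they are data, not code — and the favorable-prognosis /
chromatin-modifier panels are starting points the user should review
against their own catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as importlib_resources

import pandas as pd

from .errors import ValidationError
from .io import read_alignment_fasta
from .model import MutationTable, ProteinAlignment, parse_protein_change
from .reactivation import ReactivationStatus, any_paralogue_positive

MIN_RECURRENT_DEFAULT = 5

TRUNCATED = "TRUNCATED"


class GeneClassCatalogue:
    """Named gene classes (symbol sets) used to pool mutation counts."""

    def __init__(self, classes: dict[str, set[str]]):
        for name, symbols in classes.items():
            if not symbols:
                raise ValidationError(f"gene class {name!r} is empty")
        self.classes = {name: set(symbols) for name, symbols in classes.items()}

    def __getitem__(self, name: str) -> set[str]:
        try:
            return self.classes[name]
        except KeyError:
            raise ValidationError(f"unknown gene class {name!r}") from None

    def __iter__(self):
        return iter(self.classes)

    def items(self):
        return self.classes.items()

    @classmethod
    def from_tsv(cls, path) -> "GeneClassCatalogue":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"class_name", "gene_symbol"} <= set(df.columns):
            raise ValidationError(f"{path}: need columns class_name, gene_symbol")
        classes: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            classes.setdefault(row["class_name"], set()).add(row["gene_symbol"])
        return cls(classes)

    def to_tsv(self, path) -> None:
        rows = [
            {"class_name": name, "gene_symbol": sym}
            for name in sorted(self.classes)
            for sym in sorted(self.classes[name])
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def default_catalogue() -> GeneClassCatalogue:
    """Packaged gene classes: canonical H2A/H2B histones plus the DLBCL
    subtype panels (the subtype panels are reviewable placeholders)."""
    ref = importlib_resources.files("sh2ascreen.resources") / "gene_panels.tsv"
    with importlib_resources.as_file(ref) as path:
        return GeneClassCatalogue.from_tsv(path)


def packaged_h2a_alignment() -> ProteinAlignment:
    """Packaged gapped alignment of canonical H2A against a short-H2A variant."""
    ref = importlib_resources.files("sh2ascreen.resources") / "h2a_alignment.fasta"
    with importlib_resources.as_file(ref) as path:
        return read_alignment_fasta(path, canonical_name="H2A_canonical")


def collate_recurrent_mutations(
    muts: MutationTable,
    catalogue: GeneClassCatalogue,
    min_count: int = MIN_RECURRENT_DEFAULT,
) -> pd.DataFrame:
    """Counts per (gene class, protein change), pooled across the genes of a
    class and across cancer types; ``recurrent`` iff count >= min_count."""
    counts: dict[tuple[str, str], int] = {}
    for rec in muts:
        for class_name, symbols in catalogue.items():
            if rec.gene_symbol in symbols:
                key = (class_name, rec.protein_change)
                counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "class_name": cls_name,
            "protein_change": change,
            "count": n,
            "recurrent": n >= min_count,
        }
        for (cls_name, change), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["class_name", "protein_change", "count", "recurrent"])


def subtype_cooccurrence(
    muts: MutationTable,
    gene_panels: GeneClassCatalogue,
    statuses: list[ReactivationStatus],
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Per-sample panel-mutation flags against the reactivation flag.

    Returns the flag table (one row per sample covered by ``statuses``) and,
    per panel, the 2x2 cross-tabulation counts keyed ``mut_pos``, ``mut_neg``,
    ``nomut_pos``, ``nomut_neg``.  Panel genes absent from the mutation
    table simply contribute no flags.
    """
    pos_any = any_paralogue_positive(statuses)
    mutated: dict[str, set[str]] = {}
    for rec in muts:
        mutated.setdefault(rec.sample_id, set()).add(rec.gene_symbol)
    sample_ids = sorted(pos_any)
    data: dict[str, list] = {"sample_id": sample_ids}
    crosstabs: dict[str, dict[str, int]] = {}
    for panel_name, symbols in gene_panels.items():
        flags = [bool(mutated.get(s, set()) & symbols) for s in sample_ids]
        data[f"{panel_name}_mutated"] = flags
        tab = {"mut_pos": 0, "mut_neg": 0, "nomut_pos": 0, "nomut_neg": 0}
        for s, f in zip(sample_ids, flags):
            key = ("mut" if f else "nomut") + ("_pos" if pos_any[s] else "_neg")
            tab[key] += 1
        crosstabs[panel_name] = tab
    data["sh2a_positive"] = [pos_any[s] for s in sample_ids]
    return pd.DataFrame(data), crosstabs


@dataclass(frozen=True)
class OncoFeature:
    canonical_position: int  # 1-based on the ungapped canonical sequence
    canonical_aa: str
    variant_name: str
    variant_aa: str  # residue, '-' for internal deletion, or TRUNCATED
    matches_oncomutation: bool
    oncomutation: str


def map_oncohistone_features(
    aln: ProteinAlignment,
    variant_name: str,
    oncomutations: list[str],
) -> list[OncoFeature]:
    """Report, for each canonical recurrent mutation, what the variant carries
    at the corresponding alignment column.

    The canonical record must show the stated reference residue at each
    stated ungapped position (guards against mis-numbered catalogues).  A
    variant gap that extends from the feature column through the alignment's
    C-terminal end is reported as TRUNCATED; internal gaps report ``-``.
    Insertions in the variant relative to the canonical create no features.
    """
    canonical_seq = aln.sequence(aln.canonical_name)
    canonical_ungapped = aln.ungapped(aln.canonical_name)
    col_of = aln.ungapped_to_gapped(aln.canonical_name)
    variant_seq = aln.sequence(variant_name)

    features: list[OncoFeature] = []
    for change in oncomutations:
        ref, pos, alt = parse_protein_change(change)
        if pos > len(canonical_ungapped):
            raise ValidationError(
                f"{change}: position {pos} beyond canonical length "
                f"{len(canonical_ungapped)}"
            )
        if canonical_ungapped[pos - 1] != ref:
            raise ValidationError(
                f"{change}: canonical sequence has "
                f"{canonical_ungapped[pos - 1]!r} at position {pos}, expected {ref!r}"
            )
        col = col_of[pos - 1]
        residue = variant_seq[col]
        if residue == ProteinAlignment.GAP:
            if set(variant_seq[col:]) == {ProteinAlignment.GAP}:
                variant_aa = TRUNCATED
            else:
                variant_aa = ProteinAlignment.GAP
            matches = False
        else:
            variant_aa = residue
            matches = residue == alt
        features.append(
            OncoFeature(
                canonical_position=pos,
                canonical_aa=canonical_seq[col],
                variant_name=variant_name,
                variant_aa=variant_aa,
                matches_oncomutation=matches,
                oncomutation=change,
            )
        )
    return features


def onco_features_frame(features: list[OncoFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "oncomutation": [f.oncomutation for f in features],
            "canonical_position": [f.canonical_position for f in features],
            "canonical_aa": [f.canonical_aa for f in features],
            "variant_name": [f.variant_name for f in features],
            "variant_aa": [f.variant_aa for f in features],
            "matches_oncomutation": [f.matches_oncomutation for f in features],
        }
    )
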