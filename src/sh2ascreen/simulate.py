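"""Synthetic TCGA-like cohort generation with known ground truth.

The generator is the test bed for every downstream stage: it plants
reactivated samples, shifted testis-antigen expression, differential-
expression genes, splicing shifts and recurrent mutation hotspots, and
records every planted effect in a :class:`GroundTruth` object.

Distributional choices (log-normal TPM background, beta-distributed Psi)
are ours: the upstream study analyzed real archives and gives no generative
model.  They are documented here and in the package README.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .model import (
    AnnotationTable,
    ExpressionMatrix,
    GeneAnnotation,
    MutationRecord,
    MutationTable,
    PsiTable,
    SampleTable,
    SH2A_PARALOGUE_NAMES,
    AMINO_ACIDS,
)

_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]

_DEFAULT_MUTATION_POOL = (
    "HIST1H2AC",
    "HIST1H2BJ",
    "EZH2",
    "CREBBP",
    "EP300",
    "KMT2D",
    "BCL11A",
    "PIK3CA",
)

_DEFAULT_HOTSPOT_GENES = ("HIST1H2AC", "HIST1H2AG", "HIST2H2AC")


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; fixed seed => byte-identical outputs."""

    n_cancer_types: int = 2
    samples_per_type: int = 50
    n_genes: int = 200
    n_cta_genes: int = 40
    n_sh2a_paralogues: int = 3
    n_marker_genes: int = 4
    reactivation_fraction: float = 0.1
    #: When set, exactly this many samples per cancer type are reactivated
    #: (overrides the Bernoulli draw) — convenient for fixed-size group tests.
    reactivated_count: int | None = None
    reactivated_tpm_location: float = 3.0
    #: Hard floor for reactivated short-H2A TPM; keeps planted positives
    #: strictly above the positive-call threshold.
    reactivated_tpm_floor: float = 1.5
    reactivated_tpm_sigma: float = 0.5
    #: Probability that a silent sample shows sub-threshold dropout noise
    #: (uniform on [0, 0.45), i.e. strictly below the 0.5 negative border).
    dropout_rate: float = 0.1
    cta_effect_sd: float = 0.0
    #: Fraction of CTA genes that carry the planted shift.
    cta_affected_fraction: float = 1.0
    n_de_genes: int = 0
    de_fold_change: float = 2.0
    log_tpm_mu_range: tuple[float, float] = (0.0, 4.0)
    log_tpm_sd_range: tuple[float, float] = (0.2, 0.5)
    n_splice_events_per_class: int = 50
    splice_classes: tuple[str, ...] = ("SE", "RI", "A3SS", "A5SS", "TandemUTR", "constitutive")
    planted_dpsi: float = 0.0
    planted_event_fraction: float = 0.0
    #: Event classes eligible for planted shifts; None = all non-constitutive.
    planted_classes: tuple[str, ...] | None = None
    psi_concentration: float = 20.0
    psi_missing_rate: float = 0.0
    mutation_rate: float = 0.0
    mutation_gene_pool: tuple[str, ...] = _DEFAULT_MUTATION_POOL
    hotspot_change: str = "E121Q"
    hotspot_genes: tuple[str, ...] = _DEFAULT_HOTSPOT_GENES
    hotspot_count: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cancer_types < 1 or self.samples_per_type < 1:
            raise ValidationError("cohort must have at least one type and one sample")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if self.n_sh2a_paralogues < 1 or self.n_sh2a_paralogues > len(SH2A_PARALOGUE_NAMES):
            raise ValidationError(
                f"n_sh2a_paralogues must be in [1, {len(SH2A_PARALOGUE_NAMES)}]"
            )
        for name, frac in [
            ("reactivation_fraction", self.reactivation_fraction),
            ("planted_event_fraction", self.planted_event_fraction),
            ("cta_affected_fraction", self.cta_affected_fraction),
            ("psi_missing_rate", self.psi_missing_rate),
            ("mutation_rate", self.mutation_rate),
            ("dropout_rate", self.dropout_rate),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {frac}")
        if not -1.0 <= self.planted_dpsi <= 1.0:
            raise ValidationError("planted_dpsi must be in [-1, 1]")
        if self.psi_concentration <= 0 or self.reactivated_tpm_location <= 0:
            raise ValidationError("concentration and TPM location must be positive")
        if self.reactivated_count is not None and not (
            0 <= self.reactivated_count <= self.samples_per_type
        ):
            raise ValidationError("reactivated_count out of range")
        if self.n_cta_genes + self.n_de_genes + self.n_marker_genes > self.n_genes:
            raise ValidationError("special gene counts exceed n_genes")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown cohort config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Planted effects, recorded so they can be re-detected downstream."""

    reactivated_samples: list[str]
    paralogue_pattern: dict[str, list[str]]  # sample -> expressed paralogue names
    sh2a_gene_ids: list[str]
    cta_gene_ids: list[str]
    cta_affected_gene_ids: list[str]
    de_gene_ids: list[str]
    planted_event_ids: list[str]
    hotspot_samples: list[str]
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _build_annotation(cfg: CohortConfig) -> AnnotationTable:
    genes: list[GeneAnnotation] = []
    pos = 1_000_000
    # short-H2A paralogues: clustered on chrX
    for i in range(cfg.n_sh2a_paralogues):
        name = SH2A_PARALOGUE_NAMES[i]
        genes.append(
            GeneAnnotation(
                gene_id=f"SH2A{i + 1:02d}",
                symbol=name,
                chromosome="chrX",
                start=pos,
                end=pos + 500,
                strand="+",
                categories=frozenset({"sH2A_paralogue", "coding"}),
                paralogue=name,
            )
        )
        pos += 50_000
    n_background = cfg.n_genes - cfg.n_cta_genes - cfg.n_marker_genes
    for i in range(cfg.n_cta_genes):
        chrom = _AUTOSOMES[i % len(_AUTOSOMES)]
        start = 2_000_000 + 100_000 * i
        genes.append(
            GeneAnnotation(
                gene_id=f"CTA{i + 1:04d}",
                symbol=f"CTAG{i + 1}",
                chromosome=chrom,
                start=start,
                end=start + 2_000,
                strand="+",
                categories=frozenset({"CTA", "coding"}),
            )
        )
    for i in range(cfg.n_marker_genes):
        chrom = _AUTOSOMES[(7 + i) % len(_AUTOSOMES)]
        start = 9_000_000 + 100_000 * i
        genes.append(
            GeneAnnotation(
                gene_id=f"MRK{i + 1:03d}",
                symbol=f"MARKER{i + 1}",
                chromosome=chrom,
                start=start,
                end=start + 3_000,
                strand="-",
                categories=frozenset({"coding", "marker_panel:variant_histones"}),
            )
        )
    # background genes; every 10th lives on chrX so X:autosome ratios are defined
    for i in range(n_background):
        chrom = "chrX" if i % 10 == 9 else _AUTOSOMES[i % len(_AUTOSOMES)]
        start = 20_000_000 + 10_000 * i
        genes.append(
            GeneAnnotation(
                gene_id=f"BG{i + 1:05d}",
                symbol=f"BGENE{i + 1}",
                chromosome=chrom,
                start=start,
                end=start + 5_000,
                strand="+" if i % 2 == 0 else "-",
                categories=frozenset({"coding"}),
            )
        )
    return AnnotationTable(genes)


def _paralogue_subset(rng: np.random.Generator, names: list[str]) -> list[str]:
    """Co-expression pattern for one reactivated sample."""
    if len(names) == 1:
        return list(names)
    r = rng.random()
    if r < 0.5:
        return [names[0]]
    if r < 0.8:
        return list(names[1:3]) if len(names) >= 3 else [names[1]]
    return list(names)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, SampleTable, AnnotationTable, PsiTable, MutationTable, GroundTruth]:
    """Generate one cohort.  Same config (incl. seed) => identical outputs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    annotation = _build_annotation(config)

    sample_ids: list[str] = []
    cancer_types: list[str] = []
    reactivated: list[str] = []
    for t in range(config.n_cancer_types):
        ct = f"CT{t + 1:02d}"
        ids = [f"{ct}-S{i + 1:04d}" for i in range(config.samples_per_type)]
        sample_ids.extend(ids)
        cancer_types.extend([ct] * len(ids))
        if config.reactivated_count is not None:
            chosen = rng.choice(len(ids), size=config.reactivated_count, replace=False)
            reactivated.extend(ids[int(i)] for i in sorted(chosen))
        else:
            flags = rng.random(len(ids)) < config.reactivation_fraction
            reactivated.extend(s for s, f in zip(ids, flags) if f)
    samples = SampleTable(sample_ids, cancer_types, ["tumor"] * len(sample_ids))
    react_set = set(reactivated)
    react_mask = np.array([s in react_set for s in sample_ids])

    gene_ids = [g.gene_id for g in annotation]
    n_genes, n_samples = len(gene_ids), len(sample_ids)
    sh2a_ids = [g.gene_id for g in annotation.with_category("sH2A_paralogue")]
    cta_ids = [g.gene_id for g in annotation.with_category("CTA")]

    mu = rng.uniform(*config.log_tpm_mu_range, size=n_genes)
    sd = rng.uniform(*config.log_tpm_sd_range, size=n_genes)
    values = rng.lognormal(mean=mu[:, None], sigma=sd[:, None], size=(n_genes, n_samples))

    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # short-H2A rows: silent everywhere, then planted expression in
    # reactivated samples according to a co-expression pattern.
    paralogue_by_id = {g.gene_id: g.paralogue for g in annotation if g.paralogue}
    id_by_paralogue = {v: k for k, v in paralogue_by_id.items()}
    paralogue_names = [paralogue_by_id[g] for g in sh2a_ids]
    for gid in sh2a_ids:
        row = np.zeros(n_samples)
        drop = rng.random(n_samples) < config.dropout_rate
        row[drop] = rng.uniform(0.0, 0.45, size=int(drop.sum()))
        values[gene_index[gid], :] = row
    pattern: dict[str, list[str]] = {}
    for s in reactivated:
        chosen = _paralogue_subset(rng, paralogue_names)
        pattern[s] = chosen
        col = samples._row[s]
        for name in chosen:
            gid = id_by_paralogue[name]
            extra = rng.lognormal(
                mean=np.log(max(config.reactivated_tpm_location - config.reactivated_tpm_floor,
                                1e-3)),
                sigma=config.reactivated_tpm_sigma,
            )
            values[gene_index[gid], col] = config.reactivated_tpm_floor + extra

    # planted CTA shift: multiply TPM by exp(effect * per-gene log-SD)
    n_cta_affected = int(round(config.cta_affected_fraction * len(cta_ids)))
    cta_affected = list(cta_ids[:n_cta_affected]) if config.cta_effect_sd != 0 else []
    if cta_affected and react_mask.any():
        for gid in cta_affected:
            i = gene_index[gid]
            values[i, react_mask] *= np.exp(config.cta_effect_sd * sd[i])

    # planted pan-cohort differential expression genes (background genes)
    bg_ids = [g for g in gene_ids if g.startswith("BG")]
    de_ids = bg_ids[: config.n_de_genes]
    for gid in de_ids:
        values[gene_index[gid], react_mask] *= config.de_fold_change

    expr = ExpressionMatrix(gene_ids, sample_ids, values, normalized=False)

    # Psi table: per-event baseline mean, beta noise, planted shifts
    planted_classes = config.planted_classes
    if planted_classes is None:
        planted_classes = tuple(c for c in config.splice_classes if c != "constitutive")
    event_ids: list[str] = []
    event_classes: list[str] = []
    planted_events: list[str] = []
    mus: list[float] = []
    planted_flags: list[bool] = []
    for cls_name in config.splice_classes:
        n_planted = (
            int(round(config.planted_event_fraction * config.n_splice_events_per_class))
            if cls_name in planted_classes and config.planted_dpsi != 0.0
            else 0
        )
        planted_idx = set(
            int(i)
            for i in rng.choice(
                config.n_splice_events_per_class, size=n_planted, replace=False
            )
        )
        for i in range(config.n_splice_events_per_class):
            eid = f"{cls_name}{i + 1:05d}"
            event_ids.append(eid)
            event_classes.append(cls_name)
            if cls_name == "constitutive":
                mus.append(float(rng.uniform(0.9, 0.98)))
            else:
                mus.append(float(rng.uniform(0.2, 0.8)))
            is_planted = i in planted_idx
            planted_flags.append(is_planted)
            if is_planted:
                planted_events.append(eid)
    kappa = config.psi_concentration
    psi_values = np.empty((len(event_ids), n_samples))
    for i, (m, is_planted) in enumerate(zip(mus, planted_flags)):
        m_eff = np.full(n_samples, m)
        if is_planted:
            m_eff[react_mask] = np.clip(m + config.planted_dpsi, 0.02, 0.98)
        psi_values[i, :] = rng.beta(m_eff * kappa, (1.0 - m_eff) * kappa)
    if config.psi_missing_rate > 0:
        miss = rng.random(psi_values.shape) < config.psi_missing_rate
        psi_values[miss] = np.nan
    psi = PsiTable(event_ids, event_classes, sample_ids, psi_values)

    # sparse mutations plus an optional recurrent hotspot
    records: list[MutationRecord] = []
    aa = list(AMINO_ACIDS)
    for s, ct in zip(sample_ids, cancer_types):
        for gene in config.mutation_gene_pool:
            if rng.random() < config.mutation_rate:
                ref, alt = rng.choice(aa, size=2, replace=False)
                pos = int(rng.integers(1, 120))
                records.append(MutationRecord(s, gene, f"{ref}{pos}{alt}", ct))
    hotspot_samples: list[str] = []
    if config.hotspot_count > 0:
        chosen = rng.choice(n_samples, size=min(config.hotspot_count, n_samples),
                            replace=False)
        for i in sorted(int(c) for c in chosen):
            s = sample_ids[i]
            gene = str(rng.choice(list(config.hotspot_genes)))
            records.append(MutationRecord(s, gene, config.hotspot_change, cancer_types[i]))
            hotspot_samples.append(s)
    muts = MutationTable(records)

    truth = GroundTruth(
        reactivated_samples=reactivated,
        paralogue_pattern=pattern,
        sh2a_gene_ids=sh2a_ids,
        cta_gene_ids=list(cta_ids),
        cta_affected_gene_ids=cta_affected,
        de_gene_ids=de_ids,
        planted_event_ids=planted_events,
        hotspot_samples=hotspot_samples,
        config=config.to_dict(),
    )
    return expr, samples, annotation, psi, muts, truth
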