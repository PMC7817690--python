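import numpy as np
import pytest

from sh2ascreen.model import (
    AnnotationTable,
    ExpressionMatrix,
    GeneAnnotation,
    SampleTable,
)
from sh2ascreen.simulate import CohortConfig, simulate_cohort


def make_expr(gene_ids, sample_ids, values, normalized=False):
    return ExpressionMatrix(gene_ids, sample_ids, np.asarray(values, dtype=float),
                            normalized)


@pytest.fixture
def toy_annotation():
    return AnnotationTable(
        [
            GeneAnnotation("SH2A01", "H2AFB1", "chrX", 1_000_000, 1_000_500, "+",
                           frozenset({"sH2A_paralogue", "coding"}), paralogue="H2AFB1"),
            GeneAnnotation("SH2A02", "H2AFB2", "chrX", 1_050_000, 1_050_500, "+",
                           frozenset({"sH2A_paralogue", "coding"}), paralogue="H2AFB2"),
            GeneAnnotation("SH2A03", "H2AFB3", "chrX", 1_100_000, 1_100_500, "+",
                           frozenset({"sH2A_paralogue", "coding"}), paralogue="H2AFB3"),
            GeneAnnotation("BG1", "BGENE1", "chr1", 500, 900, "+",
                           frozenset({"coding"})),
            GeneAnnotation("BG2", "BGENE2", "chrX", 5_000_000, 5_001_000, "-",
                           frozenset({"coding"})),
        ]
    )


@pytest.fixture
def small_cohort():
    """Deterministic mid-size cohort with planted effects of every kind."""
    cfg = CohortConfig(
        n_cancer_types=2,
        samples_per_type=40,
        n_genes=120,
        n_cta_genes=20,
        n_de_genes=5,
        reactivation_fraction=0.25,
        cta_effect_sd=1.0,
        n_splice_events_per_class=20,
        planted_dpsi=0.2,
        planted_event_fraction=0.3,
        mutation_rate=0.02,
        hotspot_count=8,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def two_group_samples():
    ids = [f"P{i}" for i in range(10)] + [f"N{i}" for i in range(10)]
    return (
        SampleTable(ids, ["CT01"] * 20, ["tumor"] * 20),
        [f"P{i}" for i in range(10)],
        [f"N{i}" for i in range(10)],
    )
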