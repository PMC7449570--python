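import numpy as np
import pytest

from seqimpower import (
    DiseaseModel,
    QualityGenConfig,
    QualityTable,
    SignificanceSpec,
    VariantQualityRecord,
    generate_quality_tables,
)


@pytest.fixture(scope="session")
def worked_model() -> DiseaseModel:
    """Rare large-effect risk variant: MAF 0.5%, RR 4, prevalence 1%, 1:1."""
    return DiseaseModel(p=0.005, gamma=4.0, K=0.01, s=1.0)


@pytest.fixture(scope="session")
def genome_wide() -> SignificanceSpec:
    return SignificanceSpec(alpha=5e-8)


@pytest.fixture(scope="session")
def synth_tables():
    """Small synthetic quality tables shared across tests (seeded)."""
    cfg = QualityGenConfig(n_variants=600, seed=11)
    return cfg, generate_quality_tables(cfg)


def make_table(records, *, population="test", array="core", panel_n=0, N=3412):
    return QualityTable(
        population=population, array=array, panel_n=panel_n, N=N, records=list(records)
    )


def make_record(
    variant_id="v0",
    maf_sample=0.005,
    mac_panel=10.0,
    r2=0.8,
    pop_specific=False,
    weight=1.0,
    N=3412,
):
    return VariantQualityRecord(
        variant_id=variant_id,
        maf_sample=maf_sample,
        mac_sample=int(round(2 * N * maf_sample)),
        mac_panel=mac_panel,
        r2=r2,
        pop_specific=pop_specific,
        weight=weight,
    )
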