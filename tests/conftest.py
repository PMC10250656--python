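import numpy as np
import pytest

from dytburden.io import (
    CohortData,
    ExonicFunction,
    SampleInfo,
    Status,
    Subgroup,
    VariantAnnotation,
    VariantRecord,
)
from dytburden.panel import load_panel
from dytburden.simulate import make_paper_fixture_data


@pytest.fixture(scope="session")
def default_panel():
    return load_panel()


@pytest.fixture(scope="session")
def table1_cohort():
    return make_paper_fixture_data("table1_ar")


@pytest.fixture(scope="session")
def table2_cohort():
    return make_paper_fixture_data("table2_ad")


def make_annotation(
    vid="chr1:100:A:G",
    gene="TH",
    func=ExonicFunction.MISSENSE,
    reve=None,
    maf=(None, None),
    cadd=None,
    splice_offset=None,
    calls=None,
):
    """Terse VariantAnnotation builder for tests."""
    return VariantAnnotation(
        variant_id=vid,
        gene=gene,
        exonic_function=func,
        splice_offset=splice_offset,
        maf_exome_eas=maf[0],
        maf_genome_eas=maf[1],
        reve=reve,
        cadd=cadd,
        predictor_calls=calls or {},
    )


def make_cohort(dosages, annotations, n_cases=None, statuses=None):
    """Build a CohortData from a dosage matrix and annotation list.

    Variants take position/id from the annotation's variant_id.  By default
    the first ``n_cases`` samples are cases (sEOPD) and the rest controls.
    """
    dosages = np.asarray(dosages, dtype=float)
    n = dosages.shape[0]
    if statuses is None:
        n_cases = n if n_cases is None else n_cases
        statuses = [Status.CASE] * n_cases + [Status.CONTROL] * (n - n_cases)
    samples = []
    for i, st in enumerate(statuses):
        sub = Subgroup.SEOPD if st is Status.CASE else Subgroup.CONTROL1
        samples.append(
            SampleInfo(
                sample_id=f"S{i:03d}", status=st, subgroup=sub,
                age=40.0 + (i * 7) % 23, sex="male" if i % 2 else "female",
                pcs=(0.0, 0.0, 0.0, 0.0, 0.0),
            )
        )
    records = []
    ann_map = {}
    for a in annotations:
        chrom, pos, ref, alt = a.variant_id.split(":")
        records.append(VariantRecord(chrom, int(pos), ref, alt))
        ann_map[a.variant_id] = a
    return CohortData(
        samples=samples, variants=records, dosages=dosages, annotations=ann_map
    )
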