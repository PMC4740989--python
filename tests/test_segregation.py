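"""Allele-frequency arithmetic and the male/female segregation filters."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from msy_seg.errors import ConfigurationError
from msy_seg.segregation import (
    SegregationConfig,
    allele_frequency,
    expected_duplication_af,
    gene_af_summary,
    male_specific_sites,
    strain_specific_sites,
)

from _oracles import oracle_male_specific, oracle_strain_specific, random_variant_table


@pytest.mark.parametrize(
    "ref,alt,expected",
    [(10, 5, 1 / 3), (0, 0, None), (0, 7, 1.0), (7, 0, 0.0)],
)
def test_allele_frequency(ref, alt, expected):
    result = allele_frequency(ref, alt)
    if expected is None:
        assert result is None
    else:
        assert result == pytest.approx(expected)


def test_allele_frequency_rejects_negative_counts():
    with pytest.raises(ValueError):
        allele_frequency(-1, 5)


@pytest.mark.parametrize(
    "origin,c,expected",
    [
        ("autosome", 1, 1 / 3),  # the 33 % single-copy autosomal expectation
        ("chrX", 1, 0.5),
        ("autosome", 2, 0.5),
        ("autosome", 0, 0.0),
        ("chrX", 0, 0.0),
    ],
)
def test_expected_duplication_af(origin, c, expected):
    assert expected_duplication_af(origin, c) == pytest.approx(expected)


def test_expected_af_increases_in_copy_number_toward_one():
    for origin in ("autosome", "chrX"):
        values = [expected_duplication_af(origin, c) for c in range(1, 40)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert values[-1] > 0.9
    with pytest.raises(ValueError):
        expected_duplication_af("autosome", -1)


def test_segregation_config_bounds_must_be_ordered():
    with pytest.raises(ConfigurationError):
        SegregationConfig(female_max_af=0.5, male_af_lower=0.1)


SAMPLES = ["M1", "M2", "F1"]
CLASSES = {"M1": "male_class", "M2": "male_class", "F1": "female"}


def test_male_specific_filter_rules():
    table = make_table(
        [
            # both males ~33 %, female 0 -> passes
            ("chr1", 100, "A", "G", [(20, 10), (21, 9), (30, 0)]),
            # female carries the variant -> fails
            ("chr1", 200, "A", "G", [(20, 10), (21, 9), (24, 6)]),
            # one male fixed at 100 % -> outside the 0.1-99.9 % window
            ("chr1", 300, "A", "G", [(20, 10), (0, 30), (30, 0)]),
            # one male at 0 % -> fails the all-male rule
            ("chr1", 400, "A", "G", [(20, 10), (30, 0), (30, 0)]),
            # zero depth in a sample -> excluded, not imputed
            ("chr1", 500, "A", "G", [(20, 10), (0, 0), (30, 0)]),
        ],
        SAMPLES,
    )
    mask = male_specific_sites(table, CLASSES)
    assert mask.tolist() == [True, False, False, False, False]


def test_male_specific_filter_is_idempotent():
    table, classes = random_variant_table(np.random.default_rng(5))
    mask = male_specific_sites(table, classes)
    again = male_specific_sites(table.subset(mask), classes)
    assert again.all()


def test_male_specific_requires_sex_call_for_every_sample():
    table = make_table([("chr1", 1, "A", "G", [(5, 5), (5, 5), (9, 0)])], SAMPLES)
    with pytest.raises(ValueError, match="sex call"):
        male_specific_sites(table, {"M1": "male_class", "M2": "male_class"})


def test_strain_specific_leave_one_out_semantics():
    samples = ["A", "B", "C", "D", "F1"]
    classes = {s: "male_class" for s in "ABCD"} | {"F1": "female"}
    table = make_table(
        [
            # absent only in A -> reported under A
            ("chr1", 10, "A", "G", [(30, 0), (20, 10), (20, 10), (20, 10), (30, 0)]),
            # absent in A and B -> reported under neither
            ("chr1", 20, "A", "G", [(30, 0), (30, 0), (20, 10), (20, 10), (30, 0)]),
            # present in all -> reported under none
            ("chr1", 30, "A", "G", [(20, 10), (20, 10), (20, 10), (20, 10), (30, 0)]),
        ],
        samples,
    )
    result = strain_specific_sites(table, classes)
    assert result["A"].tolist() == [True, False, False]
    for strain in "BCD":
        assert not result[strain].any()


def test_strain_specific_requires_two_males():
    table = make_table([("chr1", 1, "A", "G", [(5, 5), (9, 0)])], ["M1", "F1"])
    with pytest.raises(ValueError, match="2 male"):
        strain_specific_sites(table, {"M1": "male_class", "F1": "female"})


@pytest.mark.parametrize("seed", range(120))
def test_filters_match_bruteforce_oracle(seed):
    """Both filters agree exactly with per-sample condition enumeration
    on randomized small tables."""
    table, classes = random_variant_table(np.random.default_rng(seed))
    cfg = SegregationConfig()
    mask = male_specific_sites(table, classes, cfg)
    assert list(np.flatnonzero(mask.to_numpy())) == oracle_male_specific(
        table, classes, cfg
    )
    males = [s for s in table.samples if classes[s] == "male_class"]
    if len(males) >= 2:
        loo = strain_specific_sites(table, classes, cfg)
        expected = oracle_strain_specific(table, classes, cfg)
        assert {s: list(np.flatnonzero(m.to_numpy())) for s, m in loo.items()} == expected


ANNOTATION = pd.DataFrame(
    [
        {"gene": "G1", "chromosome": "chr1", "gene_start": 50, "gene_end": 150},
        {"gene": "G2", "chromosome": "chr1", "gene_start": 300, "gene_end": 400},
    ]
)


def test_gene_af_summary_mean_and_sem():
    """Two sites with strain-averaged AF 0.30 and 0.34 give mean 0.32 and
    SEM 0.02; a single-site gene has no SEM."""
    table = make_table(
        [
            ("chr1", 100, "A", "G", [(70, 30), (70, 30), (30, 0)]),
            ("chr1", 110, "A", "G", [(66, 34), (66, 34), (30, 0)]),
            ("chr1", 350, "A", "G", [(20, 10), (20, 10), (30, 0)]),
        ],
        SAMPLES,
    )
    summaries = {s.gene: s for s in gene_af_summary(table, CLASSES, ANNOTATION)}
    assert summaries["G1"].n_snvs == 2
    assert summaries["G1"].mean_af == pytest.approx(0.32)
    assert summaries["G1"].sem_af == pytest.approx(0.02)
    assert summaries["G2"].n_snvs == 1
    assert summaries["G2"].sem_af is None


def test_gene_af_summary_reports_lacking_strain():
    """A gene absent from one strain is still summarized, with that
    strain listed under strains_lacking and excluded from the mean."""
    samples = ["A", "B", "C", "F1"]
    classes = {s: "male_class" for s in "ABC"} | {"F1": "female"}
    rows = [
        ("chr1", pos, "A", "G", [(30, 0), (20, 10), (20, 10), (30, 0)])
        for pos in (100, 140)
    ]
    table = make_table(rows, samples)
    summaries = gene_af_summary(table, classes, ANNOTATION)
    (g1,) = [s for s in summaries if s.gene == "G1"]
    assert g1.strains_lacking == frozenset({"A"})
    assert g1.mean_af == pytest.approx(1 / 3)


def test_site_in_two_genes_is_an_error():
    overlapping = pd.DataFrame(
        [
            {"gene": "G1", "chromosome": "chr1", "gene_start": 50, "gene_end": 150},
            {"gene": "G3", "chromosome": "chr1", "gene_start": 100, "gene_end": 200},
        ]
    )
    table = make_table([("chr1", 120, "A", "G", [(20, 10), (20, 10), (30, 0)])], SAMPLES)
    with pytest.raises(ValueError, match="chr1:120"):
        gene_af_summary(table, CLASSES, overlapping)
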