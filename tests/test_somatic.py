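"""Unit and property tests of the tumor/normal somatic caller."""

import math

import pysam
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from neotcr.somatic import (
    CallingParams,
    PileupSite,
    ReadObservation,
    call_cohort,
    call_site,
    evaluate_site,
    filter_read,
    fisher_exact_p,
    normalize_alleles,
    read_pileup_tsv,
    sites_from_counts_tsv,
    write_vcf,
)

from oracles import fisher_greater_oracle


# ---------------------------------------------------------------------------
# read pre-filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mapq,mismatches,length,keep",
    [
        (29, 0, 100, False),  # below the MAPQ 30 bound
        (30, 0, 100, True),   # boundary kept: only MAPQ < 30 is excluded
        (60, 6, 100, False),  # 6% mismatches exceeds the 5% bound
        (60, 5, 100, True),   # exactly 5% is retained
        (60, 0, 100, True),
    ],
)
def test_filter_read_boundaries(mapq, mismatches, length, keep):
    obs = ReadObservation("A", 30, mapq, length, mismatches)
    assert filter_read(obs) is keep


def test_read_observation_validation():
    with pytest.raises(ValueError):
        ReadObservation("A", 30, 60, 0, 0)
    with pytest.raises(ValueError):
        ReadObservation("A", 30, 60, 10, 11)
    with pytest.raises(ValueError):
        ReadObservation("", 30, 60, 10, 0)


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def test_fisher_trivial_and_derived_values():
    # zero alt margin: only one table is possible
    assert fisher_exact_p(0, 50, 0, 50) == 1.0
    # margins (2,2)/(2,2): enumeration gives P(X >= 1) = 5/6
    assert fisher_exact_p(1, 1, 1, 1) == pytest.approx(5 / 6, abs=1e-15)
    # frozen from the enumeration oracle
    assert fisher_exact_p(10, 90, 0, 100) == pytest.approx(
        fisher_greater_oracle(10, 90, 0, 100), abs=1e-14
    )


def test_fisher_invalid_inputs():
    with pytest.raises(ValueError):
        fisher_exact_p(-1, 5, 0, 5)
    with pytest.raises(ValueError):
        fisher_exact_p(0, 0, 0, 0)


@given(
    ta=st.integers(0, 40), tr=st.integers(0, 40),
    na=st.integers(0, 40), nr=st.integers(0, 40),
)
@settings(max_examples=200, deadline=None)
def test_fisher_matches_oracle_and_scipy(ta, tr, na, nr):
    if ta + tr + na + nr == 0:
        return
    p = fisher_exact_p(ta, tr, na, nr)
    assert 0.0 <= p <= 1.0
    assert p == pytest.approx(fisher_greater_oracle(ta, tr, na, nr), abs=1e-12)
    p_scipy = scipy.stats.fisher_exact([[ta, tr], [na, nr]], alternative="greater")[1]
    assert p == pytest.approx(p_scipy, rel=1e-9, abs=1e-12)


def test_fisher_two_sided_matches_scipy():
    for table in [(3, 7, 1, 9), (10, 2, 2, 10), (0, 5, 5, 0), (4, 4, 4, 4)]:
        p = fisher_exact_p(*table, alternative="two-sided")
        p_scipy = scipy.stats.fisher_exact(
            [table[:2], table[2:]], alternative="two-sided"
        )[1]
        assert p == pytest.approx(p_scipy, rel=1e-9, abs=1e-12)


@given(ta=st.integers(0, 20), tr=st.integers(0, 20), nr=st.integers(1, 30))
@settings(max_examples=100, deadline=None)
def test_fisher_monotone_in_tumor_alt(ta, tr, nr):
    """Adding a tumor alt read can only strengthen one-sided enrichment."""
    p_lo = fisher_exact_p(ta + 1, tr, 0, nr)
    p_hi = fisher_exact_p(ta, tr, 0, nr)
    assert p_lo <= p_hi + 1e-15


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------

def _site(t_alt, t_depth, n_alt, n_depth, **kw):
    return PileupSite.from_counts(
        "chr1", 100, "A", "T", t_alt, t_depth, n_alt, n_depth, **kw
    )


def test_pass_call_example():
    calls = call_site(_site(20, 100, 0, 100))
    assert len(calls) == 1
    v = calls[0]
    assert v.tumor_vaf == pytest.approx(0.20)
    assert v.fisher_p == pytest.approx(fisher_greater_oracle(20, 80, 0, 100), abs=1e-12)
    assert v.fisher_p < 0.05
    assert v.is_pass and not v.failed_criteria


@pytest.mark.parametrize(
    "site,expected_fail",
    [
        (_site(4, 9, 0, 100), "depth"),          # tumor depth 9 < 10
        (_site(3, 30, 0, 100), "variant_depth"),  # alt 3 < 4 (vaf 0.1 still passes)
        (_site(999, 10000, 0, 10000), "tumor_vaf"),  # VAF 0.0999 < 0.10
        (_site(20, 100, 2, 100), "normal_vaf"),   # normal VAF exactly 2%: strict bound
        (_site(4, 20, 0, 20), "fisher_p"),        # p = 0.0530 >= 0.05
    ],
)
def test_single_criterion_failures(site, expected_fail):
    assert call_site(site) == []
    [v] = evaluate_site(site)
    assert v.criterion_flags[expected_fail] is False
    others = set(v.failed_criteria) - {expected_fail}
    assert not others, f"unexpected additional failures: {others}"


@pytest.mark.parametrize(
    "site",
    [
        _site(4, 10, 0, 100),       # depth exactly 10
        _site(4, 30, 0, 100),       # alt exactly 4
        _site(1000, 10000, 0, 10000),  # VAF exactly 0.10
        _site(20, 100, 1, 100),     # normal VAF 1% < 2%
        _site(4, 20, 0, 30),        # p = 0.0210 < 0.05
    ],
)
def test_boundary_values_inclusive(site):
    assert len(call_site(site)) == 1


def test_base_quality_flips_call():
    """Alt support at Q15 counts; at Q14 it is excluded and the call vanishes."""
    def site(q):
        alt = [ReadObservation("T", q, 60, 100) for _ in range(4)]
        ref = [ReadObservation("A", 40, 60, 100) for _ in range(30)]
        nrm = [ReadObservation("A", 40, 60, 100) for _ in range(100)]
        return PileupSite("chr1", 7, "A", alt + ref, nrm)

    assert len(call_site(site(15))) == 1
    assert call_site(site(14)) == []


def test_excluded_reads_never_increase_counts():
    base = _site(20, 100, 0, 100)
    [v0] = call_site(base)
    # add tumor alt reads that fail the MAPQ filter: counts must not grow
    extra = [ReadObservation("T", 40, 10, 100) for _ in range(50)]
    noisy = PileupSite("chr1", 100, "A", base.tumor_obs + extra, base.normal_obs)
    [v1] = call_site(noisy)
    assert v1.tumor_alt_depth == v0.tumor_alt_depth
    assert v1.tumor_depth == v0.tumor_depth


def test_empty_pileup_is_no_call():
    assert call_site(PileupSite("chr1", 1, "A")) == []


def test_multiallelic_site_emits_sorted_alts():
    alt1 = [ReadObservation("G", 40, 60, 100) for _ in range(20)]
    alt2 = [ReadObservation("T", 40, 60, 100) for _ in range(20)]
    ref = [ReadObservation("A", 40, 60, 100) for _ in range(60)]
    nrm = [ReadObservation("A", 40, 60, 100) for _ in range(100)]
    site = PileupSite("chr1", 5, "A", alt2 + alt1 + ref, nrm)
    calls = call_site(site)
    assert [v.alt_allele for v in calls] == ["G", "T"]


def test_cohort_ordering_and_duplicates():
    assert call_cohort([]) == []
    sites = [
        _site(20, 100, 0, 100),
        PileupSite.from_counts("chr1", 50, "C", "G", 20, 100, 0, 100),
        PileupSite.from_counts("chr0", 100, "C", "G", 20, 100, 0, 100),
    ]
    calls = call_cohort(sites)
    assert [(v.chrom, v.pos) for v in calls] == [("chr0", 100), ("chr1", 50), ("chr1", 100)]
    with pytest.raises(RuntimeError):
        call_cohort([sites[0], sites[0]])


def test_raising_thresholds_never_adds_calls():
    sites = [
        PileupSite.from_counts("chr1", 10 * i + 1, "A", "T", t_alt, 100, n_alt, 100)
        for i, (t_alt, n_alt) in enumerate(
            (t, n) for t in (5, 10, 15, 30) for n in (0, 1, 2)
        )
    ]
    base = {v.key() for v in call_cohort(sites)}
    for params in (
        CallingParams(min_tumor_vaf=0.15),
        CallingParams(min_tumor_vaf=0.31),
        CallingParams(max_fisher_p=0.01),
        CallingParams(max_fisher_p=1e-6),
    ):
        stricter = {v.key() for v in call_cohort(sites, params)}
        assert stricter <= base


def test_normalize_alleles():
    assert normalize_alleles(10, "A", "T") == ("A", "T", 10)
    assert normalize_alleles(10, "CAG", "CTG") == ("A", "T", 11)
    assert normalize_alleles(10, "CAA", "CA") == ("CA", "C", 10)


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def test_pileup_tsv_round_trip(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text(
        "chrom\tpos\tref\tbase\tbase_qual\tmapq\tread_len\tn_mismatch\n"
        "chr1\t5\tA\tT\t40\t60\t100\t1\n"
        "chr1\t5\tA\tA\t40\t60\t100\t0\n"
    )
    sites = read_pileup_tsv(p)
    assert list(sites) == [("chr1", 5, "A")]
    assert [o.base for o in sites[("chr1", 5, "A")]] == ["T", "A"]
    bad = tmp_path / "bad.tsv"
    bad.write_text("chrom\tpos\n")
    with pytest.raises(ValueError):
        read_pileup_tsv(bad)


def test_counts_tsv_and_vcf_round_trip(tmp_path):
    counts = tmp_path / "counts.tsv"
    counts.write_text(
        "chrom\tpos\tref\talt\ttumor_alt\ttumor_depth\tnormal_alt\tnormal_depth\n"
        "chr1\t100\tA\tT\t20\t100\t0\t100\n"
        "chr1\t200\tA\tT\t3\t100\t0\t100\n"
    )
    sites = sites_from_counts_tsv(counts)
    calls = call_cohort(sites, emit_all=True)
    assert len(calls) == 2
    vcf_path = tmp_path / "out.vcf"
    write_vcf(calls, vcf_path)
    with pysam.VariantFile(str(vcf_path)) as vcf:
        recs = list(vcf)
    assert len(recs) == 2
    assert recs[0].pos == 100 and recs[0].alts == ("T",)
    assert list(recs[0].filter) == ["PASS"]
    assert recs[0].info["TAD"] == 20
    assert recs[0].info["TVAF"] == pytest.approx(0.2, abs=1e-6)
    assert "variant_depth" in list(recs[1].filter)
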