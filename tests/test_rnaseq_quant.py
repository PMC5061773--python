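"""Region extraction, glocal read mapping with the stated filters, and FPKM."""

import math

import pytest

from tubuliq.ms_match import IsotypeAbundance
from tubuliq.rnaseq_quant import (
    AMBIGUOUS_TIE,
    ASSIGNED,
    FILTERED_MISMATCH,
    UNMAPPED,
    FpkmRecord,
    ReferenceRegion,
    RegionError,
    compute_fpkm,
    concordance_report,
    extract_region,
    map_read,
    map_reads,
    revcomp,
)
from tubuliq.synthetic_data import random_dna, substream


@pytest.fixture(scope="module")
def two_regions():
    rng = substream(42, "regions")
    return [
        ReferenceRegion("TUB15", random_dna(180, rng)),
        ReferenceRegion("TUB16", random_dna(180, rng)),
    ]


def test_extract_region_index_arithmetic():
    rng = substream(1, "tx")
    transcript = random_dna(900, rng)
    region = extract_region(transcript, stop_pos=840, cds_tail_bp=120, utr_bp=80)
    assert region.length_bp == 180
    assert region.sequence == transcript[720:900]


def test_extract_region_truncates_short_transcript_with_warning(caplog):
    transcript = random_dna(150, substream(2, "tx"))
    with caplog.at_level("WARNING"):
        region = extract_region(transcript, stop_pos=150, cds_tail_bp=200, utr_bp=0)
    assert region.length_bp == 150
    assert "truncat" in caplog.text


def test_extract_region_rejects_degenerate_request():
    with pytest.raises(RegionError):
        extract_region("ACGT" * 50, stop_pos=100, cds_tail_bp=0, utr_bp=0)
    with pytest.raises(RegionError):
        extract_region("ACGT" * 100, stop_pos=300, cds_tail_bp=150, utr_bp=100)


def test_perfect_substring_read_is_assigned(two_regions):
    read = two_regions[0].sequence[40:115]
    aln = map_read(read, two_regions, read_id="r1")
    assert aln.status == ASSIGNED
    assert aln.region_id == "TUB15"
    assert aln.mismatches == 0
    assert aln.coverage_fraction == 1.0


def test_reverse_strand_read_is_assigned_unless_stranded(two_regions):
    read = revcomp(two_regions[0].sequence[40:115])
    assert map_read(read, two_regions).status == ASSIGNED
    assert map_read(read, two_regions, stranded=True).status == UNMAPPED


def test_two_mismatches_on_75bp_exceed_the_2_percent_allowance(two_regions):
    read = list(two_regions[0].sequence[40:115])
    for pos in (10, 50):
        read[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[pos]]
    aln = map_read("".join(read), two_regions)
    assert aln.status == FILTERED_MISMATCH
    assert aln.mismatches == 2


def test_read_from_shared_segment_is_an_ambiguous_tie():
    rng = substream(3, "shared")
    shared = random_dna(100, rng)
    regions = [
        ReferenceRegion("TUB1", shared + random_dna(80, rng)),
        ReferenceRegion("TUB2", shared + random_dna(80, rng)),
    ]
    aln = map_read(shared[10:85], regions)
    assert aln.status == AMBIGUOUS_TIE
    assert aln.region_id == ""


def test_short_read_and_empty_region_set_are_errors(two_regions):
    with pytest.raises(RegionError):
        map_read("ACGT", two_regions)
    with pytest.raises(RegionError):
        map_read("A" * 75, [])


def test_fpkm_formula_and_zero_case():
    regions = [ReferenceRegion("TUB15", "ACGT" * 50),
               ReferenceRegion("TUB16", "TTGA" * 50)]
    alignments = [
        # 100 assigned to TUB15, none to TUB16
        *(map_read_stub("TUB15") for _ in range(100)),
    ]
    records = {r.isotype_id: r for r in compute_fpkm(alignments, regions, total_reads=10**6)}
    assert records["TUB15"].fpkm == pytest.approx(500.0)
    assert records["TUB16"].fpkm == 0.0
    halved = {r.isotype_id: r for r in compute_fpkm(alignments, regions, total_reads=2 * 10**6)}
    assert halved["TUB15"].fpkm == pytest.approx(250.0)


def map_read_stub(region_id):
    from tubuliq.rnaseq_quant import ReadAlignment

    return ReadAlignment("r", region_id, 75, 1.0, 0, 75, ASSIGNED)


def test_fpkm_requires_positive_total():
    with pytest.raises(RegionError):
        compute_fpkm([], [ReferenceRegion("TUB15", "ACGT" * 30)], total_reads=0)


def test_statuses_partition_all_reads(two_regions):
    rng = substream(4, "reads")
    reads = []
    for i in range(50):
        start = int(rng.integers(0, 100))
        reads.append((f"r{i}", two_regions[i % 2].sequence[start : start + 75]))
    reads.append(("junk", random_dna(75, rng)))
    alignments = map_reads(reads, two_regions)
    assert len(alignments) == len(reads)
    assert all(a.status in {ASSIGNED, FILTERED_MISMATCH, "filtered_coverage",
                            AMBIGUOUS_TIE, UNMAPPED} for a in alignments)


def test_tightening_filters_never_increases_assignments(two_regions):
    rng = substream(5, "reads")
    reads = []
    for i in range(60):
        start = int(rng.integers(0, 100))
        seq = list(two_regions[0].sequence[start : start + 75])
        for _ in range(int(rng.integers(0, 3))):
            p = int(rng.integers(0, 75))
            seq[p] = "ACGT"[int(rng.integers(0, 4))]
        reads.append((f"r{i}", "".join(seq)))

    def n_assigned(**kwargs):
        return sum(a.status == ASSIGNED for a in map_reads(reads, two_regions, **kwargs))

    base = n_assigned()
    assert n_assigned(min_coverage=0.99) <= base
    assert n_assigned(max_mismatch_frac=0.01) <= base
    assert n_assigned(max_mismatch_frac=0.05) >= base


def _abundances(values):
    return [IsotypeAbundance(iso, iso[:3], v, math.nan) for iso, v in values.items()]


def _fpkms(values):
    return [FpkmRecord(iso, 0, 180, v) for iso, v in values.items()]


def test_proportional_profiles_are_concordant_without_flags():
    prot = {f"TUB{i}": 10.0 * i for i in range(1, 9)}
    tx = {f"TUB{i}": 3.0 * i for i in range(1, 9)}
    report = concordance_report(_abundances(prot), _fpkms(tx))
    assert report.spearman["TUB"] == pytest.approx(1.0)
    assert report.flagged == ()


def test_suppressed_isotype_is_flagged_discordant():
    prot = {f"TUB{i}": 10.0 * i for i in range(1, 9)}
    tx = {f"TUB{i}": 3.0 * i for i in range(1, 9)}
    prot["TUB8"] = prot["TUB2"] / 10  # highest transcript, protein below median
    report = concordance_report(_abundances(prot), _fpkms(tx))
    assert "TUB8" in report.flagged


def test_too_few_shared_isotypes_omits_correlation(caplog):
    prot = {"TUB1": 5.0, "TUB2": 4.0}
    tx = {"TUB1": 3.0, "TUB2": 6.0}
    with caplog.at_level("WARNING"):
        report = concordance_report(_abundances(prot), _fpkms(tx))
    assert report.spearman["TUB"] is None
    assert "omitted" in caplog.text
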