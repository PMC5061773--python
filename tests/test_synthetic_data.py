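"""Ground-truth generators: determinism, statistical structure, truth tables."""

import io
import math

import numpy as np
import pytest

from tubuliq.catalog import Family, IsotypeRecord
from tubuliq.ptm_scan import DETECTED, default_modifications, enumerate_isoforms, scan_spectrum
from tubuliq.rnaseq_quant import ReferenceRegion
from tubuliq.synthetic_data import (
    PtmSpike,
    ReadParams,
    SimulationError,
    SimulationManifest,
    SpectrumParams,
    default_manifest,
    random_dna,
    random_manifest,
    simulate_family,
    simulate_reads,
    simulate_spectrum,
    substream,
    tile_reads,
    write_fastq,
)


def _fastq_bytes(reads):
    buf = io.StringIO()
    for r in reads:
        buf.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
    return buf.getvalue()


def test_same_seed_gives_identical_reads_and_spectrum(pd_reporters):
    region = ReferenceRegion("TUA1", random_dna(180, substream(0, "r")))
    args = ([region], {"TUA1": 1.0}, 200, 75, 0.01)
    r1, t1 = simulate_reads(*args, seed=5)
    r2, t2 = simulate_reads(*args, seed=5)
    assert _fastq_bytes(r1) == _fastq_bytes(r2)
    assert t1.equals(t2)
    s1, _ = simulate_spectrum(pd_reporters, {"TUA1": 1.0}, (), SpectrumParams(), seed=5)
    s2, _ = simulate_spectrum(pd_reporters, {"TUA1": 1.0}, (), SpectrumParams(), seed=5)
    assert np.array_equal(s1.mz, s2.mz) and np.array_equal(s1.intensity, s2.intensity)


def test_zero_divergence_is_identity(pd_catalog):
    mutated, truth = simulate_family(pd_catalog, divergence=0.0, seed=3)
    assert truth == []
    assert [r.protein_seq for r in mutated] == [r.protein_seq for r in pd_catalog]


def test_divergence_concentrates_in_the_cterminal_tail():
    rng = substream(13, "prot")
    records = [
        IsotypeRecord(
            id=f"TUA{i}", family=Family.TUA, species_tag="sim",
            protein_seq="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=500)),
            cterm_span=(401, 500),
        )
        for i in range(1, 9)
    ]
    _, truth = simulate_family(records, divergence=0.03, seed=14)
    core = sum(1 for s in truth if s.kind == "aa" and s.position <= 400)
    tail = sum(1 for s in truth if s.kind == "aa" and s.position > 400)
    core_rate = core / (8 * 400)
    tail_rate = tail / (8 * 100)
    assert 0.02 <= core_rate <= 0.04      # ~3% in the conserved core
    assert 0.11 <= tail_rate <= 0.19      # ~15% in the hypervariable tail


def test_read_origins_follow_the_multinomial_mixture():
    rng = substream(15, "regions")
    regions = [ReferenceRegion(f"TUB{i}", random_dna(180, rng)) for i in (1, 2, 4)]
    props = {"TUB1": 0.5, "TUB2": 0.3, "TUB4": 0.2}
    _, truth = simulate_reads(regions, props, n_reads=10000, read_length=75,
                              error_rate=0.0, seed=16)
    counts = truth["origin"].value_counts()
    for iso, p in props.items():
        sigma = math.sqrt(10000 * p * (1 - p))
        assert abs(counts[iso] - 10000 * p) < 3 * sigma


def test_error_free_single_origin_reads_are_exact_substrings():
    region = ReferenceRegion("TUA1", random_dna(180, substream(17, "r")))
    reads, truth = simulate_reads([region], {"TUA1": 1.0}, n_reads=50,
                                  read_length=75, error_rate=0.0, seed=18)
    for r, (_, row) in zip(reads, truth.iterrows()):
        assert r.sequence == region.sequence[row.start : row.start + 75]


def test_read_length_longer_than_region_is_an_error():
    region = ReferenceRegion("TUA1", random_dna(60, substream(19, "r")))
    with pytest.raises(SimulationError):
        simulate_reads([region], {"TUA1": 1.0}, 10, 75, 0.0, seed=1)


def test_tile_reads_cover_both_ends():
    seq = random_dna(300, substream(20, "t"))
    reads = tile_reads(seq, 75, 7)
    assert reads[0].sequence == seq[:75]
    assert reads[-1].sequence == seq[-75:]


def test_noise_only_spectrum_yields_no_detections(pd_reporters):
    spec, truth = simulate_spectrum(pd_reporters, {}, (), SpectrumParams(), seed=21)
    assert (truth["label"] == "noise").all()
    isoforms = enumerate_isoforms(pd_reporters, default_modifications())
    assert all(v.status != DETECTED for v in scan_spectrum(spec, isoforms))


def test_noise_peaks_keep_minimum_spacing(pd_reporters):
    spec, _ = simulate_spectrum(pd_reporters, {}, (), SpectrumParams(), seed=22)
    assert np.all(np.diff(spec.mz) >= 1.5 - 1e-9)


def test_dey_spike_is_detected_with_expected_apex_ratio(pd_reporters):
    spike = PtmSpike("TUA1", "dEY", 0.2)
    spec, truth = simulate_spectrum(pd_reporters, {"TUA1": 1.0}, (spike,),
                                    SpectrumParams(), seed=23)
    apex = dict(zip(truth["label"], truth["apex"]))
    assert apex["TUA1"] / apex["TUA1:dEY"] == pytest.approx(5.0)
    isoforms = enumerate_isoforms(pd_reporters, default_modifications())
    detected = {v.isoform.label for v in scan_spectrum(spec, isoforms)
                if v.status == DETECTED and v.isoform.modification.name != "unmodified"}
    assert detected == {"TUA1:dEY"}


def test_inapplicable_spike_is_rejected(pd_reporters):
    # TUA5's reporter ends in Met and cannot be detyrosinated
    with pytest.raises(SimulationError):
        simulate_spectrum(pd_reporters, {"TUA5": 1.0},
                          (PtmSpike("TUA5", "dY", 0.2),), SpectrumParams(), seed=1)


def test_manifest_json_round_trip():
    manifest = default_manifest(seed=4)
    again = SimulationManifest.from_json(manifest.to_json())
    assert again == manifest
    assert again.hash == manifest.hash


def test_manifest_validates_proportions_and_stoichiometry():
    with pytest.raises(SimulationError):
        SimulationManifest(seed=0, isotype_proportions={"TUA1": 0.5})
    with pytest.raises(SimulationError):
        SimulationManifest(seed=0, isotype_proportions={"TUA1": 1.2})
    with pytest.raises(SimulationError):
        PtmSpike("TUA1", "dEY", 1.5)


def test_random_manifest_is_valid_and_reproducible():
    m1 = random_manifest(seed=9)
    m2 = random_manifest(seed=9)
    assert m1 == m2
    fam_sums = {"TUA": 0.0, "TUB": 0.0}
    for iso, p in m1.isotype_proportions.items():
        assert p >= 0.05
        fam_sums[iso[:3]] += p
    assert fam_sums["TUA"] == pytest.approx(1.0, abs=1e-9)
    assert fam_sums["TUB"] == pytest.approx(1.0, abs=1e-9)
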