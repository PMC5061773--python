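"""Synthetic ground-truth data: paralog families, stranded reads, MALDI spectra.

Everything the pipeline consumes can be generated here with known truth:

* paralog transcript families that are near-identical over a shared coding
  core and divergent over the C-terminal tail / 3'-UTR (the structure that
  makes region-restricted read assignment work at all);
* stranded short reads drawn from a mixture of regions with i.i.d.
  substitution errors, plus a per-read origin table;
* MALDI peak lists with 4-peak isotopic envelopes at reporter masses
  (apex intensity proportional to abundance, geometric decay), optional
  PTM satellite envelopes at a configurable stoichiometry, and noise
  peaks that never form envelopes (a minimum spacing of 1.5 Da is
  enforced, so the envelope check is a meaningful discriminator — a
  deliberate simulator idealization).

A single integer seed keys one run; per-stage substreams are derived
deterministically so stages can be re-run in isolation.  Output files
carry the manifest hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ptm_scan
from .catalog import IsotypeRecord, ReporterPeptide, family_of
from .mass_core import MassTable, reporters_from_catalog
from .ms_match import ISOTOPE_SPACING, PeakList
from .rnaseq_quant import ReferenceRegion, extract_region

log = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


def substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from the run seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(stage.encode())])
    )


# ---------------------------------------------------------------------------
# Manifest

@dataclass(frozen=True)
class PtmSpike:
    isotype: str
    modification: str  # dY | dEY | glu+n | acetyl
    stoichiometry: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.stoichiometry <= 1.0):
            raise SimulationError("spike stoichiometry must be in [0, 1]")


@dataclass(frozen=True)
class ReadParams:
    """Read-set size and error model.

    20,000 reads over the tubulin regions reflects the very high tubulin
    transcript abundance in developing xylem and keeps multinomial
    sampling noise on a 5% isotype well under the pipeline's own error;
    0.5% substitution errors and 75 bp reads are typical short-read values.
    """

    n_reads: int = 20000
    read_length: int = 75
    error_rate: float = 0.005


@dataclass(frozen=True)
class SpectrumParams:
    n_noise_peaks: int = 50
    noise_mz_range: tuple[float, float] = (2900.0, 4400.0)
    intensity_scale: float = 1000.0
    envelope_decay: float = 0.65
    noise_intensity: float = 15.0


@dataclass(frozen=True)
class SimulationManifest:
    seed: int
    isotype_proportions: Mapping[str, float]
    ptm_spikes: tuple[PtmSpike, ...] = ()
    read_params: ReadParams = field(default_factory=ReadParams)
    spectrum_params: SpectrumParams = field(default_factory=SpectrumParams)

    def __post_init__(self) -> None:
        fam_sums: dict[str, float] = {}
        for iso, p in self.isotype_proportions.items():
            if not (0.0 <= p <= 1.0):
                raise SimulationError(f"proportion for {iso} outside [0, 1]")
            fam_sums[family_of(iso).value] = fam_sums.get(family_of(iso).value, 0.0) + p
        for fam, s in fam_sums.items():
            if abs(s - 1.0) > 1e-9:
                raise SimulationError(f"{fam} proportions sum to {s}, expected 1")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["isotype_proportions"] = dict(self.isotype_proportions)
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimulationManifest":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            isotype_proportions=d["isotype_proportions"],
            ptm_spikes=tuple(PtmSpike(**s) for s in d.get("ptm_spikes", ())),
            read_params=ReadParams(**d.get("read_params", {})),
            spectrum_params=SpectrumParams(
                **{k: tuple(v) if k == "noise_mz_range" else v
                   for k, v in d.get("spectrum_params", {}).items()}
            ),
        )

    @property
    def hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:10]


def default_manifest(seed: int = 0) -> SimulationManifest:
    """Xylem-like study conditions: a few dominant isotypes per family.

    Proportions echo the observed profile shape (TUA1 and TUA5 dominating
    the TUA pool; TUB15/TUB16 the TUB pool) without copying any measured
    value; no PTM spikes, i.e. the null-PTM condition.
    """
    proportions = {
        "TUA1": 0.35, "TUA5": 0.30, "TUA6": 0.15, "TUA2": 0.12, "TUA8": 0.08,
        "TUB15": 0.35, "TUB16": 0.25, "TUB17": 0.15, "TUB18": 0.15, "TUB1": 0.10,
    }
    return SimulationManifest(seed=seed, isotype_proportions=proportions)


#: Isotypes whose reporter masses are not resolvable from another isotype's
#: at MALDI-TOF tolerance (TUA4/TUA5 differ by 0.037 Da; TUB3 and TUB20
#: have identical residue composition).  Mixture-recovery studies sample
#: from the resolvable pool; degeneracy handling is exercised separately.
MASS_DEGENERATE = frozenset({"TUA4", "TUB3"})


def random_manifest(
    seed: int,
    n_per_family: int = 5,
    min_proportion: float = 0.05,
    **kwargs,
) -> SimulationManifest:
    """A random mixture manifest: n isotypes per family, Dirichlet
    proportions floored at ``min_proportion`` (then renormalized)."""
    rng = substream(seed, "manifest")
    proportions: dict[str, float] = {}
    pools = {
        "TUA": [f"TUA{i}" for i in range(1, 9) if f"TUA{i}" not in MASS_DEGENERATE],
        "TUB": [f"TUB{i}" for i in range(1, 21) if f"TUB{i}" not in MASS_DEGENERATE],
    }
    for fam, pool in pools.items():
        chosen = sorted(rng.choice(pool, size=n_per_family, replace=False))
        # floor + scaled Dirichlet keeps every proportion >= min_proportion
        p = min_proportion + (1.0 - n_per_family * min_proportion) * rng.dirichlet(
            np.full(n_per_family, 2.0))
        p[-1] = 1.0 - p[:-1].sum()
        for iso, pi in zip(chosen, p):
            proportions[iso] = float(pi)
    return SimulationManifest(seed=seed, isotype_proportions=proportions, **kwargs)


# ---------------------------------------------------------------------------
# Sequence-family simulation

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}

_NT = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """One random synonymous coding sequence for a protein."""
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_NT, size=n))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator,
                    alphabet: np.ndarray = _NT) -> tuple[str, list[tuple[int, str, str]]]:
    """Point-substitute each position i.i.d. at ``rate``; returns (seq, log).

    The log lists (1-based position, ref, alt) for every substitution.
    """
    if rate <= 0:
        return seq, []
    chars = list(seq)
    subs = []
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = [c for c in alphabet if c != chars[i]]
        alt = choices[rng.integers(len(choices))]
        subs.append((int(i) + 1, chars[i], alt))
        chars[i] = alt
    return "".join(chars), subs


@dataclass(frozen=True)
class Substitution:
    record_id: str
    kind: str  # "aa" | "nt"
    position: int  # 1-based
    ref: str
    alt: str


def simulate_family(
    records: Sequence[IsotypeRecord],
    divergence: float,
    seed: int,
    cterm_factor: float = 5.0,
) -> tuple[list[IsotypeRecord], list[Substitution]]:
    """Derive a mutated isotype family with divergence concentrated in the tail.

    Protein positions outside the C-terminal span mutate at ``divergence``;
    positions inside the span — and the entire nucleotide region, which is
    C-terminus + 3'-UTR by construction — mutate at ``cterm_factor`` times
    that rate (the cores of real paralogs are 88-98% identical while the
    tails are hypervariable).  The truth log lists every substitution.
    """
    if not (0.0 <= divergence <= 0.1):
        raise SimulationError("divergence must be within [0, 0.1]")
    rng = substream(seed, "family")
    tail_rate = min(cterm_factor * divergence, 1.0)
    out_records: list[IsotypeRecord] = []
    truth: list[Substitution] = []
    for rec in records:
        start, end = rec.cterm_span
        full = len(rec.protein_seq) >= end
        chars = list(rec.protein_seq)
        for i in range(len(chars)):
            pos1 = i + 1
            in_tail = (start <= pos1 <= end) if full else True
            rate = tail_rate if in_tail else divergence
            if rng.random() < rate:
                choices = [c for c in _AA if c != chars[i]]
                alt = choices[rng.integers(len(choices))]
                truth.append(Substitution(rec.id, "aa", pos1, chars[i], alt))
                chars[i] = alt
        nt = rec.nt_region
        if nt is not None:
            nt, subs = mutate_sequence(nt, tail_rate, rng)
            truth.extend(Substitution(rec.id, "nt", p, r, a) for p, r, a in subs)
        out_records.append(replace(rec, protein_seq="".join(chars), nt_region=nt,
                                   printed_mh=None))
    return out_records, truth


@dataclass(frozen=True)
class Transcript:
    isotype_id: str
    sequence: str
    stop_pos: int  # 1-based last coding base


def synthesize_transcripts(
    records: Sequence[IsotypeRecord],
    seed: int,
    core_len: int = 300,
    utr_len: int = 90,
) -> dict[str, Transcript]:
    """Build paralog transcripts: shared per-family core + reporter tail + UTR.

    The coding core is identical across a family (the near-identity that
    defeats naive read mapping); the reporter region is reverse-translated
    with per-isotype random synonymous codons and the 3'-UTR is random per
    isotype, so the extracted reference regions are mutually diagnostic.
    """
    rng = substream(seed, "transcripts")
    cores = {fam: random_dna(core_len, rng) for fam in ("TUA", "TUB")}
    transcripts = {}
    for rec in sorted(records, key=lambda r: r.id):
        cds = cores[rec.family.value] + reverse_translate(rec.reporter_sequence, rng) + "TAA"
        utr = random_dna(utr_len, rng)
        transcripts[rec.id] = Transcript(rec.id, cds + utr, stop_pos=len(cds))
    return transcripts


def regions_from_transcripts(
    transcripts: Mapping[str, Transcript],
    cds_tail_bp: int = 90,
    utr_bp: int = 90,
) -> list[ReferenceRegion]:
    return [
        extract_region(t.sequence, t.stop_pos, cds_tail_bp, utr_bp, isotype_id=t.isotype_id)
        for t in sorted(transcripts.values(), key=lambda t: t.isotype_id)
    ]


# ---------------------------------------------------------------------------
# Read simulation

@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    quality: str


def simulate_reads(
    regions: Sequence[ReferenceRegion],
    proportions: Mapping[str, float],
    n_reads: int,
    read_length: int,
    error_rate: float,
    seed: int,
    tag: str = "sim",
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Forward-strand reads from a mixture of regions, with an origin table.

    Origins are multinomial in the (renormalized) proportions; start
    positions are uniform within each region; substitution errors are
    i.i.d. per base at ``error_rate``.
    """
    rng = substream(seed, "reads")
    keyed = {r.isotype_id: r for r in regions}
    ids = [i for i in sorted(proportions) if proportions[i] > 0 and i in keyed]
    if not ids:
        raise SimulationError("no region with positive proportion")
    short = [i for i in ids if keyed[i].length_bp < read_length]
    if short:
        raise SimulationError(f"read_length exceeds region length for {short}")
    weights = np.array([proportions[i] for i in ids], dtype=float)
    weights /= weights.sum()

    origins = rng.choice(len(ids), size=n_reads, p=weights)
    reads: list[FastqRead] = []
    rows = []
    for n, oi in enumerate(origins):
        region = keyed[ids[oi]]
        start = int(rng.integers(region.length_bp - read_length + 1))
        seq = region.sequence[start : start + read_length]
        seq, _ = mutate_sequence(seq, error_rate, rng)
        read_id = f"{tag}:{n}"
        reads.append(FastqRead(read_id, seq, "I" * read_length))
        rows.append((read_id, ids[oi], start, "+"))
    truth = pd.DataFrame(rows, columns=["read_id", "origin", "start", "strand"])
    return reads, truth


def tile_reads(sequence: str, read_length: int, stride: int,
               tag: str = "tile") -> list[FastqRead]:
    """Error-free reads tiling a sequence end to end (both ends included)."""
    starts = list(range(0, len(sequence) - read_length + 1, stride))
    last = len(sequence) - read_length
    if starts[-1] != last:
        starts.append(last)
    return [
        FastqRead(f"{tag}:{i}", sequence[s : s + read_length], "I" * read_length)
        for i, s in enumerate(starts)
    ]


def write_fastq(reads: Sequence[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[FastqRead]:
    from Bio import SeqIO

    return [
        FastqRead(rec.id, str(rec.seq).upper(),
                  "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


# ---------------------------------------------------------------------------
# Spectrum simulation

_MOD_BY_NAME = {
    "dY": ptm_scan.detyrosination,
    "dEY": ptm_scan.nontyrosination,
    "acetyl": ptm_scan.acetylation,
}


def _lookup_modification(name: str) -> ptm_scan.Modification:
    if name in _MOD_BY_NAME:
        return _MOD_BY_NAME[name]()
    if name.startswith("glu+"):
        return ptm_scan.glutamylation(int(name.split("+")[1]))
    raise SimulationError(f"unknown modification {name!r}")


def simulate_spectrum(
    reporters: Sequence[ReporterPeptide],
    proportions: Mapping[str, float],
    ptm_spikes: Sequence[PtmSpike],
    params: SpectrumParams,
    seed: int,
    source_id: str = "sim",
) -> tuple[PeakList, pd.DataFrame]:
    """A MALDI peak list from a known isotype mixture with optional PTM spikes.

    Each isotype with proportion > 0 contributes a 4-peak envelope at its
    reporter MH+ (apex = intensity_scale x proportion, geometric decay);
    each spike contributes a satellite envelope at the modification's mass
    offset with apex scaled by stoichiometry.  Noise peaks are uniform in
    m/z at >= 1.5 Da spacing from every other peak and carry no envelope.
    """
    rng = substream(seed, "spectrum")
    keyed = {r.isotype_id: r for r in reporters}
    peaks: list[tuple[float, float]] = []
    rows = []

    def add_envelope(mono: float, apex: float, label: str) -> None:
        for k in range(4):
            peaks.append((mono + k * ISOTOPE_SPACING, apex * params.envelope_decay**k))
        rows.append((label, mono, apex))

    for iso in sorted(proportions):
        p = proportions[iso]
        if p <= 0:
            continue
        if iso not in keyed:
            raise SimulationError(f"no reporter for isotype {iso}")
        add_envelope(keyed[iso].theoretical_mh, params.intensity_scale * p, iso)

    for spike in ptm_spikes:
        if spike.isotype not in keyed:
            raise SimulationError(f"no reporter for spiked isotype {spike.isotype}")
        base = keyed[spike.isotype]
        mod = _lookup_modification(spike.modification)
        if not mod.applies_to(base.sequence):
            raise SimulationError(
                f"{spike.modification} does not apply to the {spike.isotype} "
                f"reporter ({base.sequence[-3:]!r} terminus)"
            )
        apex = params.intensity_scale * proportions.get(spike.isotype, 0.0) * spike.stoichiometry
        if apex > 0:
            add_envelope(base.theoretical_mh + mod.mass_delta, apex,
                         f"{spike.isotype}:{mod.name}")

    lo, hi = params.noise_mz_range
    placed = sorted(mz for mz, _ in peaks)
    n_placed = 0
    attempts = 0
    while n_placed < params.n_noise_peaks and attempts < 50 * params.n_noise_peaks:
        attempts += 1
        mz = float(rng.uniform(lo, hi))
        j = int(np.searchsorted(placed, mz))
        if (j > 0 and mz - placed[j - 1] < 1.5) or (j < len(placed) and placed[j] - mz < 1.5):
            continue
        inten = float(rng.uniform(0.5, 1.5) * params.noise_intensity)
        peaks.append((mz, inten))
        placed.insert(j, mz)
        rows.append(("noise", mz, inten))
        n_placed += 1

    # merge exactly coincident peaks (mass-degenerate reporters)
    merged: dict[float, float] = {}
    for mz, inten in peaks:
        key = round(mz, 6)
        merged[key] = merged.get(key, 0.0) + inten
    peaklist = PeakList.from_pairs(merged.items(), source_id=source_id)
    truth = pd.DataFrame(rows, columns=["label", "mz", "apex"])
    return peaklist, truth


# ---------------------------------------------------------------------------
# Whole-dataset generation

@dataclass(frozen=True)
class SimulatedDataset:
    manifest: SimulationManifest
    regions: list[ReferenceRegion]
    reads: list[FastqRead]
    read_truth: pd.DataFrame
    spectrum: PeakList
    spectrum_truth: pd.DataFrame
    reporters: list[ReporterPeptide]


def simulate_dataset(
    manifest: SimulationManifest,
    records: Sequence[IsotypeRecord],
    table: MassTable | None = None,
) -> SimulatedDataset:
    """Generate all pipeline inputs for one manifest, in memory."""
    reporters = reporters_from_catalog(records, table=table)
    transcripts = synthesize_transcripts(records, seed=manifest.seed)
    regions = regions_from_transcripts(transcripts)
    reads, read_truth = simulate_reads(
        regions, manifest.isotype_proportions,
        n_reads=manifest.read_params.n_reads,
        read_length=manifest.read_params.read_length,
        error_rate=manifest.read_params.error_rate,
        seed=manifest.seed, tag=f"sim{manifest.hash}",
    )
    spectrum, spectrum_truth = simulate_spectrum(
        reporters, manifest.isotype_proportions, manifest.ptm_spikes,
        manifest.spectrum_params, seed=manifest.seed,
        source_id=f"sim{manifest.hash}",
    )
    return SimulatedDataset(
        manifest=manifest, regions=regions, reads=reads, read_truth=read_truth,
        spectrum=spectrum, spectrum_truth=spectrum_truth, reporters=reporters,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    mhash = dataset.manifest.hash
    with open(outdir / "manifest.json", "w") as fh:
        fh.write(dataset.manifest.to_json() + "\n")
    with open(outdir / "regions.fa", "w") as fh:
        for r in dataset.regions:
            fh.write(f">{r.isotype_id} manifest={mhash}\n{r.sequence}\n")
    write_fastq(dataset.reads, outdir / "reads.fq")
    dataset.spectrum.to_tsv(outdir / "spectrum.tsv", header_comment=f"manifest={mhash}")
    dataset.read_truth.to_csv(outdir / "truth" / "reads.tsv", sep="\t", index=False)
    dataset.spectrum_truth.to_csv(outdir / "truth" / "spectrum.tsv", sep="\t", index=False)
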