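"""Paralog-aware transcript quantification on hypervariable C-terminal regions.

Tubulin paralogs are nearly identical over most of their coding sequence,
so reads are quantified against short (<= 200 bp) reference regions that
span the hypervariable C-terminus plus part of the 3'-UTR — the only
stretch where near-identical paralogs can be told apart.  Each read is
glocally aligned (read-global, region-local) to every region on both
strands, filtered by >95% read coverage and a 2% mismatch allowance
(gaps count as edit operations), and assigned to the unique best-scoring
region; equal top scores on different regions are discarded as ambiguous
rather than randomly assigned, since random assignment would fabricate
resolution between paralogs.  Abundance is reported as FPKM: fragments per
kilobase of region per million total reads.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from scipy import stats

from .catalog import family_of
from .ms_match import IsotypeAbundance

log = logging.getLogger(__name__)

ASSIGNED = "assigned"
FILTERED_COVERAGE = "filtered_coverage"
FILTERED_MISMATCH = "filtered_mismatch"
AMBIGUOUS_TIE = "ambiguous_tie"
UNMAPPED = "unmapped"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RegionError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceRegion:
    isotype_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise RegionError(f"{self.isotype_id}: empty region")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise RegionError(f"{self.isotype_id}: non-ACGT characters {sorted(bad)}")
        if len(self.sequence) > 200:
            raise RegionError(f"{self.isotype_id}: region exceeds 200 bp")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    region_id: str  # "" when no single region applies
    aligned_length: int
    coverage_fraction: float
    mismatches: int
    score: int
    status: str


@dataclass(frozen=True)
class FpkmRecord:
    isotype_id: str
    assigned_fragments: int
    length_bp: int
    fpkm: float


def extract_region(
    transcript: str,
    stop_pos: int,
    cds_tail_bp: int,
    utr_bp: int,
    isotype_id: str = "",
) -> ReferenceRegion:
    """Cut the C-terminal reference region out of a transcript.

    ``stop_pos`` is the 1-based position of the last coding base (end of
    the stop codon); the region is the last ``cds_tail_bp`` coding bases
    followed by the first ``utr_bp`` UTR bases, truncated at the
    transcript's ends with a warning.
    """
    if cds_tail_bp + utr_bp > 200:
        raise RegionError("cds_tail_bp + utr_bp must not exceed 200")
    if cds_tail_bp + utr_bp == 0:
        raise RegionError("empty region requested (cds_tail_bp = utr_bp = 0)")
    if not (1 <= stop_pos <= len(transcript)):
        raise RegionError(f"stop position {stop_pos} outside transcript")
    start = stop_pos - cds_tail_bp
    if start < 0:
        log.warning(
            "%s: transcript CDS shorter than %d bp tail; truncating",
            isotype_id or "region", cds_tail_bp,
        )
        start = 0
    end = min(stop_pos + utr_bp, len(transcript))
    if stop_pos + utr_bp > len(transcript):
        log.warning(
            "%s: transcript ends %d bp into the requested UTR window",
            isotype_id or "region", len(transcript) - stop_pos,
        )
    return ReferenceRegion(isotype_id=isotype_id, sequence=transcript[start:end])


# ---------------------------------------------------------------------------
# Glocal read mapping

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _parse_cigar(cigar: str, t_start: int = 1, t_end: int = -1,
                 t_len: int = 0) -> tuple[int, int, int, int, int]:
    """Return (matches, internal_edits, leading_unaligned, trailing_unaligned,
    score) for an extended glocal cigar.

    Read bases hanging off the end of the region are unaligned, not errors.
    edlib represents such overhangs either as terminal insertion runs or —
    when the alignment is jammed against a region boundary — as terminal
    mismatch runs, so leading I/X runs are trimmed while the alignment
    touches the region start (``t_start == 0``) and trailing ones while it
    touches the region end.  Score uses +1 match, -1 mismatch, gap open -2
    / extend -1 on internal gap runs.
    """
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    lead = trail = 0
    at_start = t_start == 0
    while ops and (ops[0][1] == "I" or (ops[0][1] == "X" and at_start)):
        n, op = ops.pop(0)
        lead += n
        if op == "X":
            at_start = False  # an X run consumes region bases
    at_end = t_end == t_len - 1
    while ops and (ops[-1][1] == "I" or (ops[-1][1] == "X" and at_end)):
        n, op = ops.pop()
        trail += n
        if op == "X":
            at_end = False
    matches = edits = 0
    score = 0
    for n, op in ops:
        if op == "=":
            matches += n
            score += n
        elif op == "X":
            edits += n
            score -= n
        else:  # I or D internal gap run
            edits += n
            score -= 2 + (n - 1)
    return matches, edits, lead, trail, score


def glocal_alignment_summary(query: str, target: str) -> tuple[int, int]:
    """(aligned query length, internal edit count) of the best glocal
    alignment of ``query`` into ``target``; terminal query overhangs are
    unaligned rather than counted as errors."""
    res = edlib.align(query, target, mode="HW", task="path")
    (t_start, t_end) = res["locations"][0]
    matches, edits, lead, trail, _ = _parse_cigar(res["cigar"], t_start, t_end,
                                                  len(target))
    return len(query) - lead - trail, edits


def _align_candidate(read: str, region: ReferenceRegion, max_edits_cap: int):
    res = edlib.align(read, region.sequence, mode="HW", task="path", k=max_edits_cap)
    if res["editDistance"] < 0:
        return None
    t_start, t_end = res["locations"][0]
    matches, edits, lead, trail, score = _parse_cigar(
        res["cigar"], t_start, t_end, len(region.sequence))
    aligned = len(read) - lead - trail
    return {
        "region": region,
        "aligned_length": aligned,
        "coverage": aligned / len(read),
        "mismatches": edits,
        "score": score,
    }


def map_read(
    read: str,
    regions: Sequence[ReferenceRegion],
    max_mismatch_frac: float = 0.02,
    min_coverage: float = 0.95,
    stranded: bool = False,
    read_id: str = "",
    candidate_regions: Sequence[ReferenceRegion] | None = None,
) -> ReadAlignment:
    """Glocal-align one read against every region and classify it.

    Mismatch allowance is proportional: mismatches (including internal
    gaps) must not exceed floor(max_mismatch_frac * read length).
    Coverage must strictly exceed ``min_coverage``.  The unique top-score
    survivor is assigned; ties across regions are discarded as ambiguous.
    """
    if not regions:
        raise RegionError("no reference regions")
    if len(read) < 20:
        raise RegionError("read shorter than 20 bp")
    read = read.upper()
    allowance = math.floor(max_mismatch_frac * len(read))
    cap = max(allowance, int(0.35 * len(read)))  # generous cap: beyond this = unmapped

    search = candidate_regions if candidate_regions is not None else regions
    candidates = []
    for region in search:
        for strand, seq in (("+", read),) if stranded else (("+", read), ("-", revcomp(read))):
            cand = _align_candidate(seq, region, cap)
            if cand is not None:
                cand["strand"] = strand
                candidates.append(cand)

    if not candidates:
        return ReadAlignment(read_id, "", 0, 0.0, 0, 0, UNMAPPED)

    survivors = [
        c for c in candidates
        if c["coverage"] > min_coverage and c["mismatches"] <= allowance
    ]
    if survivors:
        best_score = max(c["score"] for c in survivors)
        top = [c for c in survivors if c["score"] == best_score]
        top_regions = {c["region"].isotype_id for c in top}
        c = min(top, key=lambda c: (c["region"].isotype_id, c["strand"]))
        if len(top_regions) > 1:
            return ReadAlignment(
                read_id, "", c["aligned_length"], c["coverage"],
                c["mismatches"], c["score"], AMBIGUOUS_TIE,
            )
        return ReadAlignment(
            read_id, c["region"].isotype_id, c["aligned_length"], c["coverage"],
            c["mismatches"], c["score"], ASSIGNED,
        )

    # No survivor: report the least-edited candidate's failure mode.
    c = min(candidates, key=lambda c: (c["mismatches"], -c["coverage"]))
    status = FILTERED_MISMATCH if c["coverage"] > min_coverage else FILTERED_COVERAGE
    return ReadAlignment(
        read_id, c["region"].isotype_id, c["aligned_length"], c["coverage"],
        c["mismatches"], c["score"], status,
    )


def _seed_index(regions: Sequence[ReferenceRegion], seed_len: int):
    index: dict[str, set[int]] = {}
    for i, region in enumerate(regions):
        for strand_seq in (region.sequence, revcomp(region.sequence)):
            for j in range(len(strand_seq) - seed_len + 1):
                index.setdefault(strand_seq[j : j + seed_len], set()).add(i)
    return index


def map_reads(
    reads: Iterable[tuple[str, str]],
    regions: Sequence[ReferenceRegion],
    max_mismatch_frac: float = 0.02,
    min_coverage: float = 0.95,
    stranded: bool = False,
    seed_len: int = 15,
) -> list[ReadAlignment]:
    """Map many (read_id, sequence) pairs; exact-seed prefilter for speed.

    A read passing the 2% mismatch allowance necessarily shares a long
    exact stretch with its region, so regions sharing no ``seed_len``-mer
    with the read need not be aligned at all.
    """
    index = _seed_index(regions, seed_len)
    out = []
    for read_id, seq in reads:
        seq = seq.upper()
        cand_idx: set[int] = set()
        for j in range(0, len(seq) - seed_len + 1, 4):
            cand_idx |= index.get(seq[j : j + seed_len], set())
        if not cand_idx:
            out.append(ReadAlignment(read_id, "", 0, 0.0, 0, 0, UNMAPPED))
            continue
        out.append(
            map_read(
                seq, regions,
                max_mismatch_frac=max_mismatch_frac, min_coverage=min_coverage,
                stranded=stranded, read_id=read_id,
                candidate_regions=[regions[i] for i in sorted(cand_idx)],
            )
        )
    return out


def compute_fpkm(
    alignments: Sequence[ReadAlignment],
    regions: Sequence[ReferenceRegion],
    total_reads: int,
) -> list[FpkmRecord]:
    """FPKM per region from assigned alignments (zeros included)."""
    if total_reads <= 0:
        raise RegionError("total_reads must be positive")
    counts: dict[str, int] = {r.isotype_id: 0 for r in regions}
    for a in alignments:
        if a.status == ASSIGNED:
            counts[a.region_id] += 1
    records = []
    for r in regions:
        n = counts[r.isotype_id]
        fpkm = n / (r.length_bp / 1000.0) / (total_reads / 1e6)
        records.append(FpkmRecord(r.isotype_id, n, r.length_bp, fpkm))
    return records


def write_fpkm_table(records: Sequence[FpkmRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("isotype\tregion_length\tassigned\tfpkm\n")
        for r in records:
            fh.write(f"{r.isotype_id}\t{r.length_bp}\t{r.assigned_fragments}\t{r.fpkm:.4f}\n")


# ---------------------------------------------------------------------------
# Protein/transcript concordance

@dataclass(frozen=True)
class ConcordanceReport:
    spearman: Mapping[str, float | None]  # per family; None when < 3 shared isotypes
    flagged: tuple[str, ...]  # isotypes with high transcript but low protein rank
    n_shared: Mapping[str, int]


def concordance_report(
    protein: Sequence[IsotypeAbundance],
    transcript: Sequence[FpkmRecord],
    transcript_quantile: float = 0.75,
    protein_quantile: float = 0.5,
) -> ConcordanceReport:
    """Rank-concordance of protein and transcript abundance per family.

    The correlation is computed over all shared isotypes (silent isotypes
    tie at the bottom of both rankings).  Discordance flags are ranked
    among the *active* isotypes of a family — those with signal in either
    assay — and mark isotypes whose transcript sits in the top quartile
    while the protein signal falls below the median, the signature of a
    translationally suppressed isotype.
    """
    prot = {a.isotype_id: a.raw_intensity for a in protein}
    tx = {t.isotype_id: t.fpkm for t in transcript}
    shared = sorted(set(prot) & set(tx))

    spearman: dict[str, float | None] = {}
    n_shared: dict[str, int] = {}
    flagged: list[str] = []
    for family in ("TUA", "TUB"):
        ids = [i for i in shared if family_of(i).value == family]
        n_shared[family] = len(ids)
        if len(ids) < 3:
            if ids:
                log.warning("only %d shared %s isotypes; correlation omitted",
                            len(ids), family)
            spearman[family] = None
            continue
        p = np.array([prot[i] for i in ids])
        t = np.array([tx[i] for i in ids])
        spearman[family] = float(stats.spearmanr(p, t).statistic)

        active = [i for i in ids if prot[i] > 0 or tx[i] > 0]
        n = len(active)
        if n < 3:
            continue
        p_rank = (stats.rankdata([prot[i] for i in active]) - 1) / (n - 1)
        t_rank = (stats.rankdata([tx[i] for i in active]) - 1) / (n - 1)
        for i, isotype in enumerate(active):
            if t_rank[i] >= transcript_quantile and p_rank[i] < protein_quantile:
                flagged.append(isotype)
    return ConcordanceReport(spearman=spearman, flagged=tuple(flagged),
                             n_shared=n_shared)
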