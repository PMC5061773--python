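"""MALDI peak lists, isotopic-envelope validation and label-free quantification.

A ~4 kDa peptide produces an isotopic envelope of peaks spaced ~1.00235 Da
apart with a first-isotope intensity comparable to the monoisotopic peak;
the presence of such an envelope is what distinguishes a real peptide
signal from background noise in a linear-TOF spectrum.  Label-free isotype
quantification sums the validated envelope intensity of each reporter
peptide and normalizes within family (TUA and TUB are reported separately;
cross-family comparisons are made on raw intensity only).

Reporter peptides whose masses cannot be told apart at the matching
tolerance (e.g., TUA4 and TUA5, 0.04 Da apart) are merged into one
ambiguity group ("TUA4/5"); an optional transcript-evidence rule reassigns
such a group to its dominant-transcript member, mirroring the reasoning
used for isotype profiles rather than silently picking one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalog import ReporterPeptide, family_of

log = logging.getLogger(__name__)

#: Average spacing of isotopologue peaks for peptides (Da).
ISOTOPE_SPACING = 1.00235

#: Default number of isotopologues required for a valid envelope (k = 0..2).
N_ISOTOPOLOGUES = 3

#: Default acceptance band for the k=1 / k=0 intensity ratio.
RATIO_BAND = (0.3, 3.0)


class PeakListError(ValueError):
    pass


@dataclass(frozen=True)
class PeakList:
    """A MALDI spectrum as sorted (m/z, intensity) pairs."""

    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "positive"
    source_id: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise PeakListError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise PeakListError("peak m/z values must be strictly increasing")
        if np.any(inten < 0):
            raise PeakListError("negative peak intensity")

    def __len__(self) -> int:
        return int(self.mz.size)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]], **kwargs) -> "PeakList":
        pairs = sorted(pairs)
        mz = np.array([p[0] for p in pairs], dtype=float)
        inten = np.array([p[1] for p in pairs], dtype=float)
        return cls(mz=mz, intensity=inten, **kwargs)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "PeakList":
        mzs, intens = [], []
        with open(path) as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln or ln.startswith("#") or ln.startswith("mz"):
                    continue
                a, b = ln.split("\t")
                mzs.append(float(a))
                intens.append(float(b))
        order = np.argsort(mzs)
        return cls(mz=np.asarray(mzs)[order], intensity=np.asarray(intens)[order],
                   source_id=str(path), **kwargs)

    def to_tsv(self, path: str | Path, header_comment: str = "") -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("mz\tintensity\n")
            for m, i in zip(self.mz, self.intensity):
                fh.write(f"{m:.5f}\t{i:.4f}\n")

    @classmethod
    def from_mgf(cls, path: str | Path, **kwargs) -> "PeakList":
        """Read the first spectrum of an MGF file (requires pyteomics)."""
        from pyteomics import mgf

        with mgf.read(str(path)) as reader:
            spec = next(iter(reader))
        order = np.argsort(spec["m/z array"])
        return cls(mz=spec["m/z array"][order],
                   intensity=spec["intensity array"][order],
                   source_id=str(path), **kwargs)

    def nearest_peak(self, target_mz: float, tolerance: float) -> int | None:
        """Index of the peak nearest ``target_mz`` within ``tolerance``, or None."""
        if not len(self):
            return None
        j = int(np.searchsorted(self.mz, target_mz))
        best, best_d = None, tolerance
        for k in (j - 1, j):
            if 0 <= k < len(self):
                d = abs(self.mz[k] - target_mz)
                if d <= best_d:
                    best, best_d = k, d
        return best

    def signal_floor(self) -> float:
        """Per-spectrum background level: median + 3 x MAD of intensities."""
        if not len(self):
            return math.inf
        med = float(np.median(self.intensity))
        mad = float(np.median(np.abs(self.intensity - med)))
        return med + 3.0 * mad


def mutual_nearest_assignments(
    peaks: PeakList,
    expected: Sequence[tuple[str, float]],
    tolerance: float,
) -> dict[int, int]:
    """Attribute peaks to expected m/z positions by mutual nearness.

    Expected position i is granted peak j only when j is the nearest peak
    to i within ``tolerance`` AND i is (one of) the nearest expected
    position(s) to j — so a peak explained better by a different reporter
    or isotopologue cannot also support this one.  Nearly isobaric
    hypotheses (e.g., an acetylated reporter 0.04 Da from another
    isotype's unmodified reporter) are thereby resolved toward the best
    match instead of being double-counted.  Returns {expected index ->
    peak index}.
    """
    if tolerance <= 0:
        raise PeakListError("tolerance must be positive")
    targets = np.array([mz for _, mz in expected], dtype=float)
    granted: dict[int, int] = {}
    for i, t in enumerate(targets):
        j = peaks.nearest_peak(t, tolerance)
        if j is None:
            continue
        d = abs(peaks.mz[j] - t)
        nearest_d = np.min(np.abs(targets - peaks.mz[j]))
        if d <= nearest_d + 1e-9:
            granted[i] = j
    return granted


def envelope_ok(
    peaks: PeakList,
    mono_mz: float,
    tolerance: float,
    ratio_band: tuple[float, float] = RATIO_BAND,
    n_isotopologues: int = N_ISOTOPOLOGUES,
) -> bool:
    """Check for a credible isotopic envelope at ``mono_mz``.

    Requires a peak within ``tolerance`` of mono_mz + k*1.00235 for
    k = 0..n_isotopologues-1 and a k=1/k=0 intensity ratio inside
    ``ratio_band``.
    """
    if tolerance <= 0:
        raise PeakListError("tolerance must be positive")
    idx = []
    for k in range(n_isotopologues):
        j = peaks.nearest_peak(mono_mz + k * ISOTOPE_SPACING, tolerance)
        if j is None:
            return False
        idx.append(j)
    i0 = peaks.intensity[idx[0]]
    i1 = peaks.intensity[idx[1]]
    if i0 <= 0:
        return False
    ratio = i1 / i0
    return ratio_band[0] <= ratio <= ratio_band[1]


# ---------------------------------------------------------------------------
# Label-free isotype quantification

@dataclass(frozen=True)
class IsotypeAbundance:
    """Summed reporter intensity and within-family fraction for one isotype
    (or one mass-ambiguity group such as "TUA4/5")."""

    isotype_id: str
    family: str
    raw_intensity: float
    relative_abundance: float  # NaN when the family has no signal
    members: tuple[str, ...] = ()


def _merge_degenerate(
    reporters: Sequence[ReporterPeptide], threshold: float
) -> list[tuple[str, tuple[ReporterPeptide, ...]]]:
    """Single-linkage merge of reporters whose MH+ differ by < threshold."""
    ordered = sorted(reporters, key=lambda p: p.theoretical_mh)
    groups: list[list[ReporterPeptide]] = []
    for p in ordered:
        if groups and p.theoretical_mh - groups[-1][-1].theoretical_mh < threshold:
            groups[-1].append(p)
        else:
            groups.append([p])
    def natural(iso_id: str):
        suffix = iso_id[3:]
        return (iso_id[:3], int(suffix)) if suffix.isdigit() else (iso_id[:3], suffix)

    out = []
    for g in groups:
        ids = sorted((p.isotype_id for p in g), key=natural)
        if len(ids) == 1:
            label = ids[0]
        else:
            fam = ids[0][:3]
            label = fam + "/".join(i.removeprefix(fam) for i in ids)
        out.append((label, tuple(sorted(g, key=lambda p: natural(p.isotype_id)))))
    return out


def quantify_isotypes(
    peaks: PeakList,
    reporters: Sequence[ReporterPeptide],
    tolerance: float = 0.3,
    transcript_evidence: Mapping[str, float] | None = None,
    dominance: float = 0.9,
) -> list[IsotypeAbundance]:
    """Label-free relative quantification of isotypes from reporter envelopes.

    For each reporter (or mass-degenerate group, merged below 2x tolerance)
    the raw intensity is the sum of the nearest matched peak at each of the
    first three isotopologue positions, provided the envelope validates;
    otherwise 0.  Fractions are normalized within family.  With
    ``transcript_evidence`` (isotype -> transcript abundance), an ambiguity
    group in which a single member holds >= ``dominance`` of the group's
    transcript signal is relabeled to that member.
    """
    if not reporters:
        raise PeakListError("empty reporter catalog")
    if tolerance <= 0:
        raise PeakListError("tolerance must be positive")

    results: list[IsotypeAbundance] = []
    by_family: dict[str, list[ReporterPeptide]] = {}
    for p in reporters:
        by_family.setdefault(family_of(p.isotype_id).value, []).append(p)

    # peak attribution is global: every reporter's isotopologue ladder
    # competes, so overlapping envelopes are resolved toward the best match
    all_groups: list[tuple[str, str, tuple[ReporterPeptide, ...]]] = []
    for family, fam_reporters in sorted(by_family.items()):
        for label, members in _merge_degenerate(fam_reporters, threshold=2 * tolerance):
            all_groups.append((family, label, members))
    expected: list[tuple[str, float]] = []
    slots: list[list[list[int]]] = []  # per group, per member, expected indices
    for _, label, members in all_groups:
        member_slots = []
        for m in members:
            idx = []
            for k in range(N_ISOTOPOLOGUES):
                idx.append(len(expected))
                expected.append((f"{m.isotype_id}:{k}",
                                 m.theoretical_mh + k * ISOTOPE_SPACING))
            member_slots.append(idx)
        slots.append(member_slots)
    granted = mutual_nearest_assignments(peaks, expected, tolerance)

    for family in sorted(by_family):
        raw: list[tuple[str, float, tuple[str, ...]]] = []
        for gi, (fam, label, members) in enumerate(all_groups):
            if fam != family:
                continue
            total = 0.0
            claimed: set[int] = set()
            for member_idx in slots[gi]:
                ladder = [granted.get(i) for i in member_idx]
                if any(j is None for j in ladder):
                    continue
                i0, i1 = peaks.intensity[ladder[0]], peaks.intensity[ladder[1]]
                if not (i0 > 0 and RATIO_BAND[0] <= i1 / i0 <= RATIO_BAND[1]):
                    continue
                for j in ladder:
                    if j not in claimed:
                        claimed.add(j)
                        total += float(peaks.intensity[j])
            if len(members) > 1 and transcript_evidence is not None:
                label = _reassign_group(label, members, transcript_evidence, dominance)
            raw.append((label, total, tuple(m.isotype_id for m in members)))

        fam_total = sum(t for _, t, _ in raw)
        if fam_total <= 0:
            log.warning("no %s reporter signal; family fractions undefined", family)
        for label, total, members in raw:
            rel = total / fam_total if fam_total > 0 else math.nan
            results.append(
                IsotypeAbundance(
                    isotype_id=label, family=family, raw_intensity=total,
                    relative_abundance=rel, members=members,
                )
            )
    return results


def _reassign_group(
    label: str,
    members: Sequence[ReporterPeptide],
    evidence: Mapping[str, float],
    dominance: float,
) -> str:
    vals = {m.isotype_id: max(evidence.get(m.isotype_id, 0.0), 0.0) for m in members}
    total = sum(vals.values())
    if total <= 0:
        return label
    best_id, best_v = max(vals.items(), key=lambda kv: kv[1])
    if best_v / total >= dominance:
        log.info(
            "ambiguity group %s reassigned to %s on transcript evidence "
            "(%.0f%% of group transcript signal)", label, best_id, 100 * best_v / total,
        )
        return best_id
    return label


def write_abundance_table(abundances: Sequence[IsotypeAbundance], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("isotype\tfamily\traw_intensity\trelative_abundance\tmembers\n")
        for a in abundances:
            rel = "" if math.isnan(a.relative_abundance) else f"{a.relative_abundance:.6f}"
            fh.write(
                f"{a.isotype_id}\t{a.family}\t{a.raw_intensity:.4f}\t{rel}\t"
                f"{','.join(a.members)}\n"
            )
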