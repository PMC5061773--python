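"""PTM isoform enumeration and MALDI peak-list scanning.

The C-terminal PTMs assayed here shift the reporter-peptide mass by exact,
composition-defined amounts: detyrosination (dY) removes the C-terminal
Tyr (-163.063 Da), non-tyrosination (dEY, the "delta-2" form) additionally
removes the penultimate Glu (-292.106 Da total), glutamylation adds n Glu
residues (+n x 129.043 Da) and Lys acetylation adds an acetyl group
(+42.011 Da).  Applicability is sequence-gated: only Tyr-ending reporters
can be detyrosinated — TUA isotypes ending in Met, Glu or Gln cannot
participate in the tyrosination cycle at all.

A scanned isoform is called *detected* only when a matched peak carries a
credible isotopic envelope and rises above the per-spectrum signal floor;
a matched peak failing either check is *background*, anything else
*absent*.  This makes the qualitative notion of a signal "near background"
operational and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from .catalog import ReporterPeptide
from .mass_core import MassTable
from .ms_match import (ISOTOPE_SPACING, PeakList, PeakListError,
                       mutual_nearest_assignments)

log = logging.getLogger(__name__)

ACETYL_DELTA = 42.0105646863  # +C2H2O

DETECTED = "detected"
BACKGROUND = "background"
ABSENT = "absent"


@dataclass(frozen=True)
class Modification:
    """A PTM with its exact mass delta and an applicability predicate."""

    name: str
    mass_delta: float
    applies_to: Callable[[str], bool] = field(compare=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Modification({self.name}, {self.mass_delta:+.4f} Da)"


def unmodified() -> Modification:
    return Modification("unmodified", 0.0, lambda seq: True)


def detyrosination(table: MassTable | None = None) -> Modification:
    table = table or MassTable.default()
    return Modification("dY", -table.residue_mass["Y"], lambda seq: seq.endswith("Y"))


def nontyrosination(table: MassTable | None = None) -> Modification:
    """Removal of the C-terminal Glu-Tyr dipeptide (the non-tyrosinatable form)."""
    table = table or MassTable.default()
    delta = -table.residue_mass["E"] - table.residue_mass["Y"]
    return Modification("dEY", delta, lambda seq: seq.endswith("EY"))


def glutamylation(n: int = 1, table: MassTable | None = None) -> Modification:
    if n < 1:
        raise ValueError("glutamylation requires n >= 1")
    table = table or MassTable.default()
    return Modification(
        f"glu+{n}",
        n * table.residue_mass["E"],
        lambda seq: ("E" in seq) or ("D" in seq),
    )


def acetylation() -> Modification:
    return Modification("acetyl", ACETYL_DELTA, lambda seq: "K" in seq)


def default_modifications(max_glutamylation: int = 3,
                          table: MassTable | None = None) -> list[Modification]:
    """The scan set: dY, dEY, glutamylation n=1..max, and Lys acetylation."""
    mods = [unmodified(), detyrosination(table), nontyrosination(table)]
    mods += [glutamylation(n, table) for n in range(1, max_glutamylation + 1)]
    mods.append(acetylation())
    return mods


MOD_FACTORIES: dict[str, Callable[[], Modification]] = {
    "dy": detyrosination,
    "dey": nontyrosination,
    "glu": glutamylation,
    "acetyl": acetylation,
}


@dataclass(frozen=True)
class PtmIsoform:
    base: ReporterPeptide
    modification: Modification
    expected_mh: float

    @property
    def label(self) -> str:
        return f"{self.base.isotype_id}:{self.modification.name}"


def enumerate_isoforms(
    peptides: Sequence[ReporterPeptide],
    mods: Sequence[Modification],
) -> list[PtmIsoform]:
    """Cartesian product of peptides and modifications, applicability-filtered.

    The unmodified isoform is always included for every peptide.
    """
    mods = list(mods)
    if not any(m.name == "unmodified" for m in mods):
        mods.insert(0, unmodified())
    isoforms = []
    for pep in peptides:
        for mod in mods:
            if not mod.applies_to(pep.sequence):
                continue
            isoforms.append(
                PtmIsoform(
                    base=pep,
                    modification=mod,
                    expected_mh=pep.theoretical_mh + mod.mass_delta,
                )
            )
    return isoforms


@dataclass(frozen=True)
class ScanVerdict:
    isoform: PtmIsoform
    status: str  # detected | background | absent
    matched_mz: float | None
    intensity: float
    score: float  # intensity / signal floor (0 when unmatched)


def scan_spectrum(
    peaks: PeakList,
    isoforms: Sequence[PtmIsoform],
    tolerance: float = 0.3,
    ratio_band: tuple[float, float] = (0.3, 3.0),
) -> list[ScanVerdict]:
    """Scan a peak list for every isoform's expected MH+.

    detected  -- an attributable peak at the monoisotopic position, a valid
                 isotopic envelope (three attributable isotopologues with a
                 k=1/k=0 ratio inside ``ratio_band``), and intensity at or
                 above the signal floor (median + 3 MAD);
    background-- a peak within tolerance failing attribution, envelope or
                 floor;
    absent    -- no peak within tolerance.

    Peak attribution is mutual-nearest across the whole isoform set, so a
    PTM isoform nearly isobaric with a different isotype's unmodified
    reporter cannot claim that reporter's envelope.  Exact isobars are
    resolved by parsimony: a peak claimed by an unmodified reporter (e.g.,
    TUB18, whose composition equals TUB17 plus two Glu and therefore sits
    exactly at TUB17's doubly glutamylated mass) never also counts as
    evidence for a modified isoform.
    """
    if tolerance <= 0:
        raise PeakListError("tolerance must be positive")
    floor = peaks.signal_floor()
    expected = [
        (f"{iso.label}:{k}", iso.expected_mh + k * ISOTOPE_SPACING)
        for iso in isoforms
        for k in range(3)
    ]
    granted = mutual_nearest_assignments(peaks, expected, tolerance)
    unmod_peaks = {
        j for i, iso in enumerate(isoforms) if iso.modification.name == "unmodified"
        for j in (granted.get(3 * i + k) for k in range(3)) if j is not None
    }
    for i, iso in enumerate(isoforms):
        if iso.modification.name != "unmodified":
            for k in range(3):
                if granted.get(3 * i + k) in unmod_peaks:
                    granted.pop(3 * i + k, None)

    verdicts = []
    for i, iso in enumerate(isoforms):
        j_any = peaks.nearest_peak(iso.expected_mh, tolerance)
        if j_any is None:
            verdicts.append(ScanVerdict(iso, ABSENT, None, 0.0, 0.0))
            continue
        ladder = [granted.get(3 * i + k) for k in range(3)]
        inten = float(peaks.intensity[j_any])
        score = inten / floor if floor > 0 else 0.0
        if ladder[0] is None or any(j is None for j in ladder):
            verdicts.append(ScanVerdict(iso, BACKGROUND, float(peaks.mz[j_any]), inten, score))
            continue
        i0 = float(peaks.intensity[ladder[0]])
        i1 = float(peaks.intensity[ladder[1]])
        ratio_ok = i0 > 0 and ratio_band[0] <= i1 / i0 <= ratio_band[1]
        status = DETECTED if (ratio_ok and i0 >= floor) else BACKGROUND
        verdicts.append(ScanVerdict(iso, status, float(peaks.mz[ladder[0]]), i0, i0 / floor if floor > 0 else 0.0))
    return verdicts


def write_verdict_table(verdicts: Sequence[ScanVerdict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("isotype\tmodification\texpected_mh\tmatched_mz\tintensity\tverdict\n")
        for v in verdicts:
            mz = f"{v.matched_mz:.4f}" if v.matched_mz is not None else ""
            fh.write(
                f"{v.isoform.base.isotype_id}\t{v.isoform.modification.name}\t"
                f"{v.isoform.expected_mh:.4f}\t{mz}\t{v.intensity:.4f}\t{v.status}\n"
            )
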