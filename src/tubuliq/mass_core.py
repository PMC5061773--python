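"""Exact monoisotopic mass arithmetic and in silico digestion.

All masses are monoisotopic and MH+ means the singly protonated peptide
observed in positive-mode MALDI-TOF: MH+ = sum(residue masses) + H2O +
proton.  CNBr cleaves proteins C-terminal to Met and converts the reacted
Met; the canonical product is homoserine lactone (a loss of CH4S,
-48.0034 Da), but the convention is resolved from the published table
rather than hard-coded (:func:`resolve_met_convention`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from .catalog import AA_ALPHABET, IsotypeRecord, ReporterPeptide

log = logging.getLogger(__name__)

WATER = 18.0105646863
PROTON = 1.00727646688

#: Met -> homoserine lactone: net loss of CH4S from the residue.
HOMOSERINE_LACTONE_DELTA = -48.0033713
#: Met -> homoserine: lactone plus one water.
HOMOSERINE_DELTA = HOMOSERINE_LACTONE_DELTA + WATER

MET_CONVENTIONS: dict[str, float] = {
    "homoserine_lactone": HOMOSERINE_LACTONE_DELTA,
    "homoserine": HOMOSERINE_DELTA,
    "unmodified": 0.0,
}


class MassError(ValueError):
    """Raised for invalid sequences or unresolvable mass conventions."""


@dataclass(frozen=True)
class MassTable:
    residue_mass: Mapping[str, float]
    water: float = WATER
    proton: float = PROTON
    met_terminal_delta: float = HOMOSERINE_LACTONE_DELTA

    def __post_init__(self) -> None:
        for letter, m in self.residue_mass.items():
            if not (50.0 < m < 200.0):
                raise MassError(f"residue mass for {letter!r} out of range: {m}")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "MassTable":
        masses: dict[str, float] = {}
        with open(path) as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln or ln.startswith("#") or ln.startswith("letter"):
                    continue
                letter, m = ln.split("\t")
                masses[letter] = float(m)
        return cls(residue_mass=masses, **kwargs)

    @classmethod
    def default(cls) -> "MassTable":
        return _default_table()


_DEFAULT: MassTable | None = None


def _default_table() -> MassTable:
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("tubuliq.data").joinpath("residue_masses.tsv")
        with resources.as_file(ref) as p:
            _DEFAULT = MassTable.from_tsv(p)
    return _DEFAULT


def peptide_mh(sequence: str, terminal_met: bool = False,
               table: MassTable | None = None) -> float:
    """Monoisotopic MH+ of a peptide.

    With ``terminal_met`` the final residue must be Met and is weighed with
    the table's CNBr conversion delta applied (the letter stays M).
    """
    table = table or MassTable.default()
    if not sequence:
        raise MassError("empty peptide sequence")
    total = table.water + table.proton
    for i, letter in enumerate(sequence):
        try:
            total += table.residue_mass[letter]
        except KeyError:
            raise MassError(f"unknown residue {letter!r} at position {i + 1}") from None
    if terminal_met:
        if sequence[-1] != "M":
            raise MassError("terminal_met requires the peptide to end in M")
        total += table.met_terminal_delta
    return total


@dataclass(frozen=True)
class MetConventionResult:
    name: str
    delta: float
    residuals: Mapping[str, float]  # per-candidate max |computed - printed|


class _HasPrintedMass(Protocol):
    sequence: str
    terminal_met: bool
    printed_mh: float | None


def resolve_met_convention(
    records: Sequence[IsotypeRecord],
    tolerance: float = 0.01,
    table: MassTable | None = None,
) -> MetConventionResult:
    """Pick the CNBr terminal-Met mass convention that fits the catalog.

    Candidates are homoserine lactone, homoserine and unmodified Met; the
    unique delta under which every terminal-Met record's computed MH+
    matches its printed value within ``tolerance`` wins.  Anything else
    (zero or several survivors, or an inconsistent table) is an error
    carrying the per-candidate residual report.
    """
    table = table or MassTable.default()
    met_rows = [r for r in records
                if r.terminal_met and r.printed_mh is not None]
    if not met_rows:
        raise MassError("no terminal-Met records with printed masses to resolve")

    residuals: dict[str, float] = {}
    for name, delta in MET_CONVENTIONS.items():
        cand = replace(table, met_terminal_delta=delta)
        worst = max(
            abs(peptide_mh(r.reporter_sequence, terminal_met=True, table=cand)
                - r.printed_mh)
            for r in met_rows
        )
        residuals[name] = worst

    fits = [name for name, res in residuals.items() if res <= tolerance]
    if len(fits) != 1:
        report = ", ".join(f"{n}: {r:.4f} Da" for n, r in residuals.items())
        raise MassError(
            f"terminal-Met convention not uniquely resolvable over "
            f"{len(met_rows)} rows (max residuals: {report})"
        )
    name = fits[0]
    log.info(
        "terminal-Met convention resolved to %s (delta %.4f Da, "
        "max residual %.4f Da over %d rows)",
        name, MET_CONVENTIONS[name], residuals[name], len(met_rows),
    )
    return MetConventionResult(name=name, delta=MET_CONVENTIONS[name],
                               residuals=residuals)


# ---------------------------------------------------------------------------
# In silico digestion

@dataclass(frozen=True)
class DigestRule:
    """Cleavage rule for a protease or chemical digestion.

    ``cleave_after`` residues trigger a cut unless the next residue is in
    ``no_cleave_before`` or the site position is marked modified
    (acetylated Lys blocks trypsin).  ``met_conversion`` marks CNBr
    chemistry: fragments ending in M carry the terminal-Met mass flag.
    """

    protease: str
    cleave_after: frozenset[str]
    no_cleave_before: frozenset[str] = frozenset()
    block_modified: bool = False
    met_conversion: bool = False

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise MassError("empty cleavage residue set")


CNBR = DigestRule(protease="CNBr", cleave_after=frozenset("M"), met_conversion=True)
TRYPSIN = DigestRule(
    protease="trypsin",
    cleave_after=frozenset("KR"),
    no_cleave_before=frozenset("P"),
    block_modified=True,
)


def digest(
    protein: str,
    rule: DigestRule,
    modified_positions: Iterable[int] = (),
    isotype_id: str = "",
    table: MassTable | None = None,
) -> list[ReporterPeptide]:
    """Cut a protein into ordered fragments under a digestion rule.

    ``modified_positions`` are 1-based residue positions carrying a
    cleavage-blocking modification.  Fragment spans are 1-based inclusive;
    the concatenation of fragment sequences reconstructs the protein.
    """
    if not protein:
        raise MassError("empty protein sequence")
    bad = set(protein) - AA_ALPHABET
    if bad:
        raise MassError(f"non-amino-acid character(s) {sorted(bad)} in protein")
    table = table or MassTable.default()
    modified = frozenset(modified_positions)

    cuts = []
    for i, letter in enumerate(protein):
        if letter not in rule.cleave_after:
            continue
        if rule.block_modified and (i + 1) in modified:
            continue
        if i + 1 < len(protein) and protein[i + 1] in rule.no_cleave_before:
            continue
        cuts.append(i + 1)  # cut after residue i (0-based) -> fragment ends at i
    bounds = [0] + cuts + ([len(protein)] if (not cuts or cuts[-1] != len(protein)) else [])

    fragments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seq = protein[a:b]
        terminal_met = rule.met_conversion and seq.endswith("M")
        fragments.append(
            ReporterPeptide(
                isotype_id=isotype_id,
                sequence=seq,
                span=(a + 1, b),
                terminal_met=terminal_met,
                theoretical_mh=peptide_mh(seq, terminal_met=terminal_met, table=table),
            )
        )
    return fragments


def reporters_from_catalog(
    records: Sequence[IsotypeRecord],
    table: MassTable | None = None,
) -> list[ReporterPeptide]:
    """Build reporter peptides (with computed MH+) from catalog records."""
    table = table or MassTable.default()
    return [
        ReporterPeptide(
            isotype_id=r.id,
            sequence=r.reporter_sequence,
            span=r.cterm_span,
            terminal_met=r.terminal_met,
            theoretical_mh=peptide_mh(
                r.reporter_sequence, terminal_met=r.terminal_met, table=table
            ),
        )
        for r in records
    ]
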