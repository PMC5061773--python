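"""Tubulin isotype catalog: domain records and standard-format I/O.

The *Populus* tubulin family comprises 8 alpha- (TUA) and 20 beta-tubulin
(TUB) isotypes.  Because the proteins are nearly identical outside the
hypervariable C-terminal tail, each isotype is identified in MALDI spectra
by its C-terminal CNBr "reporter" peptide, whose monoisotopic mass is
(almost always) unique to the isotype.  This module houses the catalog of
isotypes/reporter regions and reads/writes the TSV and FASTA formats the
rest of the pipeline consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
NT_ALPHABET = frozenset("ACGT")


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog inputs."""


class Family(str, Enum):
    TUA = "TUA"
    TUB = "TUB"


def family_of(isotype_id: str) -> Family:
    """Family is determined by the isotype id prefix (TUA*/TUB*)."""
    prefix = isotype_id[:3].upper()
    try:
        return Family(prefix)
    except ValueError:
        raise CatalogError(f"cannot infer family from isotype id {isotype_id!r}")


@dataclass(frozen=True)
class IsotypeRecord:
    """One tubulin isotype (per species variant).

    ``protein_seq`` may be the full-length protein or, as in the packaged
    catalog, just the C-terminal reporter region itself; ``cterm_span`` is
    the 1-based inclusive residue interval of the reporter region in the
    full protein either way.  ``terminal_met`` marks reporter regions that
    end in a CNBr-converted Met; ``printed_mh`` carries the published MH+
    where one exists (used to resolve mass conventions, never to compute).
    """

    id: str
    family: Family
    species_tag: str
    protein_seq: str
    cterm_span: tuple[int, int]
    nt_region: str | None = None
    terminal_met: bool = False
    printed_mh: float | None = None

    def __post_init__(self) -> None:
        if not self.protein_seq:
            raise CatalogError(f"{self.id}: empty protein sequence")
        bad = set(self.protein_seq) - AA_ALPHABET
        if bad:
            raise CatalogError(
                f"{self.id}: non-amino-acid character(s) {sorted(bad)} in sequence"
            )
        start, end = self.cterm_span
        if not (1 <= start <= end):
            raise CatalogError(f"{self.id}: invalid span {self.cterm_span}")
        span_len = end - start + 1
        if len(self.protein_seq) != span_len and len(self.protein_seq) < end:
            raise CatalogError(
                f"{self.id}: span {self.cterm_span} inconsistent with "
                f"sequence of length {len(self.protein_seq)}"
            )
        if self.nt_region is not None:
            badnt = set(self.nt_region) - NT_ALPHABET
            if badnt:
                raise CatalogError(f"{self.id}: non-ACGT nucleotide(s) {sorted(badnt)}")
        if family_of(self.id) != self.family:
            raise CatalogError(f"{self.id}: family {self.family} contradicts id prefix")

    @property
    def reporter_sequence(self) -> str:
        """The C-terminal reporter region of this isotype."""
        start, end = self.cterm_span
        if len(self.protein_seq) == end - start + 1:
            return self.protein_seq
        return self.protein_seq[start - 1 : end]


@dataclass(frozen=True)
class ReporterPeptide:
    """A digestion product carrying its theoretical singly protonated mass.

    ``terminal_met`` refers to the mass convention only: a CNBr-converted
    Met is still written as the letter M but weighed as homoserine lactone.
    """

    isotype_id: str
    sequence: str
    span: tuple[int, int]
    terminal_met: bool
    theoretical_mh: float

    def __post_init__(self) -> None:
        if self.theoretical_mh <= 0:
            raise CatalogError(f"{self.isotype_id}: non-positive MH+")
        if self.terminal_met and not self.sequence.endswith("M"):
            raise CatalogError(
                f"{self.isotype_id}: terminal_met set but sequence ends "
                f"in {self.sequence[-1]!r}"
            )


# ---------------------------------------------------------------------------
# Catalog I/O

_TSV_COLUMNS = [
    "isotype", "family", "species", "span_start", "span_end",
    "sequence", "terminal_met", "printed_mh",
]


def load_catalog(path: str | Path, species: str | None = None) -> list[IsotypeRecord]:
    """Load isotype records from a TSV or tagged-FASTA catalog file.

    Records are keyed by (isotype id, species); duplicates are a hard
    error.  ``species`` filters to one species tag.
    """
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".faa"}:
        records = _load_fasta(path)
    else:
        records = _load_tsv(path)
    if species is not None:
        records = [r for r in records if r.species_tag == species]
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.id, rec.species_tag)
        if key in seen:
            raise CatalogError(f"duplicate catalog entry for {rec.id} ({rec.species_tag})")
        seen.add(key)
    if not records:
        log.warning("catalog %s is empty", path)
    return records


def _load_tsv(path: Path) -> list[IsotypeRecord]:
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    header = lines[0].split("\t")
    idx = {name: header.index(name) for name in header}
    for ln in lines[1:]:
        f = ln.split("\t")
        mh = f[idx["printed_mh"]] if "printed_mh" in idx else ""
        nt = f[idx["nt_region"]] if "nt_region" in idx and idx["nt_region"] < len(f) else ""
        records.append(
            IsotypeRecord(
                id=f[idx["isotype"]],
                family=Family(f[idx["family"]]),
                species_tag=f[idx["species"]],
                protein_seq=f[idx["sequence"]],
                cterm_span=(int(f[idx["span_start"]]), int(f[idx["span_end"]])),
                nt_region=nt or None,
                terminal_met=f[idx["terminal_met"]] in ("1", "True", "true"),
                printed_mh=float(mh) if mh else None,
            )
        )
    return records


def _parse_header_tags(description: str) -> dict[str, str]:
    parts = description.split()
    return dict(p.split("=", 1) for p in parts[1:] if "=" in p)


def _load_fasta(path: Path) -> list[IsotypeRecord]:
    from Bio import SeqIO

    records = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        tags = _parse_header_tags(seq_rec.description)
        try:
            start, end = tags["span"].split("-")
            span = (int(start), int(end))
        except KeyError:
            span = (1, len(seq_rec.seq))
        seq = str(seq_rec.seq).upper()
        is_nt = set(seq) <= NT_ALPHABET and len(seq) > 0
        records.append(
            IsotypeRecord(
                id=seq_rec.id,
                family=Family(tags.get("family", family_of(seq_rec.id).value)),
                species_tag=tags.get("species", ""),
                protein_seq=seq if not is_nt else tags.get("protein", seq),
                cterm_span=span,
                nt_region=seq if is_nt else None,
                terminal_met=tags.get("terminal_met", "0") in ("1", "True", "true"),
                printed_mh=float(tags["mh"]) if "mh" in tags else None,
            )
        )
    return records


def write_catalog(records: Iterable[IsotypeRecord], path: str | Path) -> None:
    """Write records as TSV (the inverse of :func:`load_catalog`)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in records:
            mh = f"{r.printed_mh:.3f}" if r.printed_mh is not None else ""
            fh.write(
                "\t".join(
                    [
                        r.id, r.family.value, r.species_tag,
                        str(r.cterm_span[0]), str(r.cterm_span[1]),
                        r.protein_seq, str(int(r.terminal_met)), mh,
                    ]
                )
                + "\n"
            )


def write_fasta(records: Iterable[IsotypeRecord], path: str | Path,
                nucleotide: bool = False) -> None:
    """Write records as FASTA with ``key=value`` header tags."""
    with open(path, "w") as fh:
        for r in records:
            tags = [
                f"species={r.species_tag}",
                f"family={r.family.value}",
                f"span={r.cterm_span[0]}-{r.cterm_span[1]}",
                f"terminal_met={int(r.terminal_met)}",
            ]
            if r.printed_mh is not None:
                tags.append(f"mh={r.printed_mh:.3f}")
            seq = r.nt_region if nucleotide else r.protein_seq
            if seq is None:
                raise CatalogError(f"{r.id}: no nucleotide region to write")
            fh.write(f">{r.id} {' '.join(tags)}\n{seq}\n")


def packaged_catalog(species: str = "Pd") -> list[IsotypeRecord]:
    """The packaged *Populus* reporter-peptide catalog (28 isotypes/species)."""
    ref = resources.files("tubuliq.data").joinpath("populus_reporters.tsv")
    with resources.as_file(ref) as p:
        return load_catalog(p, species=species)


def packaged_nterm_fragment() -> IsotypeRecord:
    """A synthetic N-terminal TUA fragment with Lys-40, for digestion demos.

    The sequence is a constructed stand-in (not a published *Populus*
    sequence): 60 residues with trypsin sites at Arg-35, Lys-40 and Arg-52,
    so that acetylation of Lys-40 visibly changes the digest pattern.
    """
    ref = resources.files("tubuliq.data").joinpath("tua_nterm_k40_synthetic.fasta")
    with resources.as_file(ref) as p:
        (rec,) = _load_fasta(Path(p))
    return rec


def family_counts(records: Iterable[IsotypeRecord]) -> dict[Family, int]:
    counts: dict[Family, int] = {Family.TUA: 0, Family.TUB: 0}
    for r in records:
        counts[r.family] += 1
    return counts


# ---------------------------------------------------------------------------
# Reporter-peptide tables

def write_reporter_table(peptides: Sequence[ReporterPeptide], path: str | Path) -> None:
    """Write a reporter-peptide TSV (mh rounded half-even to 3 decimals)."""
    if not peptides:
        raise CatalogError("no peptides to write")
    with open(path, "w") as fh:
        fh.write("isotype\tspan\tsequence\tterminal_met\tmh\n")
        for p in peptides:
            fh.write(
                f"{p.isotype_id}\t{p.span[0]}-{p.span[1]}\t{p.sequence}\t"
                f"{int(p.terminal_met)}\t{round(p.theoretical_mh, 3):.3f}\n"
            )


def read_reporter_table(path: str | Path) -> list[ReporterPeptide]:
    peptides = []
    with open(path) as fh:
        header = fh.readline()
        for ln in fh:
            iso, span, seq, tm, mh = ln.rstrip("\n").split("\t")
            start, end = span.split("-")
            peptides.append(
                ReporterPeptide(
                    isotype_id=iso,
                    sequence=seq,
                    span=(int(start), int(end)),
                    terminal_met=tm == "1",
                    theoretical_mh=float(mh),
                )
            )
    return peptides
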