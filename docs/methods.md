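# Methods

## Mass model

All masses are monoisotopic. A peptide's singly protonated mass is
MH⁺ = Σ residue masses + mass(H₂O) + mass(proton), with the residue table
shipped as a versioned TSV (`tubuliq/data/residue_masses.tsv`; standard
4–6-decimal monoisotopic values, cross-checked against pyteomics in the
test suite), water = 18.0105647 Da and proton = 1.0072765 Da. Cys is
weighed unmodified (no carbamidomethylation); the Cys-containing TUB6
reporter reproduces its published mass under this choice. Display
rounding is half-even to 3 decimals; all comparisons use full precision.

CNBr cleaves C-terminal to Met and chemically converts the reacted Met.
Rather than hard-coding the product, `resolve_met_convention` brute-forces
the three candidate conventions (homoserine lactone −48.0034 Da,
homoserine −29.9928 Da, unmodified 0 Da) against every terminal-Met row
of the packaged published mass table and requires a unique fit within
0.01 Da. Homoserine lactone is the unique survivor (max residual
0.0039 Da over 16 rows; the alternatives miss by ≥18 Da). The choice,
and the per-candidate residuals, are logged on every run.

### Published-table discrepancies

Five of the 56 printed reporter masses cannot be produced from their own
printed sequences under *any* uniform residue table: Pd TUB3 (+36.5 mDa),
TUB4 (+15.8 mDa), TUB8 (−32.2 mDa), TUB20 (+36.5 mDa) and the hybrid-aspen
TUB2 variant (+8.9 mDa). The TUB3/TUB20 offset equals exactly
mass(Lys) − mass(Gln) = 36.4 mDa — those two rows also share an identical
printed mass — indicating the published mass column was computed from a
composition differing from the printed sequence by one K↔Q. The other 51
rows, including every terminal-Met row and every anchor value this
package reports, reproduce to ≲0.5 mDa (TUB6 and TUB16: ≲4 mDa). The
whole-table acceptance test asserts the printed values as printed and is
therefore expected to fail on those five rows; the discrepancy is a
property of the source table, not of the arithmetic.

## Digestion

`digest` cuts after every residue in the rule's cleavage set. CNBr: cut
after every Met; fragments ending in Met (including a protein-terminal
Met) carry the terminal-Met mass flag. Trypsin: cut after Lys/Arg except
before Pro and except at positions listed as modified — an acetylated
Lys-40 therefore fuses the two flanking tryptic peptides, which is the
digest-pattern signature used to recognize Lys-40 acetylation. The
packaged N-terminal fragment used to demonstrate this
(`tua_nterm_k40_synthetic.fasta`) is a constructed 60-residue stand-in
with cleavage sites at Arg-35/Lys-40/Arg-52, not a published sequence.
Missed cleavages are not enumerated.

## PTM scanning

Each reporter is expanded into PTM isoforms with exact composition-defined
deltas: dY (−mass(Y), requires a …Y terminus), dEY (−mass(E)−mass(Y),
requires …EY; Met/Glu/Gln-ending TUAs cannot participate in the
tyrosination cycle and get no dY/dEY isoform), glutamylation n = 1..3
(+n × mass(E); the published search covered n = 1, the wider scan is a
package default), and Lys acetylation (+42.0106 Da). The unmodified
isoform is always scanned.

A spectrum match is judged at ±0.3 Da (a linear-TOF-scale default for
~4 kDa peptides; the source analysis states no tolerance). An isoform is
**detected** only when (i) peaks exist at its monoisotopic position and
the next two isotopologue positions (spacing 1.00235 Da), (ii) the
k=1/k=0 intensity ratio lies in 0.3–3.0 (appropriate for ~4 kDa
peptides, where the first isotope is comparable to the monoisotopic
peak), (iii) the monoisotopic intensity reaches the per-spectrum signal
floor, median + 3×MAD of all peak intensities — an operational version of
"above background" — and (iv) the peaks are *attributable* to the
isoform. Attribution is mutual-nearest matching between observed peaks
and the expected positions of every hypothesis in play, which resolves
two real degeneracies in this family: TUB7's monoisotopic mass lies
0.02 Da from TUB16's first isotopologue, and acetyl-TUA1 lies 0.04 Da
from unmodified TUA3. Exact isobars are resolved by parsimony: TUB18's
composition equals TUB17 plus two Glu, so a TUB18-attributed peak is
never also counted as doubly glutamylated TUB17. A matched but
non-attributable or envelope-less peak is **background**; no peak within
tolerance is **absent**.

## Label-free quantification

A reporter's raw intensity is the summed intensity of its attributed
isotopologue peaks (k = 0..2), zero if the envelope does not validate.
Reporters whose masses differ by < 2× tolerance are merged into an
ambiguity group (TUA4/TUA5 at 0.037 Da; TUB3/TUB20 are exactly isobaric),
each member's ladder contributing to the group total. Fractions are
normalized within family — TUA and TUB are never mixed in one
denominator; cross-family statements use raw intensities only. An
optional transcript-evidence rule relabels a group to a member holding
≥90% of the group's transcript signal (logged, never silent). With no
family signal, fractions are NaN and flagged. This summed-envelope /
within-family scheme is the simplest reading of per-family label-free
reporter quantification; no retention-time alignment or absolute scale is
attempted.

## Transcript quantification

Reference regions are the last `cds_tail_bp` coding bases plus the first
`utr_bp` UTR bases (defaults 90 + 90, ≤200 bp total), truncated with a
warning on short transcripts. Reads are aligned glocally (read-global,
region-local) with edlib against every region on both strands (a
`--stranded` flag restricts to forward; the emulated libraries are
stranded, the default stays permissive). From the alignment: terminal
read overhangs off a region end are unaligned (coverage < 1) rather than
errors; internal substitutions and gaps are edit operations. Filters:
coverage > 0.95 of the read and edits ≤ floor(0.02 × read length) — the
proportional reading is the only one consistent with variable read
lengths. Scoring for best-hit choice is +1 match, −1 mismatch, −2 gap
open, −1 gap extend. A unique top score is assigned; equal top scores on
different regions are discarded as ambiguous ties, because random
assignment would fabricate resolution between near-identical paralogs —
the exact failure mode the region design avoids. Coverage is measured on
the read ("hit length coverage" is ambiguous between read and reference;
read-length coverage is implemented). FPKM = assigned /
(region_kb) / (total_reads/10⁶), zeros included. A k-mer prefilter
(15-mers) skips regions sharing no exact seed with a read; any read
passing the 2% allowance must share long exact stretches, so the filter
is lossless for assignable reads.

Concordance: Spearman rank correlation between protein raw intensity and
FPKM per family over all shared isotypes (silent isotypes tie at the
bottom of both rankings); omitted with a warning below 3 shared isotypes.
Discordance flags rank only the *active* isotypes (signal in either
assay) and mark transcript rank ≥ 75th percentile with protein rank below
the median — the translational-suppression signature.

## Bait assembly

The reference-correction loop: recruit reads sharing an exact k-mer
(k = 21, either strand) with any bait and matching the bait at ≤5% edit
distance over the k-mer-implied overlap (so reads overhanging a
contig-sized bait are judged on their overlap); assemble recruited reads
by greedy overlap-layout-consensus — exact-substring containment, then
pairwise merging by maximal exact suffix–prefix overlap ≥30 bp (ties:
longer overlap, then lexicographic read id), then a refinement pass that
realigns substitution-only singleton fragments onto larger layouts, then
per-column majority consensus (ties to the smallest base) — and assign
contigs to genes at ≥90% identity over ≥100 aligned bases; assigned
contigs are the next round's baits. The loop stops when the recruited
read-id set repeats (recruitment is monotone in the baits, so this
stabilizes), when no contig is assigned, or at 10 iterations; the longest
contig per gene from the final round is returned. Stability is defined on
the recruited id set rather than on contig sequences, which can
oscillate under consensus ties. The stage internals deliberately replace
the original external mapper/assembler/search tools; the loop structure,
stability criterion, iteration cap and longest-contig selection are the
procedure under test. No paired-end or splice-graph handling.

## Synthetic data

The generator encodes the statistical structure the analysis assumes, with
a single seed and deterministic per-stage substreams (`substream`), and a
manifest hash recorded in every output.

* **Families/transcripts**: per-family shared random coding core (300 bp —
  the near-identity that defeats naive mapping), the reporter region
  reverse-translated with per-isotype random synonymous codons, a stop
  codon, and a random per-isotype 90 bp UTR; so extracted regions are
  mutually diagnostic while full transcripts are near-identical — the
  real family's geometry. `simulate_family` adds point substitutions at a
  core rate with a 5× rate in the C-terminal/UTR region, logging every
  substitution.
* **Reads**: forward-strand (stranded libraries), multinomial origins,
  uniform starts, i.i.d. substitutions at 0.5%, 75 bp, 20,000 reads by
  default — tubulins are among the most abundant xylem transcripts, and
  this depth keeps multinomial noise on a 5% isotype well below the
  ±15% recovery band being tested. Truth tables map read → origin.
* **Spectra**: each present isotype emits a 4-peak envelope at its
  reporter MH⁺ (apex ∝ proportion, geometric decay 0.65); PTM spikes emit
  satellite envelopes scaled by stoichiometry (spikes on inapplicable
  isoforms are rejected); noise peaks are uniform in m/z with ≥1.5 Da
  spacing from every other peak, so noise can never form an isotopic
  envelope — a deliberate idealization that makes the envelope check a
  clean discriminator. No peak shapes, baselines, calibration drift or
  quality-score error models are simulated; passing tests therefore
  demonstrate the pipeline's logic on idealized signals, not robustness
  to instrument artifacts.

Mixture-recovery studies sample 5 isotypes per family (Dirichlet
proportions floored at 5%) from the mass-resolvable pool; the TUA4/TUA5
and TUB3/TUB20 degeneracies are exercised by dedicated tests instead.

## Defaults

| parameter | default | origin |
|---|---|---|
| MALDI matching tolerance | ±0.3 Da | package assumption (linear TOF, ~4 kDa) |
| envelope ratio band (k1/k0) | 0.3–3.0 | package assumption (~4 kDa peptides) |
| signal floor | median + 3×MAD | package operationalization of "near background" |
| read coverage filter | >0.95 | stated analysis parameter |
| mismatch allowance | ≤2% of read length | stated analysis parameter |
| degenerate-mass merge | <2× tolerance | package assumption |
| recruitment k-mer | 21 | package assumption |
| assembly min overlap | 30 bp | package assumption |
| contig→gene assignment | ≥90% id over ≥100 bp | package assumption (unstated in source) |
| iteration cap | 10 | stated analysis parameter |
| glutamylation scan depth | n = 1..3 | package extension of the n = 1 search |

## Known limitations

Single merged peak list per sample (no per-fraction handling); positive
ion mode only; no MS/MS fragment-ion scoring; no average-mass mode; no
paired-end reads, rRNA filtering or differential expression. Problem
sizes in tests (300 bp transcripts, 180 bp regions, 20k reads, 1,000
null spectra) are desk-scale choices that keep every property
statistically decidable while the full suite runs in well under a minute
per module.
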