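# Methods

## Input model

A *mapped assembly* encodes gene annotations positionally: the complete
ungapped mitogenome is the first FASTA record and each gene is a row of the
same length, gapped (`-`) outside its genomic span. Coordinates are
recovered by locating the first and last non-gap character of each row
(1-based, closed intervals, the feature-table convention). The format can
express exactly one contiguous span per gene, which matches the biology
this tool targets — animal mitochondrial genes are unsplit — and makes two
classes of curation mistakes detectable as hard errors: a gap strictly
inside a gene's span (a split block) and a duplicated gene name. Genes
spanning the circular origin cannot be drawn in a linear alignment row and
are likewise rejected rather than guessed; they must be annotated manually.

Only `-` is accepted as a gap. Editors disagree about `.`; accepting both
silently would risk misreading a `.`-holding sequence, so `.` is a clear
error instead. IUPAC ambiguity codes are carried through verbatim and
compare as literal characters in identity checks.

Row identity against the genome slice is a *warning*, not an error: after
manual curation a gene row may legitimately differ from what was originally
mapped (e.g. an extended boundary), and the genome — not the row — is the
sequence being submitted. The genome substring is therefore what gets
annotated and analyzed; the row only defines the span.

## Strand handling

The forward-genes list is the single source of strand information: rows
named there are forward, all others reverse. Reverse genes are
reverse-complemented (Biopython, IUPAC-aware) before codon analysis, and
their printed coordinates are swapped (start > end), which is how the
five-column format encodes strand. This swap is involutive, and double
reverse-complementation is the identity — both are property-tested.

## Codon analysis

Genetic codes are the NCBI translation tables bundled with Biopython,
keyed by NCBI id (2 vertebrate mitochondrial, 5 invertebrate, 4, 9, 13,
14, ... — any id NCBI defines). The canonical-start set is the table's own
start-codon set, deliberately broad for mitochondrial tables (GTG is a
canonical start under table 5 and raises no exception).

A CDS's 3' end is classified purely by length mod 3 and terminal bases:
remainder 0 → full stop iff the last codon is in the stop set; remainder
1 → truncated stop iff the last base is `T`; remainder 2 → truncated stop
iff the last bases are `TA`; everything else is invalid. Invalid stops are
annotated with the literal `ERROR IN STOP CODON` note and make the run
exit nonzero — the table is still written in full so the curator can see
every problem at once. Ambiguous bases (N, R, ...) at a decisive position
are classified non-canonical/invalid with a distinct log message, never
resolved optimistically. Internal stop codons are not scanned; only the
terminal codon is checked.

`transl_except` positions are genomic. On the reverse strand they are
printed in coding order (descending), consistent with the reversed
location-line coordinates; a forward truncated `T` at the end of interval
(s, e) yields `(pos:e,aa:TERM)`, the same gene on the reverse strand
`(pos:s,aa:TERM)`. The truncated-stop annotation carries the standard
polyadenylation note. `TA` truncations are annotated correctly but logged
as discouraged, since some downstream consumers accept only the single-`T`
form. Non-canonical starts are annotated `(pos:S1..S3,aa:Met)` over the
first codon plus a note naming the observed codon — the usual mitochondrial
practice — and can be switched off (`--no-start-exceptions`) for databases
that prefer bare starts. The `codon_start` qualifier is never needed:
genes are annotated full-length, so the reading frame always opens at the
first base.

## Table construction

Rows are processed in input order and never dropped or sorted (downstream
submission tools reorder features themselves). Every gene-like row (CDS,
tRNA, rRNA) yields a `gene` feature carrying the raw curated name — so the
table stays traceable to the alignment — paired with a typed feature at
the same location carrying the product and any codon annotations. Control
regions are emitted as a single `D-loop` feature with note
`control region` (the standard mitochondrial key; configurable to
`misc_feature`), and unknown names as a single `misc_feature`; neither is
a gene, so neither gets a paired `gene` feature. CDS qualifier order is
fixed — `product`, `transl_table`, `transl_except`(s), `note`(s) — so
output is deterministic and diffable.

Product strings expand the compact names to full GenBank vocabulary
(`nad3` → `NADH dehydrogenase subunit 3`, `cox1` → `cytochrome c oxidase
subunit I`, `M` → `tRNA-Met`, `rrnL` → `16S ribosomal RNA`). Name matching
is case-sensitive (preventing `Nad4l`/`nad4L` ambiguity) with a logged
"did you mean" hint; a `name=product` config file can override any
product. The L/S isoacceptor codon family (CUN/UUR/AGN/UCN) is emitted as
a `note` (`codons recognized: CUN`), keeping products standard. Partial
genes' `<`/`>` markers are never emitted; if a gene is genuinely partial
the table must be corrected by hand.

## MITOS bridge

MITOS-style gene FASTA records (four `;`-separated header fields, gene
name last, `trn`-prefixed tRNA names) are placed on the genome by exact
substring search: forward strand first, then the reverse complement —
MITOS writes reverse genes gene-oriented. If both strands match, forward
wins with a warning. With multiple candidate positions the search cursor,
which advances strictly past the previous record's start (records are
position ordered), disambiguates; this also lets two *identical*
duplicated genes land on successive occurrences. Duplicated normalized
names are suffixed `-copy2` and thereby demoted to miscellaneous features
with a loud warning, since duplicated gene names cannot be submitted
automatically. The emitted rows always satisfy the mapped-assembly
invariants, so the bridge output feeds the table builder unchanged.

## Synthetic data generator

Tests and the acceptance script run on generated mitogenomes with known
ground truth. A gene plan lists name, length, strand and, for CDSs, the
start style (canonical / non-canonical) and stop style (full / T / TA /
invalid); the generator builds each CDS codon-by-codon under the chosen
genetic code so every planted style is realized exactly (plans whose
length is inconsistent with the stop style's mod-3 remainder are
rejected). The stock full plan is the canonical animal complement — 13
CDSs with realistic lengths, 22 tRNAs (~66–68 bp), both rRNAs and a control
region, eleven features on the reverse strand — separated by random 20–100
bp spacers; the randomized plan mixes strands, both codes and all four
stop styles. All randomness flows from a single integer seed, and a fixed
seed reproduces byte-identical output.

The generator also returns the *expected* feature table, computed from the
planting coordinates by direct arithmetic (not by running the converter),
which is the oracle for the feature-for-feature equivalence tests. What
the fixtures do **not** emulate: real mitochondrial base composition
(AT-richness, strand skew), overlapping genes, origin-spanning genes and
sequencing ambiguity codes — so passing tests demonstrate coordinate,
strand, codon and format correctness, not robustness to every curation
pathology. Fixture sizes (≈17 kb full genomes, 100 randomized genomes of
≈8–12 genes in the equivalence sweep) keep the whole suite within a few
seconds while exercising every code path.

## Exit-code policy

`aln2tbl` exits 0 on a clean run, 1 on unusable input (bad FASTA, unknown
genetic code, malformed gene list), and 2 when the table was written but
contains stop-codon error markers — nonzero so pipelines fail fast, a
distinct code so wrappers can distinguish "fix your alignment" from "fix
your command line". The table goes to standard output (redirect with `>`),
or to a file via `-o`; every diagnostic goes to standard error, never into
the table stream.

## External validation recipe (manual)

The rendered table is designed to be consumed by NCBI's `tbl2asn` together
with the genome FASTA and a submission template
(`tbl2asn -i genome.fas -f table.tbl -t template.sbt`); running it and
inspecting the resulting `.val` files is a useful manual end-to-end check.
It is not part of the automated suite, which instead verifies the format
contract directly (field counts per line, qualifier placement, round-trip
re-parsing).
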