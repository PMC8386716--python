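# mitotbl

Rebuild a submission-ready DDBJ/ENA/GenBank **five-column feature table**
from a manually curated FASTA alignment of genes mapped on a complete
mitochondrial genome.

## The problem

Animal mitogenomes (typically 37 genes: 13 protein-coding genes, 2 rRNAs,
22 tRNAs, plus a control region) are usually annotated automatically
(e.g. with MITOS), then curated by hand in an alignment editor such as
Aliview or Seaview — gene boundaries of CDSs and rRNAs in particular often
need adjustment. The moment you edit the alignment, the automatically
generated feature table is stale, and rewriting it by hand is slow and
error-prone. `mitotbl` regenerates the table directly from the curated
alignment, so the whole path from primary sequence to a `.sqn` submission
(via NCBI's `tbl2asn`) can be scripted, with manual curation as the only
interactive step.

The input "mapped assembly" is a multi-FASTA in which:

* record 1 is the complete, ungapped mitogenome;
* every later record is one gene, written as a row of exactly the genome's
  length — gaps (`-`) everywhere except the gene's span, which carries the
  genome's forward-strand sequence.

A one-line, comma-separated list names the genes encoded on the forward
strand; everything else is annotated on the reverse strand (printed with
swapped coordinates, the feature-table convention). Gene names use the
compact mitochondrial nomenclature: `atp6 atp8 cob cox1 cox2 cox3
nad1..nad6 nad4L`, `rrnL`/`16S` and `rrnS`/`12S`, single amino-acid letters
for tRNAs with `L1`(CUN)/`L2`(UUR) and `S1`(AGN)/`S2`(UCN) for the leucine
and serine isoacceptors, and `control_region`/`CR` (or `CR1`, `CR2`).
Unknown names become `misc_feature`s.

## Mitochondria-specific codon handling

CDS ends are classified against the chosen NCBI genetic code (`-c 2`
vertebrate mitochondrial, `-c 5` invertebrate mitochondrial, ...):

* a final in-frame stop codon — clean, no extra qualifiers;
* a trailing `T` (length ≡ 1 mod 3) or `TA` (length ≡ 2 mod 3) — a
  *truncated stop codon*, completed to `TAA` by polyadenylation of the
  mRNA; annotated with `transl_except (pos:N,aa:TERM)` (or
  `(pos:N1..N2,aa:TERM)`) plus the standard note
  `TAA stop codon is completed by the addition of 3' A residues to the mRNA`;
* anything else — the literal note `ERROR IN STOP CODON` is placed on the
  CDS and the program exits nonzero, so you can fix the alignment and rerun.

Non-canonical start codons (not in the code's start set) are annotated as
`transl_except (pos:S1..S3,aa:Met)` with an explanatory note (disable with
`--no-start-exceptions`). Truncated `TA` stops are processed correctly but
trigger a warning, since some downstream tools only accept the single-`T`
form.

## Worked example

```
aln2tbl -f example_assembly.fas -g example_forward.txt -c 5 > example.tbl
```

with a forward-genes file containing `M,nad3,control_region` (so `Q` is
reverse-strand) prints:

```
>Feature synthmito1
26	92	gene
			gene	M
26	92	tRNA
			product	tRNA-Met
103	448	gene
			gene	nad3
103	448	CDS
			product	NADH dehydrogenase subunit 3
			transl_table	5
			transl_except	(pos:448,aa:TERM)
			note	TAA stop codon is completed by the addition of 3' A residues to the mRNA
528	461	gene
			gene	Q
528	461	tRNA
			product	tRNA-Gln
537	656	D-loop
			note	control region
```

Reading it: each feature starts with a location line (start, end, feature
key — three tab-separated fields) followed by qualifier lines (three empty
fields, qualifier name, value — five fields). `nad3` occupies genome
positions 103–448; its length (448−103+1 = 346) is 1 mod 3 and it ends on
a bare `T`, so translation terminates at position 448 via the
polyadenylated stop. `Q` prints `528 461` (start > end): it lies on the
reverse strand. The control region becomes a `D-loop` feature with no
paired `gene` feature.

Genes split across the circular origin, partial genes (`<`/`>` markers)
and duplicated gene names cannot be handled automatically and must be
annotated manually, as with the upstream annotators this tool complements.

## Converting MITOS output

`mitos2aln` builds the mapped assembly from a genome FASTA plus a
MITOS-style gene FASTA (ungapped sequences, four semicolon-separated
header fields, gene name last, `trn`-prefixed tRNA names):

```
mitos2aln -f genome.fas -m genes.fas -o assembly.fas --genes-out forward_genes.txt
```

Each gene is located by exact sequence search (forward strand first, then
reverse complement), names are normalized (`trnM` → `M`, `trnL1` → `L1`),
and the forward-genes list is written as a convenience. The resulting
alignment can be curated in an editor and fed to `aln2tbl`.

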