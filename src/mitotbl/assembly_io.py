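"""Reading and validation of the mapped-assembly FASTA and forward-genes list.

A *mapped assembly* is a multi-FASTA alignment in which the first record is
the complete, ungapped mitogenome and every following record is one gene,
written as a row of exactly the genome's length: gap characters (``-``)
everywhere except the gene's genomic span, which carries the gene sequence
on the forward strand.  This is the format produced by mapping curated gene
sequences onto the genome in an alignment editor (Aliview, Seaview) or by
:mod:`mitotbl.mitos_bridge` from automatic annotator output.

Coordinates are 1-based, fully closed intervals, matching the feature-table
convention used by DDBJ/ENA/GenBank.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

from Bio import SeqIO

log = logging.getLogger("mitotbl")

GAP = "-"


class AssemblyError(ValueError):
    """Raised for malformed mapped-assembly or gene-list input."""


@dataclass(frozen=True)
class GeneInterval:
    """A 1-based, closed genomic interval (start <= end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise AssemblyError(
                f"invalid interval ({self.start}, {self.end}): need 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MappedAssembly:
    """Parsed mapped-assembly alignment: genome plus one gapped row per gene."""

    seq_id: str
    genome: str
    rows: list[tuple[str, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.genome)

    def to_fasta(self, width: int = 0) -> str:
        """Re-serialize as FASTA. ``width=0`` writes each sequence on one line."""
        out: list[str] = []

        def emit(name: str, seq: str) -> None:
            out.append(f">{name}")
            if width > 0:
                out.extend(seq[i : i + width] for i in range(0, len(seq), width))
            else:
                out.append(seq)

        emit(self.seq_id, self.genome)
        for name, seq in self.rows:
            emit(name, seq)
        return "\n".join(out) + "\n"


def _check_alphabet(name: str, seq: str) -> None:
    if "." in seq:
        raise AssemblyError(
            f"record '{name}' uses '.' as a gap character; only '-' is accepted "
            "(re-export the alignment with '-' gaps)"
        )


def parse_assembly(fasta_text: str) -> MappedAssembly:
    """Parse a mapped-assembly FASTA.

    The first record is taken to be the complete genome; every later record
    is a gene row.  Sequences are uppercased; row order is preserved (the
    downstream table keeps input order — submission tools reorder features
    themselves if needed).

    Raises
    ------
    AssemblyError
        If there are fewer than two records, the genome contains gaps, a
        row's length differs from the genome's, a row is all gaps, a gap
        character other than ``-`` is used, or two rows share a name.
    """
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if len(records) < 2:
        raise AssemblyError(
            f"mapped assembly needs the genome plus at least one gene row; "
            f"got {len(records)} record(s)"
        )

    genome_rec, gene_recs = records[0], records[1:]
    genome = str(genome_rec.seq).upper()
    _check_alphabet(genome_rec.id, genome)
    if GAP in genome:
        raise AssemblyError(
            f"genome record '{genome_rec.id}' (first record) contains gap "
            "characters; the complete ungapped mitogenome must come first"
        )
    if not genome:
        raise AssemblyError(f"genome record '{genome_rec.id}' is empty")

    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in gene_recs:
        name = rec.id  # first whitespace-delimited header token
        seq = str(rec.seq).upper()
        _check_alphabet(name, seq)
        if len(seq) != len(genome):
            raise AssemblyError(
                f"gene row '{name}' has length {len(seq)} but the genome has "
                f"length {len(genome)}; all rows must align to the genome"
            )
        if seq.count(GAP) == len(seq):
            raise AssemblyError(f"gene row '{name}' is all gaps")
        if name in seen:
            raise AssemblyError(
                f"duplicate gene name '{name}': duplicated genes cannot be "
                "annotated automatically and must be handled manually"
            )
        seen.add(name)
        if GAP not in seq:
            log.warning(
                "gene row '%s' has no gaps (spans the whole genome); "
                "check that the genome is really the first record",
                name,
            )
        rows.append((name, seq))

    return MappedAssembly(seq_id=genome_rec.id, genome=genome, rows=rows)


def parse_forward_genes(text: str) -> set[str]:
    """Parse the forward-strand gene list: one line, comma-separated, no spaces.

    Genes named here are annotated on the forward strand; every other row is
    treated as reverse-strand.  The control region belongs in this list if it
    is to be annotated forward.
    """
    stripped = text.strip("\r\n")
    if not stripped.strip():
        raise AssemblyError("forward-genes list is empty")
    names: set[str] = set()
    for token in stripped.split(","):
        if token == "":
            continue
        if any(ch.isspace() for ch in token):
            raise AssemblyError(
                f"forward-genes entry '{token}' contains whitespace; names "
                "must be separated by commas without spaces"
            )
        names.add(token)
    if not names:
        raise AssemblyError("forward-genes list contains no names")
    return names


def check_forward_names(forward: set[str], assembly: MappedAssembly) -> None:
    """Warn about forward-list names that match no assembly row."""
    row_names = {name for name, _ in assembly.rows}
    for name in sorted(forward - row_names):
        log.warning("forward-genes entry '%s' matches no row in the assembly", name)


def locate_gene(gapped_seq: str) -> GeneInterval:
    """Find a gene row's genomic span: first to last non-gap character, 1-based.

    A mapped gene must be one contiguous block; a gap strictly inside the
    span means the row was split, which this format cannot represent
    (partial/split genes need manual annotation), so it is a hard error.
    """
    n = len(gapped_seq)
    first = next((i for i in range(n) if gapped_seq[i] != GAP), None)
    if first is None:
        raise AssemblyError("gene row is all gaps")
    last = next(i for i in range(n - 1, -1, -1) if gapped_seq[i] != GAP)
    if GAP in gapped_seq[first : last + 1]:
        raise AssemblyError(
            f"gene row has internal gap(s) between positions {first + 1} and "
            f"{last + 1}; split genes are not supported — fix the alignment"
        )
    return GeneInterval(first + 1, last + 1)


def verify_row_identity(
    assembly: MappedAssembly, row_seq: str, interval: GeneInterval | None = None
) -> tuple[bool, str]:
    """Check that a row's ungapped sequence equals the genome slice it covers.

    Case-insensitive; IUPAC ambiguity codes compare as literal characters.
    A mismatch is reported (first differing genome position), never fatal:
    curators sometimes extend genes beyond the originally mapped read.
    """
    if interval is None:
        interval = locate_gene(row_seq)
    gene = row_seq[interval.start - 1 : interval.end].upper()
    ref = assembly.genome[interval.start - 1 : interval.end].upper()
    if gene == ref:
        return True, "identical"
    offset = next(i for i, (a, b) in enumerate(zip(gene, ref)) if a != b)
    pos = interval.start + offset
    report = (
        f"row differs from genome at position {pos} "
        f"(row '{gene[offset]}' vs genome '{ref[offset]}')"
    )
    log.warning("%s", report)
    return False, report


def extract_gene(assembly: MappedAssembly, interval: GeneInterval) -> str:
    """Forward-strand genome substring covered by *interval*."""
    return assembly.genome[interval.start - 1 : interval.end]
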