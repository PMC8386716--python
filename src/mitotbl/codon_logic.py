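"""Genetic-code tables and CDS start/stop analysis.

Animal mitochondrial CDSs frequently start at non-canonical codons and end
on truncated stop codons — a bare ``T`` or ``TA`` at the 3' end of the
mRNA, completed to ``TAA`` by post-transcriptional polyadenylation.  Both
cases are legitimate and are annotated in feature tables with
``transl_except`` qualifiers rather than treated as errors.  A CDS whose
final in-frame codon is neither a stop nor a recognized truncation, on the
other hand, indicates a curation mistake and is flagged.

Genetic codes are the NCBI translation tables (bundled with Biopython, no
network access), keyed by the NCBI table id: 2 vertebrate mitochondrial,
5 invertebrate mitochondrial, etc.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .assembly_io import GeneInterval

log = logging.getLogger("mitotbl")

POLYA_NOTE = "TAA stop codon is completed by the addition of 3' A residues to the mRNA"

_BASES = "TCAG"
_ALL_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]


class CodonError(ValueError):
    """Raised for unsupported genetic codes or degenerate coding sequences."""


@dataclass(frozen=True)
class GeneticCode:
    """One NCBI translation table: 64-codon map plus start/stop sets."""

    table_id: int
    codon_to_aa: dict[str, str]  # DNA codons -> amino-acid letter, '*' = stop
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[codon]


def supported_tables() -> list[int]:
    return sorted(CodonTable.unambiguous_dna_by_id)


def load_code(table_id: int) -> GeneticCode:
    """Load an NCBI translation table (e.g. 2 vertebrate mito, 5 invertebrate)."""
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError:
        raise CodonError(
            f"unsupported genetic code {table_id}; supported NCBI table ids: "
            f"{', '.join(map(str, supported_tables()))}"
        ) from None
    codon_to_aa = {c: table.forward_table.get(c, "*") for c in _ALL_CODONS}
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        start_codons=frozenset(table.start_codons),
        stop_codons=frozenset(table.stop_codons),
    )


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return str(Seq(seq).reverse_complement())


def orient(genome: str, interval: GeneInterval, is_forward: bool) -> str:
    """Extract the coding-strand sequence of a gene.

    Forward genes are the genome substring as-is; reverse genes are its
    reverse complement, so the result always reads 5'→3' in coding order.
    """
    sub = genome[interval.start - 1 : interval.end]
    return sub if is_forward else reverse_complement(sub)


@dataclass(frozen=True)
class CdsCodonReport:
    """Start/stop classification of one coding sequence."""

    start_status: str  # canonical | non_canonical
    stop_status: str  # full_stop | truncated_T | truncated_TA | invalid
    first_codon: str
    terminal_bases: str
    remainder: int  # len(cds) mod 3


def analyze_cds(coding_sequence: str, code: GeneticCode) -> CdsCodonReport:
    """Classify the start codon and the 3' end of a coding sequence.

    The start is canonical iff the first codon is in the table's start set
    (mitochondrial tables are broad here: e.g. GTG is a canonical start
    under table 5).  The 3' end is classified by length mod 3:

    * remainder 0 — full stop iff the last codon is in the stop set,
      otherwise invalid;
    * remainder 1 — a truncated ``T`` stop iff the trailing base is T,
      otherwise invalid;
    * remainder 2 — a truncated ``TA`` stop iff the trailing bases are TA,
      otherwise invalid.

    Ambiguous bases (N, R, Y, ...) at the decisive positions classify as
    non-canonical/invalid with a distinct log message, never guessed.
    """
    seq = coding_sequence.upper()
    if len(seq) < 6:
        raise CodonError(
            f"coding sequence of length {len(seq)} is too short for a CDS (< 6)"
        )
    first = seq[:3]
    remainder = len(seq) % 3

    if first in code.start_codons:
        start_status = "canonical"
    else:
        start_status = "non_canonical"
        if first not in code.codon_to_aa:
            log.warning(
                "start codon '%s' contains ambiguous bases; treated as "
                "non-canonical", first,
            )

    if remainder == 0:
        terminal = seq[-3:]
        if terminal in code.stop_codons:
            stop_status = "full_stop"
        else:
            stop_status = "invalid"
            if terminal not in code.codon_to_aa:
                log.warning(
                    "terminal codon '%s' contains ambiguous bases; treated "
                    "as invalid stop", terminal,
                )
    elif remainder == 1:
        terminal = seq[-1:]
        stop_status = "truncated_T" if terminal == "T" else "invalid"
    else:
        terminal = seq[-2:]
        stop_status = "truncated_TA" if terminal == "TA" else "invalid"

    return CdsCodonReport(start_status, stop_status, first, terminal, remainder)


def _coding_positions(interval: GeneInterval, is_forward: bool) -> range:
    """Genomic positions of the coding sequence, in 5'→3' coding order."""
    if is_forward:
        return range(interval.start, interval.end + 1)
    return range(interval.end, interval.start - 1, -1)


def transl_except_qualifiers(
    report: CdsCodonReport,
    interval: GeneInterval,
    is_forward: bool,
    annotate_start: bool = True,
) -> list[tuple[str, str]]:
    """Translation-exception qualifiers for a CDS, as (name, value) pairs.

    Truncated stops yield ``transl_except (pos:P,aa:TERM)`` (one position
    for a bare T, a two-position range for TA) plus the standard
    polyadenylation note.  A non-canonical start yields
    ``transl_except (pos:S1..S3,aa:Met)`` over the first codon plus a note
    naming the observed codon (suppressed with ``annotate_start=False``).
    Positions are genomic; for reverse-strand genes they are printed in
    coding order (descending), matching the table's reversed-coordinate
    convention.  A canonical start with a full stop yields no qualifiers;
    an invalid stop is the caller's problem (it becomes an error marker in
    the table, not a translation exception).

    All ``transl_except`` pairs precede all ``note`` pairs so qualifier
    order in the rendered table is deterministic.
    """
    positions = _coding_positions(interval, is_forward)
    excepts: list[tuple[str, str]] = []
    notes: list[tuple[str, str]] = []

    if report.start_status == "non_canonical" and annotate_start:
        s1, s3 = positions[0], positions[2]
        excepts.append(("transl_except", f"(pos:{s1}..{s3},aa:Met)"))
        notes.append(
            ("note", f"non-canonical start codon {report.first_codon} translated as Met")
        )

    if report.stop_status == "truncated_T":
        p = positions[-1]
        excepts.append(("transl_except", f"(pos:{p},aa:TERM)"))
        notes.append(("note", POLYA_NOTE))
    elif report.stop_status == "truncated_TA":
        p1, p2 = positions[-2], positions[-1]
        excepts.append(("transl_except", f"(pos:{p1}..{p2},aa:TERM)"))
        notes.append(("note", POLYA_NOTE))
        log.warning(
            "use of truncated TA stop codons is discouraged as this is not "
            "recognized by some downstream applications; a truncated T codon "
            "can be used as a substitute"
        )

    return excepts + notes
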