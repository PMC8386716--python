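"""Conversion of MITOS-style gene FASTA output into a mapped assembly.

MITOS (an automatic mitogenome annotator) writes each predicted gene as an
ungapped FASTA record whose header carries four semicolon-separated fields,
the last being the gene name in MITOS nomenclature (``trnM``, ``trnL1``,
``cox1``, ...).  This module places each gene on the genome by exact
sequence search (forward, then reverse complement), normalizes the names to
the compact nomenclature the table builder expects (``M``, ``L1``, ...),
and emits the mapped-assembly alignment plus, as a convenience, the
forward-strand gene list.

Placement assumes the MITOS records are position ordered and identical to
the genome sequence (true for unedited MITOS output); genes that cannot be
found verbatim are a hard error.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

from Bio import SeqIO

from .assembly_io import GAP, GeneInterval
from .codon_logic import reverse_complement

log = logging.getLogger("mitotbl")


class MitosError(ValueError):
    """Raised for malformed MITOS FASTA input or unplaceable genes."""


@dataclass
class MitosRecord:
    """One MITOS FASTA entry: the four header fields plus the sequence."""

    header_fields: list[str]
    raw_name: str
    sequence: str


def parse_mitos_fasta(text: str) -> list[MitosRecord]:
    """Parse MITOS-style gene FASTA: four ``;``-separated header fields.

    The gene name is the last header field (MITOS convention); whitespace
    around fields is trimmed.  Records are returned in file order.
    """
    records: list[MitosRecord] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        header = rec.description
        fields = [f.strip() for f in header.split(";")]
        if len(fields) != 4:
            raise MitosError(
                f"record '{header}': expected 4 semicolon-separated header "
                f"fields, found {len(fields)}"
            )
        seq = str(rec.seq).upper()
        if not seq:
            raise MitosError(f"record '{header}' has an empty sequence")
        if GAP in seq:
            raise MitosError(f"record '{header}' contains gap characters")
        records.append(MitosRecord(fields, fields[-1], seq))
    if not records:
        raise MitosError("no FASTA records found in MITOS gene file")
    return records


#: trn-prefixed MITOS tRNA names map to the single-letter scheme.
def normalize_name(raw_name: str) -> str:
    """MITOS gene name -> compact name (``trnM``→``M``, ``trnL1``→``L1``).

    Names already in the compact scheme (the 13 protein-coding genes,
    rrnL/rrnS) pass through; unknown names also pass through and become
    miscellaneous features downstream.
    """
    if raw_name.startswith("trn") and len(raw_name) in (4, 5):
        return raw_name[3:]
    return raw_name


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def place_gene(
    genome: str, record: MitosRecord, min_start: int = 0
) -> tuple[GeneInterval, bool]:
    """Locate a MITOS gene on the genome by exact match.

    The forward strand is searched first; if the sequence is absent its
    reverse complement is searched (MITOS writes reverse-strand genes
    gene-oriented).  When several candidate positions exist, the first one
    at or after *min_start* (0-based; the previous record's start, since
    records are position ordered) wins and a warning is logged; if both
    orientations match, forward wins with a warning.

    Returns the 1-based closed interval and whether the placement is
    forward-strand.
    """
    genome = genome.upper()
    fwd_hits = _find_all(genome, record.sequence)
    rev_hits = _find_all(genome, reverse_complement(record.sequence))
    if fwd_hits and rev_hits:
        log.warning(
            "gene '%s' matches both strands; keeping the forward placement",
            record.raw_name,
        )
    hits, is_forward = (fwd_hits, True) if fwd_hits else (rev_hits, False)
    if not hits:
        raise MitosError(
            f"gene '{record.raw_name}' not found in the genome on either "
            "strand; MITOS input must be identical to the genome sequence"
        )
    if len(hits) > 1:
        log.warning(
            "gene '%s' matches the genome at %d positions; choosing the "
            "first at or after the previous gene's start",
            record.raw_name, len(hits),
        )
    start0 = next((h for h in hits if h >= min_start), hits[0])
    interval = GeneInterval(start0 + 1, start0 + len(record.sequence))
    return interval, is_forward


@dataclass
class Placement:
    name: str  # normalized gene name
    interval: GeneInterval
    is_forward: bool


def place_all(genome: str, records: list[MitosRecord]) -> list[Placement]:
    """Place every record; rename duplicate genes and demote them to misc.

    Two genes normalizing to the same name cannot both be annotated
    automatically (downstream tooling rejects duplicated gene names), so the
    second copy is suffixed ``-copy2`` (then ``-copy3``, ...), which turns it
    into a miscellaneous feature, and a warning is logged.
    """
    placements: list[Placement] = []
    counts: dict[str, int] = {}
    min_start = 0
    for rec in records:
        interval, is_forward = place_gene(genome, rec, min_start)
        # advance strictly past this start so an identical duplicated gene
        # takes its next occurrence instead of colliding on the same spot
        min_start = interval.start
        name = normalize_name(rec.raw_name)
        counts[name] = counts.get(name, 0) + 1
        if counts[name] > 1:
            renamed = f"{name}-copy{counts[name]}"
            log.warning(
                "duplicated gene name '%s' (from '%s'): renamed to '%s' and "
                "demoted to miscellaneous feature; annotate manually",
                name, rec.raw_name, renamed,
            )
            name = renamed
        placements.append(Placement(name, interval, is_forward))
    return placements


def emit_alignment(
    genome_id: str, genome: str, placements: list[Placement]
) -> tuple[str, str]:
    """Build the mapped-assembly FASTA text and the forward-genes line.

    Each gene becomes a row of the genome's length: gaps everywhere except
    its interval, which carries the genome's forward-strand substring
    (strandedness lives in the forward-genes list, not in the row).  The
    forward-genes line is a convenience companion output listing the
    forward placements comma-separated.
    """
    if not placements:
        log.warning("no genes to place; emitting the genome alone")
    lines = [f">{genome_id}", genome.upper()]
    for p in placements:
        row = (
            GAP * (p.interval.start - 1)
            + genome[p.interval.start - 1 : p.interval.end].upper()
            + GAP * (len(genome) - p.interval.end)
        )
        lines.append(f">{p.name}")
        lines.append(row)
    fasta = "\n".join(lines) + "\n"
    forward = ",".join(p.name for p in placements if p.is_forward)
    return fasta, forward
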