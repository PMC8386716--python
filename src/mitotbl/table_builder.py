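"""Assembly of gene annotations into a five-column feature table.

The DDBJ/ENA/GenBank feature table is a tab-delimited text format: a header
line ``>Feature SEQ_ID``, then for each feature a location line
``START<TAB>END<TAB>KEY`` followed by qualifier lines
``<TAB><TAB><TAB>NAME<TAB>VALUE`` (three empty columns, so five columns in
all).  Strand is encoded by coordinate order: reverse-strand features print
START > END.

Each gene row of the mapped assembly becomes a ``gene`` feature paired with
a typed feature (CDS, tRNA or rRNA) at the same location.  Control regions
become a single ``D-loop`` feature and unknown names a single
``misc_feature`` — neither is a gene, so no paired gene feature is emitted.
A CDS whose terminal codon is neither a stop nor a recognized truncation
gets the literal note ``ERROR IN STOP CODON`` so the curator can fix the
alignment and rerun.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import codon_logic, nomenclature
from .assembly_io import (
    MappedAssembly,
    check_forward_names,
    locate_gene,
    verify_row_identity,
)
from .codon_logic import GeneticCode, analyze_cds, orient, transl_except_qualifiers

log = logging.getLogger("mitotbl")

STOP_ERROR_NOTE = "ERROR IN STOP CODON"

FEATURE_KEYS = ("gene", "CDS", "tRNA", "rRNA", "D-loop", "misc_feature")


@dataclass
class Feature:
    """One table feature: key, printed coordinates and ordered qualifiers.

    ``start > end`` encodes the reverse strand, as in the printed table.
    """

    key: str
    start: int
    end: int
    qualifiers: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_forward(self) -> bool:
        return self.start <= self.end


@dataclass
class FeatureTable:
    seq_id: str
    features: list[Feature] = field(default_factory=list)

    @property
    def stop_errors(self) -> int:
        """Number of CDS features flagged with the stop-codon error marker."""
        return sum(
            1
            for f in self.features
            if f.key == "CDS" and ("note", STOP_ERROR_NOTE) in f.qualifiers
        )


def _printed_coords(start: int, end: int, is_forward: bool) -> tuple[int, int]:
    return (start, end) if is_forward else (end, start)


def build_features(
    assembly: MappedAssembly,
    forward_set: set[str],
    code: GeneticCode,
    *,
    products: dict[str, str] | None = None,
    annotate_start: bool = True,
    control_region_key: str = "D-loop",
) -> FeatureTable:
    """Convert a validated mapped assembly into a feature table.

    Rows are processed in input order and never dropped.  Genes absent from
    *forward_set* are treated as reverse-strand: their printed coordinates
    are swapped and their sequence is reverse-complemented before codon
    analysis.  CDS qualifiers are emitted in a fixed order (product,
    transl_table, transl_except..., note...) so output is deterministic.

    *products* overrides default product strings; *annotate_start* toggles
    translation-exception annotation of non-canonical start codons;
    *control_region_key* may be set to ``misc_feature`` for databases that
    prefer it over ``D-loop``.
    """
    check_forward_names(forward_set, assembly)
    table = FeatureTable(seq_id=assembly.seq_id)

    for name, row_seq in assembly.rows:
        interval = locate_gene(row_seq)
        verify_row_identity(assembly, row_seq, interval)
        is_forward = name in forward_set
        identity = nomenclature.classify(name, products)
        start, end = _printed_coords(interval.start, interval.end, is_forward)

        if identity.category == "control_region":
            table.features.append(
                Feature(control_region_key, start, end, [("note", "control region")])
            )
            continue
        if identity.category == "misc":
            table.features.append(
                Feature("misc_feature", start, end, [("note", name)])
            )
            continue

        table.features.append(Feature("gene", start, end, [("gene", name)]))

        if identity.category == "CDS":
            cds = orient(assembly.genome, interval, is_forward)
            report = analyze_cds(cds, code)
            quals: list[tuple[str, str]] = [
                ("product", identity.product or name),
                ("transl_table", str(code.table_id)),
            ]
            if report.stop_status == "invalid":
                quals.append(("note", STOP_ERROR_NOTE))
                log.error(
                    "CDS '%s' ends with non-canonical stop '%s'; correct the "
                    "input alignment and run again", name, report.terminal_bases,
                )
            else:
                quals.extend(
                    transl_except_qualifiers(
                        report, interval, is_forward, annotate_start=annotate_start
                    )
                )
            table.features.append(Feature("CDS", start, end, quals))
        elif identity.category == "tRNA":
            quals = [("product", identity.product or name)]
            if identity.trna_codon_family:
                quals.append(
                    ("note", f"codons recognized: {identity.trna_codon_family}")
                )
            table.features.append(Feature("tRNA", start, end, quals))
        else:  # rRNA
            table.features.append(
                Feature("rRNA", start, end, [("product", identity.product or name)])
            )

    return table


def render(table: FeatureTable) -> str:
    """Render the five-column, tab-delimited table text.

    Location lines have exactly 3 tab-separated fields, qualifier lines
    exactly 5; no line has trailing whitespace and the text ends with a
    newline.
    """
    lines = [f">Feature {table.seq_id}"]
    for feat in table.features:
        lines.append(f"{feat.start}\t{feat.end}\t{feat.key}")
        for name, value in feat.qualifiers:
            lines.append(f"\t\t\t{name}\t{value}")
    return "\n".join(lines) + "\n"


def parse_table(text: str) -> FeatureTable:
    """Parse rendered five-column table text back into a :class:`FeatureTable`.

    Inverse of :func:`render` for tables this package writes; used for
    round-trip verification.
    """
    lines = text.splitlines()
    if not lines or not lines[0].startswith(">Feature "):
        raise ValueError("not a feature table: missing '>Feature' header")
    table = FeatureTable(seq_id=lines[0][len(">Feature ") :])
    current: Feature | None = None
    for lineno, line in enumerate(lines[1:], 2):
        fields = line.split("\t")
        if len(fields) == 3:
            current = Feature(fields[2], int(fields[0]), int(fields[1]))
            table.features.append(current)
        elif len(fields) == 5 and fields[0] == fields[1] == fields[2] == "":
            if current is None:
                raise ValueError(f"line {lineno}: qualifier before any feature")
            current.qualifiers.append((fields[3], fields[4]))
        else:
            raise ValueError(f"line {lineno}: malformed table line {line!r}")
    return table
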