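"""Synthetic mitogenome fixture generator.

Builds deterministic test genomes gene-by-gene under a chosen NCBI genetic
code, so every planted start style (canonical / non-canonical) and stop
style (full stop / truncated T / truncated TA / invalid) is realized
exactly, on either strand.  Alongside the mapped-assembly FASTA and the
forward-genes list it returns the ground-truth :class:`FeatureTable`
derived from the planting coordinates by direct arithmetic — the oracle
against which the converter's output is compared feature-for-feature.

The default plan emulates the canonical animal mitogenome: 13 protein-coding
genes, 2 ribosomal RNAs and 22 tRNAs (37 genes) plus a control region, with
realistic gene lengths and a mix of strands and truncated stops.  Base
composition is uniform random, which is unrealistic for real mitogenomes
(AT-rich, strand-asymmetric) but irrelevant to coordinate and codon logic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import nomenclature
from .assembly_io import GAP, GeneInterval
from .codon_logic import GeneticCode, load_code, reverse_complement
from .table_builder import STOP_ERROR_NOTE, Feature, FeatureTable


class FixtureError(ValueError):
    """Raised for gene plans that cannot be realized (e.g. bad mod-3 length)."""


@dataclass(frozen=True)
class GenePlan:
    """One planted gene: name, span length and, for CDSs, codon styles."""

    name: str
    length: int
    strand: str = "+"  # '+' forward, '-' reverse
    stop_style: str | None = None  # CDS only: full | T | TA | invalid
    start_style: str = "canonical"  # CDS only: canonical | non_canonical


@dataclass
class SyntheticGenomeSpec:
    seed: int
    gene_plan: list[GenePlan]
    code_id: int = 5
    spacer_lengths: list[int] | None = None  # cycled; random 20-100 bp if None


@dataclass
class Fixture:
    """A generated genome with its ground-truth annotation."""

    seq_id: str
    genome: str
    assembly_fasta: str
    forward_genes: str
    expected: FeatureTable
    plantings: list[tuple[GenePlan, GeneInterval]] = field(default_factory=list)


_REQUIRED_REMAINDER = {"full": 0, "invalid": 0, "T": 1, "TA": 2}


def _pick(rng: random.Random, items: list[str]) -> str:
    return items[rng.randrange(len(items))]


def _build_cds(plan: GenePlan, code: GeneticCode, rng: random.Random) -> str:
    """Coding-orientation CDS sequence realizing the planned codon styles."""
    if plan.stop_style not in _REQUIRED_REMAINDER:
        raise FixtureError(f"gene '{plan.name}': unknown stop style {plan.stop_style!r}")
    need = _REQUIRED_REMAINDER[plan.stop_style]
    if plan.length % 3 != need:
        raise FixtureError(
            f"gene '{plan.name}': length {plan.length} has remainder "
            f"{plan.length % 3} mod 3 but stop style '{plan.stop_style}' "
            f"needs {need}"
        )
    if plan.length < 9:
        raise FixtureError(f"gene '{plan.name}': CDS length {plan.length} < 9")

    non_stop = sorted(c for c, aa in code.codon_to_aa.items() if aa != "*")
    if plan.start_style == "canonical":
        first = "ATG" if "ATG" in code.start_codons else sorted(code.start_codons)[0]
    elif plan.start_style == "non_canonical":
        first = _pick(rng, [c for c in non_stop if c not in code.start_codons])
    else:
        raise FixtureError(f"gene '{plan.name}': unknown start style {plan.start_style!r}")

    if plan.stop_style == "full":
        terminal = "TAA" if "TAA" in code.stop_codons else sorted(code.stop_codons)[0]
    elif plan.stop_style == "invalid":
        terminal = "CCC"  # proline in every NCBI table, never a stop
    elif plan.stop_style == "T":
        terminal = "T"
    else:
        terminal = "TA"

    n_middle = (plan.length - 3 - len(terminal)) // 3
    middle = "".join(_pick(rng, non_stop) for _ in range(n_middle))
    seq = first + middle + terminal
    assert len(seq) == plan.length
    return seq


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(_pick(rng, ["A", "C", "G", "T"]) for _ in range(length))


def _cds_expected_qualifiers(
    plan: GenePlan,
    interval: GeneInterval,
    identity,
    code: GeneticCode,
    first_codon: str,
) -> list[tuple[str, str]]:
    """Ground-truth CDS qualifiers from the planting log (coordinate arithmetic)."""
    from .codon_logic import POLYA_NOTE

    quals = [
        ("product", identity.product or plan.name),
        ("transl_table", str(code.table_id)),
    ]
    forward = plan.strand == "+"
    excepts: list[tuple[str, str]] = []
    notes: list[tuple[str, str]] = []
    if plan.start_style == "non_canonical":
        if forward:
            s1, s3 = interval.start, interval.start + 2
        else:
            s1, s3 = interval.end, interval.end - 2
        excepts.append(("transl_except", f"(pos:{s1}..{s3},aa:Met)"))
        notes.append(
            ("note", f"non-canonical start codon {first_codon} translated as Met")
        )
    if plan.stop_style == "T":
        p = interval.end if forward else interval.start
        excepts.append(("transl_except", f"(pos:{p},aa:TERM)"))
        notes.append(("note", POLYA_NOTE))
    elif plan.stop_style == "TA":
        if forward:
            p1, p2 = interval.end - 1, interval.end
        else:
            p1, p2 = interval.start + 1, interval.start
        excepts.append(("transl_except", f"(pos:{p1}..{p2},aa:TERM)"))
        notes.append(("note", POLYA_NOTE))
    elif plan.stop_style == "invalid":
        return quals + [("note", STOP_ERROR_NOTE)]
    return quals + excepts + notes


def generate_fixture(spec: SyntheticGenomeSpec, seq_id: str = "synthmito1") -> Fixture:
    """Generate a synthetic genome, its mapped assembly and the expected table.

    Deterministic for a fixed spec (byte-identical outputs across runs).
    """
    rng = random.Random(spec.seed)
    code = load_code(spec.code_id)
    spacers = spec.spacer_lengths

    parts: list[str] = []
    pos = 0  # 0-based running genome length
    plantings: list[tuple[GenePlan, GeneInterval, str]] = []

    def next_spacer(i: int) -> int:
        if spacers:
            return spacers[i % len(spacers)]
        return rng.randint(20, 100)

    for i, plan in enumerate(spec.gene_plan):
        spacer = _random_dna(rng, next_spacer(i))
        parts.append(spacer)
        pos += len(spacer)

        identity = nomenclature.classify(plan.name)
        if identity.category == "CDS":
            if plan.stop_style is None:
                raise FixtureError(f"gene '{plan.name}': CDS needs a stop style")
            coding = _build_cds(plan, code, rng)
        else:
            if plan.length < 1:
                raise FixtureError(f"gene '{plan.name}': non-positive length")
            coding = _random_dna(rng, plan.length)

        genomic = coding if plan.strand == "+" else reverse_complement(coding)
        parts.append(genomic)
        interval = GeneInterval(pos + 1, pos + plan.length)
        pos += plan.length
        plantings.append((plan, interval, coding))

    parts.append(_random_dna(rng, next_spacer(len(spec.gene_plan))))
    genome = "".join(parts)

    # mapped-assembly rows carry the forward-strand genome substring
    fasta_lines = [f">{seq_id}", genome]
    for plan, interval, _ in plantings:
        row = (
            GAP * (interval.start - 1)
            + genome[interval.start - 1 : interval.end]
            + GAP * (len(genome) - interval.end)
        )
        fasta_lines.extend([f">{plan.name}", row])
    assembly_fasta = "\n".join(fasta_lines) + "\n"

    forward_genes = ",".join(p.name for p, _, _ in plantings if p.strand == "+")

    expected = FeatureTable(seq_id=seq_id)
    for plan, interval, coding in plantings:
        identity = nomenclature.classify(plan.name)
        forward = plan.strand == "+"
        start, end = (
            (interval.start, interval.end) if forward else (interval.end, interval.start)
        )
        if identity.category == "control_region":
            expected.features.append(
                Feature("D-loop", start, end, [("note", "control region")])
            )
            continue
        if identity.category == "misc":
            expected.features.append(
                Feature("misc_feature", start, end, [("note", plan.name)])
            )
            continue
        expected.features.append(Feature("gene", start, end, [("gene", plan.name)]))
        if identity.category == "CDS":
            quals = _cds_expected_qualifiers(plan, interval, identity, code, coding[:3])
            expected.features.append(Feature("CDS", start, end, quals))
        elif identity.category == "tRNA":
            quals = [("product", identity.product or plan.name)]
            if identity.trna_codon_family:
                quals.append(("note", f"codons recognized: {identity.trna_codon_family}"))
            expected.features.append(Feature("tRNA", start, end, quals))
        else:
            expected.features.append(
                Feature("rRNA", start, end, [("product", identity.product or plan.name)])
            )

    return Fixture(
        seq_id=seq_id,
        genome=genome,
        assembly_fasta=assembly_fasta,
        forward_genes=forward_genes,
        expected=expected,
        plantings=[(p, i) for p, i, _ in plantings],
    )


def mitos_fasta_for(fixture: Fixture) -> str:
    """Render the fixture's genes as a MITOS-style FASTA (for bridge tests).

    Headers carry the four semicolon-separated fields MITOS writes; the gene
    name (last field) uses MITOS nomenclature (``trnM`` for ``M``).  Reverse
    genes are written gene-oriented, as MITOS does.
    """
    lines: list[str] = []
    for plan, interval in fixture.plantings:
        name = plan.name
        if name in nomenclature.AA3 or name in nomenclature.TRNA_FAMILIES:
            name = f"trn{name}"
        seq = fixture.genome[interval.start - 1 : interval.end]
        if plan.strand == "-":
            seq = reverse_complement(seq)
        lines.append(
            f">{fixture.seq_id}; {interval.start}-{interval.end}; {plan.strand}; {name}"
        )
        lines.append(seq)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Stock gene plans

#: Realistic animal mitogenome gene lengths (bp), full-stop variants.
_CDS_LENGTHS = {
    "atp6": 681, "atp8": 168, "cob": 1140, "cox1": 1536, "cox2": 684,
    "cox3": 786, "nad1": 957, "nad2": 1038, "nad3": 348, "nad4": 1377,
    "nad4L": 297, "nad5": 1716, "nad6": 522,
}

_TRNA_ORDER = [
    "F", "V", "L1", "I", "Q", "M", "W", "A", "N", "C", "Y", "S2", "D",
    "K", "G", "R", "H", "S1", "L2", "E", "T", "P",
]

_REVERSE_DEFAULT = {"nad1", "nad4", "nad4L", "nad5", "Q", "A", "N", "C", "Y", "E", "P"}


def _cds_length_for(name: str, stop_style: str) -> int:
    base = _CDS_LENGTHS[name]
    return base - {"full": 0, "invalid": 0, "T": 2, "TA": 1}[stop_style]


def full_gene_plan(
    stop_styles: dict[str, str] | None = None,
    start_styles: dict[str, str] | None = None,
) -> list[GenePlan]:
    """The canonical 37-gene animal mitochondrial complement plus control region.

    Gene order loosely follows the vertebrate arrangement; eleven genes sit
    on the reverse strand.  *stop_styles* / *start_styles* override the
    defaults (full stop, canonical start) per CDS name.
    """
    stop_styles = stop_styles or {}
    start_styles = start_styles or {}
    plan: list[GenePlan] = []
    trnas = iter(_TRNA_ORDER)

    def trna(n: int) -> list[GenePlan]:
        out = []
        for _ in range(n):
            name = next(trnas)
            strand = "-" if name in _REVERSE_DEFAULT else "+"
            out.append(GenePlan(name, 66 + len(name), strand))
        return out

    plan += trna(2)
    plan.append(GenePlan("rrnS", 804, "+"))
    plan.append(GenePlan("rrnL", 1302, "+"))
    plan += trna(1)
    for name in ("nad1", "nad2", "cox1", "cox2", "atp8", "atp6", "cox3",
                 "nad3", "nad4L", "nad4", "nad5", "nad6", "cob"):
        stop = stop_styles.get(name, "full")
        start = start_styles.get(name, "canonical")
        strand = "-" if name in _REVERSE_DEFAULT else "+"
        plan.append(GenePlan(name, _cds_length_for(name, stop), strand, stop, start))
    plan += trna(len(_TRNA_ORDER) - 3)
    plan.append(GenePlan("control_region", 512, "+"))
    return plan


def random_gene_plan(rng: random.Random, n_cds: int = 6) -> list[GenePlan]:
    """A randomized plan mixing strands and all four stop styles."""
    names = list(_CDS_LENGTHS)
    rng.shuffle(names)
    styles = ["full", "T", "TA", "invalid"]
    plan: list[GenePlan] = []
    trnas = list(_TRNA_ORDER)
    rng.shuffle(trnas)
    for i, name in enumerate(names[:n_cds]):
        stop = styles[i % len(styles)] if i < len(styles) else rng.choice(styles)
        start = rng.choice(["canonical", "non_canonical"])
        strand = rng.choice("+-")
        plan.append(GenePlan(name, _cds_length_for(name, stop), strand, stop, start))
        plan.append(GenePlan(trnas[i], 66, rng.choice("+-")))
    plan.append(GenePlan("rrnS", 801, rng.choice("+-")))
    plan.append(GenePlan("control_region", 256, "+"))
    return plan
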