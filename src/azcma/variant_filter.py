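"""De-novo mutation calling filters and mutation classification.

Candidate variants from mutation-accumulation (MA) lines are screened against
their ancestor strain: a call is kept only when it is well supported in the
line (depth, allele support on both strands, site quality) and essentially
absent from the ancestor.  Retained single-base changes are then classified
into the six strand-collapsed base-change classes, the 96 pyrimidine-centred
trinucleotide contexts, and synonymous/nonsynonymous/stop-gained CDS effects
using a built-in codon-table classifier.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome import BASES, COMPLEMENT, Transcript, decode_seq, encode_seq
from .intervals import IntervalSet

# ---------------------------------------------------------------------------
# Six-class and 96-context labelling
# ---------------------------------------------------------------------------

#: strand-collapsed single-base substitution classes
SIX_CLASSES = (
    "C:G>T:A",
    "C:G>A:T",
    "C:G>G:C",
    "T:A>C:G",
    "T:A>G:C",
    "T:A>A:T",
)

#: the six pyrimidine-centred substitutions in COSMIC order
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the 96 trinucleotide substitution labels in COSMIC order
CONTEXTS_96 = tuple(
    f"{l}[{sub}]{r}" for sub in SUBSTITUTIONS for l in BASES for r in BASES
)


def classify_six(ref: str, alt: str) -> str:
    """Strand-collapsed six-class label of a single-base substitution.

    Purine reference bases are complemented first, so ``(G, C)`` and ``(C, G)``
    both map to ``C:G>G:C``.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
        raise ValueError(f"classify_six expects single ACGT bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":  # collapse to the pyrimidine strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}:{COMPLEMENT[ref]}>{alt}:{COMPLEMENT[alt]}"


def class_alt_map(six_class: str) -> dict[str, str]:
    """Per-reference-base alternate allele implied by a six-class label.

    For ``C:G>G:C`` this is ``{'C': 'G', 'G': 'C'}``: a site whose reference
    base is C mutates to G and vice versa.
    """
    if six_class not in SIX_CLASSES:
        raise ValueError(f"unknown six-class label {six_class!r}")
    frm, to = six_class.split(">")
    f1, f2 = frm.split(":")
    t1, t2 = to.split(":")
    return {f1: t1, f2: t2}


def trinuc_context(
    sequences: dict[str, np.ndarray], chrom: str, pos1: int, ref: str, alt: str
) -> str:
    """96-context label ``N[P>Q]N`` of an SNV at a 1-based position.

    The genome base at ``pos1`` must equal ``ref``.  Purine-reference sites
    are reverse-complemented so every SNV maps onto a pyrimidine-centred
    label.  Positions at a contig edge have no flanking context and raise
    ``ValueError``; callers tally such exclusions.
    """
    seq = sequences[chrom]
    i = pos1 - 1
    if i < 1 or i >= len(seq) - 1:
        raise ValueError(f"{chrom}:{pos1} is at a contig edge; no trinucleotide context")
    genome_ref = BASES[int(seq[i])]
    if genome_ref != ref.upper():
        raise ValueError(f"reference mismatch at {chrom}:{pos1}: genome {genome_ref}, call {ref}")
    left, right = BASES[int(seq[i - 1])], BASES[int(seq[i + 1])]
    ref, alt = ref.upper(), alt.upper()
    if ref in "AG":
        left, right = COMPLEMENT[right], COMPLEMENT[left]
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{left}[{ref}>{alt}]{right}"


# ---------------------------------------------------------------------------
# CDS effect annotation
# ---------------------------------------------------------------------------


def _aa_table(table_id: int = 1) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    return aa


def annotate_cds_effect(
    chrom: str,
    pos1: int,
    ref: str,
    alt: str,
    transcripts: list[Transcript],
    sequences: dict[str, np.ndarray],
    table_id: int = 1,
) -> tuple[str, list[str]]:
    """Coding effect of an SNV: ``synonymous``, ``nonsynonymous``,
    ``stop-gained`` or ``noncoding``.

    When several CDS models contain the site, the primary effect is computed
    on the longest one; effects on all containing models are returned as the
    secondary list.  Minus-strand models are handled by complementing the
    change into the sense strand.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in BASES or alt not in BASES:
        raise ValueError("CDS effect is defined for single-base substitutions only")
    pos0 = pos1 - 1
    aa_of = _aa_table(table_id)
    hits = [t for t in transcripts if t.chrom == chrom and t.contains(pos0)]
    if not hits:
        return "noncoding", []
    hits.sort(key=lambda t: (-t.coding_length, t.name))
    effects = []
    for tr in hits:
        if tr.coding_length % 3 != 0:
            raise ValueError(f"CDS {tr.name} length not a multiple of 3")
        cpos = tr.coding_positions()
        off = int(np.nonzero(cpos == pos0)[0][0])
        codon_idx, within = divmod(off, 3)
        codes = tr.coding_codes(sequences)
        codon = codes[3 * codon_idx : 3 * codon_idx + 3].copy()
        sense_ref = BASES[int(codon[within])]
        sense_alt = alt if tr.strand == "+" else COMPLEMENT[alt]
        expect_ref = ref if tr.strand == "+" else COMPLEMENT[ref]
        if sense_ref != expect_ref:
            raise ValueError(
                f"frame inconsistency in {tr.name} at {chrom}:{pos1}: "
                f"codon base {sense_ref} != call ref {expect_ref}"
            )
        ref_aa = aa_of[decode_seq(codon)]
        codon[within] = encode_seq(sense_alt)[0]
        alt_aa = aa_of[decode_seq(codon)]
        if alt_aa == ref_aa:
            effects.append("synonymous")
        elif alt_aa == "*":
            effects.append("stop-gained")
        else:
            effects.append("nonsynonymous")
    return effects[0], effects


# ---------------------------------------------------------------------------
# MA-line filters
# ---------------------------------------------------------------------------


@dataclass
class VariantCall:
    """One candidate variant call in one sample (VCF 1-based convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    alt_reads: int
    alt_plus: int
    alt_minus: int
    line_id: str | None = None

    def __post_init__(self) -> None:
        if self.alt_reads > self.depth:
            raise ValueError("alt-supporting reads exceed depth")
        if self.qual < 0:
            raise ValueError("negative quality")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def kind(self) -> str:
        if self.is_snv:
            return "SNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"


@dataclass
class AncestorEvidence:
    """Read support observed in the ancestor strain at a candidate site."""

    depth: int
    alt_reads: int


@dataclass
class FilterConfig:
    """Thresholds of the de-novo mutation filters.

    Defaults: both the MA line and the ancestor need >=5x depth at the site,
    >=5 reads must support the alternate allele in the line while at most one
    may in the ancestor, site quality must exceed 30 and the alternate allele
    must be seen on both strands.
    """

    min_depth: int = 5
    min_alt_reads: int = 5
    max_ancestor_alt_reads: int = 1
    min_qual: float = 30.0
    require_both_strands: bool = True

    def __post_init__(self) -> None:
        for name in ("min_depth", "min_alt_reads", "max_ancestor_alt_reads", "min_qual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class MALineMeta:
    """Metadata of one mutation-accumulation line."""

    line_id: str
    genotype: str  # WT, dim2, dim5, dim2;dim5
    treatment: str  # 5AzC or control
    days: float
    transfers: int

    def __post_init__(self) -> None:
        if self.days <= 0:
            raise ValueError("days must be positive")
        if self.transfers > 0 and abs(self.days - 3 * self.transfers) > 1e-9:
            raise ValueError("each transfer cycle takes ~3 days: days must equal 3 x transfers")


#: fixed rejection bookkeeping order; a record failing several filters is
#: tallied under the first.
REJECTION_REASONS = (
    "no_ancestor_evidence",
    "line_depth",
    "ancestor_depth",
    "alt_support",
    "ancestor_alt",
    "quality",
    "strand",
)


def apply_ma_filters(
    candidates: list[VariantCall],
    ancestor: dict[tuple[str, int], AncestorEvidence],
    cfg: FilterConfig | None = None,
) -> tuple[list[VariantCall], "OrderedDict[str, int]"]:
    """Screen candidate calls against the ancestor strain.

    Returns the retained calls and an ordered per-filter rejection tally.
    ``retained + sum(tally) == len(candidates)`` always holds.  A site with
    no queryable ancestor evidence is rejected with its own reason, never
    silently retained.
    """
    cfg = cfg or FilterConfig()
    tally: OrderedDict[str, int] = OrderedDict((r, 0) for r in REJECTION_REASONS)
    retained: list[VariantCall] = []
    for v in candidates:
        anc = ancestor.get((v.chrom, v.pos))
        reason = None
        if anc is None:
            reason = "no_ancestor_evidence"
        elif v.depth < cfg.min_depth:
            reason = "line_depth"
        elif anc.depth < cfg.min_depth:
            reason = "ancestor_depth"
        elif v.alt_reads < cfg.min_alt_reads:
            reason = "alt_support"
        elif anc.alt_reads > cfg.max_ancestor_alt_reads:
            reason = "ancestor_alt"
        elif v.qual <= cfg.min_qual:
            reason = "quality"
        elif cfg.require_both_strands and (v.alt_plus < 1 or v.alt_minus < 1):
            reason = "strand"
        if reason is None:
            retained.append(v)
        else:
            tally[reason] += 1
    return retained, tally


# ---------------------------------------------------------------------------
# Annotated mutations
# ---------------------------------------------------------------------------


@dataclass
class Mutation:
    """A retained mutation with all downstream labels."""

    chrom: str
    pos: int
    ref: str
    alt: str
    line_id: str | None
    kind: str
    six_class: str | None = None
    context: str | None = None
    in_h3k9me3: bool = False
    in_pr: bool = False
    cds_effect: str = "noncoding"
    secondary_effects: list[str] = field(default_factory=list)
    homopolymer_flag: bool = False
    mixed_support: bool = False


def homopolymer_adjacent(
    sequences: dict[str, np.ndarray], chrom: str, pos1: int, min_run: int = 6
) -> bool:
    """Automated stand-in for visual curation: flag sites next to long
    single-base runs, where alignment artifacts concentrate.  Flagged records
    are reported, not dropped."""
    seq = sequences[chrom]
    i = pos1 - 1
    lo = max(0, i - min_run)
    hi = min(len(seq), i + min_run + 1)
    window = seq[lo:hi]
    run = best = 1
    for k in range(1, len(window)):
        run = run + 1 if window[k] == window[k - 1] else 1
        best = max(best, run)
    return best >= min_run


def annotate_mutations(
    retained: list[VariantCall],
    sequences: dict[str, np.ndarray],
    transcripts: list[Transcript] | None = None,
    h3k9me3: IntervalSet | None = None,
    pr: IntervalSet | None = None,
    table_id: int = 1,
) -> list[Mutation]:
    """Attach six-class, trinucleotide-context, region and CDS-effect labels
    to retained calls.  Indels get kind labels only; SNVs at contig edges
    keep ``context=None`` (tallied by spectrum builders)."""
    transcripts = transcripts or []
    out: list[Mutation] = []
    for v in retained:
        mut = Mutation(
            chrom=v.chrom,
            pos=v.pos,
            ref=v.ref,
            alt=v.alt,
            line_id=v.line_id,
            kind=v.kind,
            mixed_support=0 < v.alt_reads < v.depth,
        )
        if v.is_snv:
            mut.six_class = classify_six(v.ref, v.alt)
            try:
                mut.context = trinuc_context(sequences, v.chrom, v.pos, v.ref, v.alt)
            except ValueError:
                mut.context = None
            mut.cds_effect, mut.secondary_effects = annotate_cds_effect(
                v.chrom, v.pos, v.ref, v.alt, transcripts, sequences, table_id
            )
        mut.homopolymer_flag = homopolymer_adjacent(sequences, v.chrom, v.pos)
        if h3k9me3 is not None:
            mut.in_h3k9me3 = bool(h3k9me3.contains_positions(v.chrom, np.array([v.pos - 1]))[0])
        if pr is not None:
            mut.in_pr = bool(pr.contains_positions(v.chrom, np.array([v.pos - 1]))[0])
        out.append(mut)
    return out


MUTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "line_id",
    "kind",
    "six_class",
    "context",
    "in_h3k9me3",
    "in_pr",
    "cds_effect",
    "homopolymer_flag",
]


def mutations_to_frame(mutations: list[Mutation]) -> pd.DataFrame:
    """Tabulate mutations for the spectrum and rate modules."""
    rows = [{k: getattr(m, k) for k in MUTATION_COLUMNS} for m in mutations]
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    return df
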