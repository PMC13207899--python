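"""Seeded synthetic genomes with the statistical structure the analysis assumes.

The generator emulates a compact fungal genome organised the way the
downstream analysis expects: each chromosome carries a centred pericentromeric
(PR) block nested inside H3K9me3 heterochromatin domains, plus non-overlapping
protein-coding CDS models.  On top of that it injects per-stratum mutations
with configurable six-class spectra and per-bp/day rates (emulating the
outcome of a mutation-accumulation experiment, 6 treated lines x 18 days by
default), and produces pre/post-treatment epigenetic tracks: per-cytosine
bisulfite calls whose treated level is a proportional fraction K of the
untreated level, and windowed ChIP signal whose treated value follows an
asymptotic exponential decay ``a - b * exp(-c * x)`` of the untreated value.

Everything is deterministic under a fixed seed, so every downstream stage is
testable without downloads.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome import BASES, A, C, G, T, GenomeBundle, Transcript, decode_seq, encode_seq, revcomp
from .intervals import IntervalSet
from .region_rates import STRATA, RegionAnnotation
from .variant_filter import (
    SIX_CLASSES,
    AncestorEvidence,
    VariantCall,
    class_alt_map,
)

#: six-class spectrum of 5AzC-treated wild type: C:G>G:C transversions
#: dominate (56.2%), transitions are suppressed, ~20% of mutations sit at
#: A/T sites.
WT_5AZC_SPECTRUM = {
    "C:G>T:A": 0.148,
    "C:G>A:T": 0.090,
    "C:G>G:C": 0.562,
    "T:A>C:G": 0.134,
    "T:A>G:C": 0.033,
    "T:A>A:T": 0.033,
}

#: per-stratum per-bp/day rates of the treated wild type regime:
#: PR > non-PR H3K9me3 > non-H3K9me3.
DEFAULT_STRATUM_RATES = {
    "PR": 2.1e-6,
    "nonPR_H3K9me3": 1.4e-6,
    "non_H3K9me3": 6.0e-7,
}

CORRUPTION_KINDS = ("low_depth", "low_alt", "ancestral", "single_strand", "low_qual")


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class GenomeSpec:
    """Parameters of the toy genome."""

    chromosome_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 600_000), ("chr2", 400_000)]
    )
    pr_fraction: float = 0.10
    h3k9me3_domain_length_mean: int = 20_000
    h3k9me3_genome_fraction: float = 0.30
    cds_count: int = 40
    cds_length_mean: int = 900
    gc_content: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_lengths or any(n <= 0 for _, n in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        for name in ("pr_fraction", "h3k9me3_genome_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.cds_length_mean % 3 != 0:
            raise ValueError("cds_length_mean must be a multiple of 3")
        if self.pr_fraction > self.h3k9me3_genome_fraction:
            raise ValueError("pr_fraction cannot exceed h3k9me3_genome_fraction")

    @property
    def genome_bp(self) -> int:
        return sum(n for _, n in self.chromosome_lengths)


@dataclass
class MutagenesisModel:
    """Per-stratum mutagenesis regime of the emulated MA experiment."""

    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STRATUM_RATES))
    spectrum: dict[str, float] = field(default_factory=lambda: dict(WT_5AZC_SPECTRUM))
    n_lines: int = 6
    days: float = 18.0
    seed: int = 0
    depth_mean: float = 63.0

    def __post_init__(self) -> None:
        if set(self.rates) - set(STRATA):
            raise ValueError(f"rates keyed by {STRATA}")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be >= 0")
        if set(self.spectrum) - set(SIX_CLASSES):
            raise ValueError("spectrum keyed by the six substitution classes")
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum must sum to 1, got {total}")
        if self.n_lines < 1 or self.days <= 0:
            raise ValueError("need n_lines >= 1 and days > 0")


@dataclass
class EpiTrackModel:
    """Parameters of the pre/post-treatment epigenetic tracks.

    Untreated methylation levels are per-stratum fractions (pericentromeres
    are 5mC-poor relative to other heterochromatin); treatment multiplies
    every level by ``k_factor``.  Untreated ChIP signal is drawn per window
    around a domain/background mean; the treated signal follows the
    saturating decay ``a - b * exp(-c * x)`` of the untreated value ``x``.
    """

    meth_levels: dict[str, float] = field(
        default_factory=lambda: {"PR": 0.08, "nonPR_H3K9me3": 0.33, "non_H3K9me3": 0.005}
    )
    k_factor: float = 0.5
    meth_depth_mean: float = 30.0
    chip_domain_mean: float = 5.4
    chip_background_mean: float = 1.0
    chip_shape: float = 8.0
    decay: tuple[float, float, float] = (2.22, 2.5, 0.37)
    chip_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.meth_levels.items():
            if not 0 <= v <= 1:
                raise ValueError(f"methylation level for {k} must be in [0, 1]")
        if not 0 < self.k_factor <= 1:
            raise ValueError("k_factor must be in (0, 1]")
        if any(p <= 0 for p in self.decay):
            raise ValueError("decay parameters a, b, c must be positive")
        if self.meth_depth_mean < 1:
            raise ValueError("read depth must be >= 1")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = [
    c
    for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
    if c not in CodonTable.unambiguous_dna_by_id[1].stop_codons
]
_NONSTOP_CODES = np.array([encode_seq(c) for c in _NONSTOP_CODONS], dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def generate_genome(spec: GenomeSpec) -> GenomeBundle:
    """Generate the toy genome bundle described by ``spec``.

    Deterministic under a fixed seed.  Raises ``ValueError`` when the CDS
    demand cannot fit in the genome.
    """
    if spec.cds_count * spec.cds_length_mean > 0.5 * spec.genome_bp:
        raise ValueError(
            f"CDS demand ({spec.cds_count} x {spec.cds_length_mean} bp) exceeds "
            f"half the genome ({spec.genome_bp} bp); enlarge the genome or trim CDS"
        )
    rng = np.random.default_rng(spec.seed)
    sequences = {
        name: _random_sequence(rng, length, spec.gc_content)
        for name, length in spec.chromosome_lengths
    }

    # centred PR block per chromosome
    pr_triples = []
    for name, length in spec.chromosome_lengths:
        pr_len = int(round(spec.pr_fraction * length))
        if pr_len > 0:
            start = (length - pr_len) // 2
            pr_triples.append((name, start, start + pr_len))
    pr = IntervalSet.from_pairs(pr_triples)

    # H3K9me3 domains: the PR blocks plus random domains up to the target bp
    target = int(spec.h3k9me3_genome_fraction * spec.genome_bp)
    triples = list(pr_triples)
    h3k9me3 = IntervalSet.from_pairs(triples)
    names = [n for n, _ in spec.chromosome_lengths]
    lengths = np.array([n for _, n in spec.chromosome_lengths], dtype=float)
    weights = lengths / lengths.sum()
    tries = 0
    while h3k9me3.total_bp < target and tries < 100_000:
        tries += 1
        chrom = names[rng.choice(len(names), p=weights)]
        dlen = max(2000, int(rng.exponential(spec.h3k9me3_domain_length_mean)))
        clen = dict(spec.chromosome_lengths)[chrom]
        if dlen >= clen:
            dlen = clen // 2
        start = int(rng.integers(0, clen - dlen))
        triples.append((chrom, start, start + dlen))
        h3k9me3 = IntervalSet.from_pairs(triples)

    # non-overlapping CDS models with stop-free coding bodies
    transcripts: list[Transcript] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    margin = 100  # keep CDS off contig edges so every site has context
    for i in range(spec.cds_count):
        placed = False
        for _ in range(200):
            n_codons = max(30, int(rng.poisson(spec.cds_length_mean / 3)))
            clen_bp = 3 * n_codons
            chrom = names[rng.choice(len(names), p=weights)]
            chrom_len = dict(spec.chromosome_lengths)[chrom]
            if chrom_len - clen_bp - 2 * margin <= 0:
                continue
            start = int(rng.integers(margin, chrom_len - clen_bp - margin))
            end = start + clen_bp
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            codons = _NONSTOP_CODES[rng.integers(0, len(_NONSTOP_CODES), size=n_codons)]
            body = codons.reshape(-1)
            sequences[chrom][start:end] = body if strand == "+" else revcomp(body)
            occupied[chrom].append((start, end))
            transcripts.append(
                Transcript(name=f"gene{i:04d}", chrom=chrom, strand=strand, parts=[(start, end)])
            )
            placed = True
            break
        if not placed:
            raise ValueError("could not place all CDS models; genome too crowded")
    transcripts.sort(key=lambda t: (t.chrom, t.parts[0][0]))
    return GenomeBundle(sequences=sequences, pr=pr, h3k9me3=h3k9me3, transcripts=transcripts)


# ---------------------------------------------------------------------------
# Mutation injection
# ---------------------------------------------------------------------------


@dataclass
class InjectionResult:
    """Truth table plus filter-ready variant evidence."""

    truth: pd.DataFrame
    variants: dict[str, list[VariantCall]]
    ancestor: dict[tuple[str, int], AncestorEvidence]
    corruptions: pd.DataFrame

    @property
    def line_ids(self) -> list[str]:
        return sorted(self.variants)


def _site_pools(bundle: GenomeBundle) -> dict[str, dict[str, np.ndarray]]:
    """Per-stratum pools of (encoded) genomic sites split by base-pair type.

    Sites are encoded as ``chrom_index * 2**33 + pos0`` to keep a flat array.
    """
    regions = RegionAnnotation.from_bundle(bundle)
    chrom_index = {name: k for k, name in enumerate(sorted(bundle.sequences))}
    pools: dict[str, dict[str, np.ndarray]] = {}
    for stratum, ivset in regions.stratum_intervals().items():
        cg_parts, at_parts = [], []
        for chrom, s, e in ivset:
            codes = bundle.sequences[chrom][s:e]
            offs = np.arange(s, e, dtype=np.int64)
            is_gc = (codes == C) | (codes == G)
            enc = chrom_index[chrom] * (1 << 33)
            cg_parts.append(enc + offs[is_gc])
            at_parts.append(enc + offs[~is_gc])
        pools[stratum] = {
            "GC": np.concatenate(cg_parts) if cg_parts else np.empty(0, dtype=np.int64),
            "AT": np.concatenate(at_parts) if at_parts else np.empty(0, dtype=np.int64),
        }
    return pools


def _decode_site(enc: int, chrom_names: list[str]) -> tuple[str, int]:
    return chrom_names[enc >> 33], int(enc & ((1 << 33) - 1))


def inject_mutations(
    bundle: GenomeBundle,
    model: MutagenesisModel,
    corruptions: dict[str, int] | None = None,
) -> InjectionResult:
    """Inject per-stratum mutations across MA lines and emit variant evidence.

    Per line and stratum the mutation count is Poisson with mean
    ``rate x stratum bp x days``; classes follow the configured spectrum and
    sites are drawn uniformly without replacement from the stratum's
    base-matched site pool, so positions are unique within a line.  Emitted
    line records pass the de-novo filters by construction (deep coverage,
    both strands, high quality, clean ancestor), unless ``corruptions``
    requests filter-failing records (count per kind, per line), which are
    returned with truth labels for filter benchmarking.
    """
    rng = np.random.default_rng(model.seed)
    pools = _site_pools(bundle)
    chrom_names = sorted(bundle.sequences)
    regions = RegionAnnotation.from_bundle(bundle)
    stratum_bp = regions.stratum_bp()
    classes = list(SIX_CLASSES)
    weights = np.array([model.spectrum.get(c, 0.0) for c in classes])
    cg_classes = [i for i, c in enumerate(classes) if c.startswith("C:G")]
    at_classes = [i for i, c in enumerate(classes) if c.startswith("T:A")]

    truth_rows = []
    variants: dict[str, list[VariantCall]] = {}
    ancestor: dict[tuple[str, int], AncestorEvidence] = {}
    corruption_rows = []

    def make_pass_record(chrom, pos1, ref, alt, line_id):
        depth = max(10, int(rng.poisson(model.depth_mean)))
        alt_reads = depth
        alt_plus = 1 + int(rng.binomial(alt_reads - 2, 0.5))
        qual = float(max(31.0, rng.normal(60.0, 8.0)))
        return VariantCall(chrom, pos1, ref, alt, qual, depth, alt_reads,
                           alt_plus, alt_reads - alt_plus, line_id)

    def ancestor_clean(chrom, pos1):
        ancestor[(chrom, pos1)] = AncestorEvidence(
            depth=max(5, int(rng.poisson(model.depth_mean))), alt_reads=int(rng.random() < 0.05)
        )

    # positions whose ancestor evidence is deliberately contaminated
    # ("ancestral" corruptions); excluded from all other sampling because the
    # ancestor evidence is shared across lines
    blocked: set[int] = set()
    global_used: set[int] = set()

    for li in range(model.n_lines):
        line_id = f"line{li + 1:02d}"
        variants[line_id] = []
        used: set[int] = set()
        for stratum in STRATA:
            rate = model.rates.get(stratum, 0.0)
            n = int(rng.poisson(rate * stratum_bp[stratum] * model.days))
            if n == 0:
                continue
            counts = rng.multinomial(n, weights)
            for group, idxs in (("GC", cg_classes), ("AT", at_classes)):
                need = int(counts[idxs].sum())
                if need == 0:
                    continue
                pool = pools[stratum][group]
                if need > pool.size:
                    raise ValueError(
                        f"rate too high: need {need} {group} sites in {stratum}, "
                        f"pool has {pool.size}"
                    )
                chosen = rng.choice(pool, size=need, replace=False)
                if blocked:
                    taken: set[int] = set()
                    for j in range(len(chosen)):
                        enc_j = int(chosen[j])
                        while enc_j in blocked or enc_j in taken:
                            enc_j = int(rng.choice(pool))
                        chosen[j] = enc_j
                        taken.add(enc_j)
                k = 0
                for ci in idxs:
                    for enc in chosen[k : k + counts[ci]]:
                        chrom, pos0 = _decode_site(int(enc), chrom_names)
                        ref = BASES[int(bundle.sequences[chrom][pos0])]
                        alt = class_alt_map(classes[ci])[ref]
                        truth_rows.append(
                            {
                                "chrom": chrom,
                                "pos": pos0 + 1,
                                "ref": ref,
                                "alt": alt,
                                "line_id": line_id,
                                "stratum": stratum,
                                "six_class": classes[ci],
                            }
                        )
                        variants[line_id].append(make_pass_record(chrom, pos0 + 1, ref, alt, line_id))
                        ancestor_clean(chrom, pos0 + 1)
                        used.add(int(enc))
                        global_used.add(int(enc))
                    k += counts[ci]

        # optional filter-failing records with truth labels
        for kind, per_line in (corruptions or {}).items():
            if kind not in CORRUPTION_KINDS:
                raise ValueError(f"unknown corruption kind {kind!r}")
            all_pool = np.concatenate([pools[s]["GC"] for s in STRATA])
            for _ in range(per_line):
                enc = int(rng.choice(all_pool))
                while enc in used or enc in global_used or enc in blocked:
                    enc = int(rng.choice(all_pool))
                used.add(enc)
                global_used.add(enc)
                if kind == "ancestral":
                    blocked.add(enc)
                chrom, pos0 = _decode_site(enc, chrom_names)
                ref = BASES[int(bundle.sequences[chrom][pos0])]
                alt = class_alt_map("C:G>G:C")[ref]
                rec = make_pass_record(chrom, pos0 + 1, ref, alt, line_id)
                if kind == "low_depth":
                    rec.depth = 3
                    rec.alt_reads = 3
                    rec.alt_plus, rec.alt_minus = 2, 1
                elif kind == "low_alt":
                    rec.alt_reads = 2
                    rec.alt_plus, rec.alt_minus = 1, 1
                elif kind == "single_strand":
                    rec.alt_plus, rec.alt_minus = rec.alt_reads, 0
                elif kind == "low_qual":
                    rec.qual = 20.0
                variants[line_id].append(rec)
                if kind == "ancestral":
                    ancestor[(chrom, pos0 + 1)] = AncestorEvidence(
                        depth=max(5, int(rng.poisson(model.depth_mean))), alt_reads=5
                    )
                else:
                    ancestor_clean(chrom, pos0 + 1)
                corruption_rows.append(
                    {"chrom": chrom, "pos": pos0 + 1, "line_id": line_id, "kind": kind}
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "line_id", "stratum", "six_class"],
    )
    corruption_df = pd.DataFrame(corruption_rows, columns=["chrom", "pos", "line_id", "kind"])
    return InjectionResult(truth=truth, variants=variants, ancestor=ancestor,
                           corruptions=corruption_df)


# ---------------------------------------------------------------------------
# Epigenetic tracks
# ---------------------------------------------------------------------------


def emulate_methylation(
    bundle: GenomeBundle, epi: EpiTrackModel, treated: bool = False
) -> pd.DataFrame:
    """Per-cytosine bisulfite calls (Bismark-style cytosine report rows).

    Both strands are emitted: a plus-strand row per genomic C and a
    minus-strand row per genomic G.  Methylated counts are binomial draws at
    the stratum level, times ``k_factor`` when treated.
    """
    rng = np.random.default_rng([epi.seed, 11 if treated else 10])
    regions = RegionAnnotation.from_bundle(bundle)
    frames = []
    for chrom in sorted(bundle.sequences):
        arr = bundle.sequences[chrom]
        for strand, base in (("+", C), ("-", G)):
            idx = np.nonzero(arr == base)[0]
            if idx.size == 0:
                continue
            in_pr = regions.pr.contains_positions(chrom, idx)
            in_k9 = regions.h3k9me3.contains_positions(chrom, idx)
            level = np.where(
                in_pr,
                epi.meth_levels["PR"],
                np.where(in_k9, epi.meth_levels["nonPR_H3K9me3"], epi.meth_levels["non_H3K9me3"]),
            )
            if treated:
                level = level * epi.k_factor
            depth = rng.poisson(epi.meth_depth_mean - 1, size=idx.size) + 1
            meth = rng.binomial(depth, level)
            if strand == "+":
                nxt = arr[np.minimum(idx + 1, len(arr) - 1)]
                nxt2 = arr[np.minimum(idx + 2, len(arr) - 1)]
                is_cpg, is_chg = nxt == G, nxt2 == G
            else:
                nxt = arr[np.maximum(idx - 1, 0)]
                nxt2 = arr[np.maximum(idx - 2, 0)]
                is_cpg, is_chg = nxt == C, nxt2 == C  # complement strand reads C as G
            context = np.where(is_cpg, "CpG", np.where(is_chg, "CHG", "CHH"))
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": idx + 1,
                        "strand": strand,
                        "methylated": meth,
                        "unmethylated": depth - meth,
                        "context": context,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="stable", ignore_index=True)


def emulate_chip(
    bundle: GenomeBundle, epi: EpiTrackModel, treated: bool = False, window_bp: int = 200
) -> pd.DataFrame:
    """Windowed ChIP signal track (bedGraph-writable).

    The untreated draw is identical for ``treated`` False/True under the same
    seed, so treated windows are a paired transform
    ``a - b * exp(-c * x) + noise`` of their untreated values — the structure
    the decay-model fit is meant to recover.
    """
    a, b, c = epi.decay
    rng_base = np.random.default_rng([epi.seed, 20])
    rng_noise = np.random.default_rng([epi.seed, 21])
    frames = []
    for chrom in sorted(bundle.sequences):
        length = len(bundle.sequences[chrom])
        starts = np.arange(0, length, window_bp, dtype=np.int64)
        ends = np.minimum(starts + window_bp, length)
        frac = bundle.h3k9me3.overlap_bp_windows(chrom, starts, ends) / (ends - starts)
        mean = epi.chip_background_mean + (epi.chip_domain_mean - epi.chip_background_mean) * frac
        x = rng_base.gamma(epi.chip_shape, mean / epi.chip_shape)
        if treated:
            y = a - b * np.exp(-c * x)
            if epi.chip_noise_sd > 0:
                y = y + rng_noise.normal(0.0, epi.chip_noise_sd, size=y.size)
            value = np.maximum(y, 0.0)
        else:
            value = x
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": value}))
    return pd.concat(frames, ignore_index=True)
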