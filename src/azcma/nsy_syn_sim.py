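"""Deleteriousness analysis: observed and simulated nsy/syn ratios in CDS.

The observed nonsynonymous-to-synonymous count ratio of coding mutations is
compared to a random-mutagenesis null: per iteration, a fixed number of sites
is drawn uniformly without replacement from the class-eligible coding
positions (e.g. all coding C/G sites for C:G>G:C transversions), the implied
base change is applied and classified with the codon table, and the
per-iteration nsy/syn ratio is summarised as mean +/- SD over (by default)
1000 iterations.  An exhaustive site-by-site enumeration provides the exact
expectation the simulation must converge to.  Stop-gained changes are folded
into the nonsynonymous count for ratios but tallied separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BASES, COMP, GenomeBundle, Transcript
from .variant_filter import SIX_CLASSES, _aa_table, annotate_cds_effect, class_alt_map

_EFFECT_CODE = {"synonymous": 0, "nonsynonymous": 1, "stop-gained": 2}


class CDSCollection:
    """Flattened view of a genome's coding positions with precomputed effects.

    For every coding site and every alternate base the synonymous /
    nonsynonymous / stop-gained outcome is tabulated once, so simulation
    iterations reduce to array indexing.  Construction validates that every
    transcript's coding length is a multiple of 3 and warns about internal
    stop codons in the reference frame.
    """

    def __init__(
        self,
        transcripts: list[Transcript],
        sequences: dict[str, np.ndarray],
        table_id: int = 1,
    ):
        if not transcripts:
            raise ValueError("no CDS models supplied")
        self.transcripts = list(transcripts)
        self.sequences = sequences
        self.table_id = table_id
        aa_of = _aa_table(table_id)
        aa64 = np.array(
            [aa_of[a + b + c] for a in BASES for b in BASES for c in BASES]
        )

        chroms, gpos, sense, strands = [], [], [], []
        effect_parts = []
        for tr in self.transcripts:
            if tr.coding_length % 3 != 0:
                raise ValueError(f"CDS {tr.name} length not a multiple of 3")
            codes = tr.coding_codes(sequences).astype(np.int64)
            codons = codes.reshape(-1, 3)
            codon_int = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
            ref_aa = aa64[codon_int]
            if (ref_aa[:-1] == "*").any():
                warnings.warn(
                    f"internal stop codon(s) in reference frame of {tr.name}",
                    stacklevel=2,
                )
            # effect of substituting each site with each alternate base
            eff = np.full((codes.size, 4), -1, dtype=np.int8)
            for within in range(3):
                mult = 4 ** (2 - within)
                base_here = codons[:, within]
                for alt in range(4):
                    alt_int = codon_int + (alt - base_here) * mult
                    alt_aa = aa64[alt_int]
                    code = np.where(
                        alt_aa == ref_aa, 0, np.where(alt_aa == "*", 2, 1)
                    ).astype(np.int8)
                    code[alt == base_here] = -1
                    eff[within::3, alt] = code
            effect_parts.append(eff)
            chroms.append(np.full(codes.size, tr.chrom, dtype=object))
            gpos.append(tr.coding_positions())
            sense.append(codes.astype(np.uint8))
            strands.append(np.full(codes.size, tr.strand, dtype=object))

        self.chrom = np.concatenate(chroms)
        self.gpos = np.concatenate(gpos)  # genomic 0-based
        self.sense = np.concatenate(sense)  # sense-strand base codes
        self.strand = np.concatenate(strands)
        #: genome (plus-strand) base codes at each coding site
        self.genome_base = np.where(self.strand == "+", self.sense, COMP[self.sense]).astype(np.uint8)
        self.effects = np.concatenate(effect_parts)  # (n_sites, 4) effect codes

    @property
    def n_sites(self) -> int:
        return int(self.gpos.size)

    def eligible_sites(self, six_class: str) -> np.ndarray:
        """Indices of coding sites whose base pair matches the class."""
        alt_map = class_alt_map(six_class)
        wanted = [BASES.index(b) for b in alt_map]
        return np.nonzero(np.isin(self.genome_base, wanted))[0]

    def alt_codes_for(self, sites: np.ndarray, six_class: str) -> np.ndarray:
        """Sense-strand alternate base codes implied by a class at given sites."""
        alt_map = class_alt_map(six_class)
        # map on the sense strand: the class is strand-symmetric
        table = np.full(4, -1, dtype=np.int64)
        for ref_b, alt_b in alt_map.items():
            table[BASES.index(ref_b)] = BASES.index(alt_b)
        alts = table[self.sense[sites]]
        if (alts < 0).any():
            raise ValueError(f"site base incompatible with class {six_class}")
        return alts


# ---------------------------------------------------------------------------
# Observed ratio and spectrum scaling
# ---------------------------------------------------------------------------


@dataclass
class RatioResult:
    nonsynonymous: int  # includes stop-gained
    synonymous: int
    stop_gained: int

    @property
    def ratio(self) -> float:
        if self.synonymous == 0:
            return float("nan")
        return self.nonsynonymous / self.synonymous


def ratio_from_counts(nonsynonymous: int, synonymous: int, stop_gained: int = 0) -> RatioResult:
    """nsy/syn ratio from explicit counts (stop-gained already folded in)."""
    return RatioResult(nonsynonymous=nonsynonymous, synonymous=synonymous,
                       stop_gained=stop_gained)


def observed_ratio(mutations: pd.DataFrame) -> RatioResult:
    """nsy/syn ratio of coding mutations (``cds_effect`` column).

    Stop-gained changes count as nonsynonymous; noncoding rows are ignored.
    With zero synonymous mutations the ratio is NaN but counts are reported.
    """
    eff = mutations["cds_effect"]
    syn = int((eff == "synonymous").sum())
    stop = int((eff == "stop-gained").sum())
    nsy = int((eff == "nonsynonymous").sum()) + stop
    return RatioResult(nonsynonymous=nsy, synonymous=syn, stop_gained=stop)


def scale_spectrum(observed_counts: dict[str, int] | pd.Series, target_n: int) -> pd.Series:
    """Proportionally scale class counts to ``target_n`` total.

    Largest-remainder apportionment of ``target_n`` by the observed class
    fractions; deterministic (ties broken by class order) and always summing
    exactly to ``target_n``.
    """
    counts = pd.Series(observed_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("observed counts are all zero")
    if target_n < 0:
        raise ValueError("target_n must be nonnegative")
    quota = counts / total * target_n
    floors = np.floor(quota).astype(int)
    short = int(target_n - floors.sum())
    remainders = quota - floors
    order = sorted(range(len(counts)), key=lambda i: (-remainders.iloc[i], i))
    out = floors.copy()
    for i in order[:short]:
        out.iloc[i] += 1
    return out


# ---------------------------------------------------------------------------
# Enumeration oracle and Monte-Carlo simulation
# ---------------------------------------------------------------------------


def enumerate_expectation(
    cds: CDSCollection, six_class: str
) -> dict[str, float]:
    """Exact syn/nsy/stop fractions of one uniformly random eligible change.

    A deliberately independent path from the simulation: every eligible site
    is walked one by one and classified through the genomic-coordinate
    annotator, not through the precomputed effect table.
    """
    sites = cds.eligible_sites(six_class)
    if sites.size == 0:
        raise ValueError(f"no eligible coding site for class {six_class}")
    alt_map = class_alt_map(six_class)
    tally = {"synonymous": 0, "nonsynonymous": 0, "stop-gained": 0}
    for i in sites:
        chrom = str(cds.chrom[i])
        pos1 = int(cds.gpos[i]) + 1
        ref = BASES[int(cds.genome_base[i])]
        alt = alt_map[ref]
        effect, _ = annotate_cds_effect(
            chrom, pos1, ref, alt, cds.transcripts, cds.sequences, cds.table_id
        )
        tally[effect] += 1
    n = sites.size
    return {k: v / n for k, v in tally.items()}


@dataclass
class MutModel:
    """Random-mutagenesis model: per-iteration class counts and iteration count."""

    class_counts: dict[str, int]
    iterations: int = 1000
    seed: int = 0
    replace: bool = False

    def __post_init__(self) -> None:
        bad = set(self.class_counts) - set(SIX_CLASSES)
        if bad:
            raise ValueError(f"unknown classes {sorted(bad)}")
        if self.n_sites < 1:
            raise ValueError("need at least one site per iteration")
        if self.iterations < 1:
            raise ValueError("need at least one iteration")

    @property
    def n_sites(self) -> int:
        return int(sum(self.class_counts.values()))

    @classmethod
    def single_class(cls, six_class: str, n_sites: int, **kw) -> "MutModel":
        return cls(class_counts={six_class: int(n_sites)}, **kw)

    @classmethod
    def from_spectrum(cls, observed_counts, target_n: int, **kw) -> "MutModel":
        scaled = scale_spectrum(observed_counts, target_n)
        return cls(class_counts={k: int(v) for k, v in scaled.items() if v > 0}, **kw)


@dataclass
class SimOutcome:
    """Per-iteration tallies and their summary."""

    synonymous: np.ndarray
    nonsynonymous: np.ndarray  # excludes stop-gained
    stop_gained: np.ndarray
    n_sites: int

    @property
    def ratios(self) -> np.ndarray:
        nsy = self.nonsynonymous + self.stop_gained
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.synonymous > 0, nsy / self.synonymous, np.nan)

    @property
    def ratio_mean(self) -> float:
        return float(np.nanmean(self.ratios))

    @property
    def ratio_sd(self) -> float:
        return float(np.nanstd(self.ratios, ddof=1))

    @property
    def mean_nonsyn_fraction(self) -> float:
        """Mean fraction of per-iteration changes that are nonsynonymous
        (stop-gained included)."""
        return float(np.mean((self.nonsynonymous + self.stop_gained) / self.n_sites))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.synonymous) + 1),
                "synonymous": self.synonymous,
                "nonsynonymous": self.nonsynonymous,
                "stop_gained": self.stop_gained,
                "ratio": self.ratios,
            }
        )


def simulate(cds: CDSCollection, model: MutModel) -> SimOutcome:
    """Monte-Carlo random mutagenesis over the coding sequence.

    Per iteration, for each base-pair group (C/G-site classes, A/T-site
    classes) the required number of distinct sites is drawn uniformly without
    replacement from the eligible coding positions and partitioned among the
    classes, so all ``n_sites`` sites of an iteration are distinct.  Effects
    come from the precomputed codon-table lookup.  Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(model.seed)
    groups: dict[str, list[str]] = {}
    for cls_name, cnt in model.class_counts.items():
        if cnt < 0:
            raise ValueError("negative class count")
        if cnt == 0:
            continue
        key = "GC" if cls_name.startswith("C:G") else "AT"
        groups.setdefault(key, []).append(cls_name)

    pools: dict[str, np.ndarray] = {}
    alt_tables: dict[str, np.ndarray] = {}
    for key, classes in groups.items():
        pool = cds.eligible_sites(classes[0])  # same pool for all classes in group
        need = sum(model.class_counts[c] for c in classes)
        if pool.size == 0 or (not model.replace and need > pool.size):
            raise ValueError(
                f"{need} sites requested from {pool.size} eligible {key} coding sites"
            )
        pools[key] = pool
        for c in classes:
            table = np.full(4, -1, dtype=np.int64)
            for ref_b, alt_b in class_alt_map(c).items():
                table[BASES.index(ref_b)] = BASES.index(alt_b)
            alt_tables[c] = table

    syn = np.zeros(model.iterations, dtype=np.int64)
    nsy = np.zeros(model.iterations, dtype=np.int64)
    stop = np.zeros(model.iterations, dtype=np.int64)
    for it in range(model.iterations):
        for key, classes in groups.items():
            need = sum(model.class_counts[c] for c in classes)
            chosen = rng.choice(pools[key], size=need, replace=model.replace)
            k = 0
            for c in classes:
                sites = chosen[k : k + model.class_counts[c]]
                k += model.class_counts[c]
                alts = alt_tables[c][cds.sense[sites]]
                eff = cds.effects[sites, alts]
                syn[it] += int((eff == 0).sum())
                nsy[it] += int((eff == 1).sum())
                stop[it] += int((eff == 2).sum())
    return SimOutcome(synonymous=syn, nonsynonymous=nsy, stop_gained=stop,
                      n_sites=model.n_sites)


def cds_collection_from_bundle(bundle: GenomeBundle, table_id: int = 1) -> CDSCollection:
    """Convenience constructor from a synthetic genome bundle."""
    return CDSCollection(bundle.transcripts, bundle.sequences, table_id=table_id)
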