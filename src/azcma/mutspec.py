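"""Mutation spectra and signature comparison.

Builds the six-class substitution spectrum and the 96-context trinucleotide
(SBS) spectrum of a mutation set, normalises context counts by genomic
trinucleotide opportunity (both strands collapsed onto pyrimidine-centred
contexts) and per line-day exposure, and ranks reference signatures from a
COSMIC-style catalog by cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_filter import BASES, CONTEXTS_96, SIX_CLASSES, SUBSTITUTIONS
from .genome import A, C, G, T, COMP

#: the 32 pyrimidine-centred trinucleotides underlying the 96 labels
TRINUCS_32 = tuple(f"{l}{p}{r}" for p in "CT" for l in BASES for r in BASES)


def context_of_label(label: str) -> str:
    """Trinucleotide (e.g. ``ACA``) underlying a 96-context label ``A[C>A]A``."""
    return label[0] + label[2] + label[6]


@dataclass
class Spectrum6:
    """Six-class fractions of an SNV set; fractions are NaN when empty."""

    fractions: pd.Series
    total: int


def build_spectrum6(mutations: pd.DataFrame) -> Spectrum6:
    """Six-class spectrum from a mutation table with a ``six_class`` column.

    Rows without a six-class label (indels) are ignored.  An empty input
    yields total 0 with undefined (NaN) fractions.
    """
    labels = mutations["six_class"].dropna()
    counts = labels.value_counts().reindex(SIX_CLASSES, fill_value=0)
    total = int(counts.sum())
    fractions = counts / total if total > 0 else counts.astype(float) * np.nan
    return Spectrum6(fractions=fractions, total=total)


def trinuc_opportunity(sequences: dict[str, np.ndarray]) -> pd.Series:
    """Genomic occurrences of each of the 32 pyrimidine-centred trinucleotides.

    Every internal genome position contributes exactly once: positions whose
    base is C or T are read on the plus strand, A/G positions are read as the
    reverse complement of their plus-strand triplet.  The per-centre totals
    therefore sum to the genome's C+T site count plus its A+G site count
    read from the opposite strand — i.e. each position counted once.
    """
    counts = np.zeros(32, dtype=np.int64)
    index = {t: i for i, t in enumerate(TRINUCS_32)}
    for arr in sequences.values():
        if arr.size < 3:
            continue
        left, centre, right = arr[:-2], arr[1:-1], arr[2:]
        is_pyr = (centre == C) | (centre == T)
        # plus-strand pyrimidine-centred triplets
        code_p = left[is_pyr] * 16 + centre[is_pyr] * 4 + right[is_pyr]
        # purine-centred: reverse complement (right' left' swap with complement)
        lc, cc, rc = COMP[right[~is_pyr]], COMP[centre[~is_pyr]], COMP[left[~is_pyr]]
        code_m = lc.astype(np.int64) * 16 + cc * 4 + rc
        for code in (code_p.astype(np.int64), code_m):
            binc = np.bincount(code, minlength=64)
            for t, i in index.items():
                tcode = BASES.index(t[0]) * 16 + BASES.index(t[1]) * 4 + BASES.index(t[2])
                counts[i] += binc[tcode]
    return pd.Series(counts, index=list(TRINUCS_32), name="opportunity")


@dataclass
class TrinucSpectrum:
    """96-context counts with opportunities, normalised rates and fractions."""

    counts: pd.Series  # indexed by CONTEXTS_96
    opportunities: pd.Series  # per 96 label (shared across the 3 alts of a context)
    line_days: float
    excluded: int  # SNVs without a context label (contig edges)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def rates(self) -> pd.Series:
        """Per-context per-site per-day rates: count / (opportunity x line-days)."""
        return self.counts / (self.opportunities * self.line_days)

    @property
    def fractions(self) -> pd.Series:
        total = self.total
        return self.counts / total if total else self.counts.astype(float) * np.nan


def build_trinuc(
    mutations: pd.DataFrame,
    sequences: dict[str, np.ndarray],
    line_days: float,
) -> TrinucSpectrum:
    """96-context spectrum of a mutation table with a ``context`` column."""
    if line_days <= 0:
        raise ValueError("line_days must be positive")
    snvs = mutations[mutations["six_class"].notna()]
    labelled = snvs["context"].dropna()
    counts = labelled.value_counts().reindex(CONTEXTS_96, fill_value=0)
    opp32 = trinuc_opportunity(sequences)
    opportunities = pd.Series(
        [opp32[context_of_label(lbl)] for lbl in CONTEXTS_96], index=list(CONTEXTS_96)
    )
    nonzero = counts[(counts > 0) & (opportunities == 0)]
    if len(nonzero):
        raise ValueError(
            f"contexts observed but absent from the genome: {list(nonzero.index)}"
        )
    return TrinucSpectrum(
        counts=counts,
        opportunities=opportunities,
        line_days=float(line_days),
        excluded=int(len(snvs) - len(labelled)),
    )


def context_group_ratio(
    spectrum: TrinucSpectrum,
    substitution: str = "C>G",
    numerator_rights: tuple[str, ...] = ("G", "T"),
    denominator_rights: tuple[str, ...] = ("A", "C"),
) -> float:
    """Enrichment of a substitution in NCx context groups.

    Default: mean opportunity-normalised C>G rate over NCG+NCT contexts
    divided by the mean over NCA+NCC contexts (unweighted means of member
    contexts).
    """
    if substitution not in SUBSTITUTIONS:
        raise ValueError(f"unknown substitution {substitution!r}")
    rates = spectrum.rates
    num = [f"{l}[{substitution}]{r}" for l in BASES for r in numerator_rights]
    den = [f"{l}[{substitution}]{r}" for l in BASES for r in denominator_rights]
    denom = rates[den].mean()
    if denom == 0:
        return float("nan")
    return float(rates[num].mean() / denom)


# ---------------------------------------------------------------------------
# Signature comparison
# ---------------------------------------------------------------------------


def cosine_similarity(u, v) -> float:
    """Cosine similarity of two nonnegative 96-vectors, in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("vectors must be nonnegative")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector has no direction")
    return float(np.dot(u, v) / (nu * nv))


def similarity_band(value: float) -> str:
    """Conventional similarity bands: high > 0.8, moderate 0.7-0.8, low < 0.7."""
    if value > 0.8:
        return "high"
    if value >= 0.7:
        return "moderate"
    return "low"


def match_signatures(fractions: pd.Series, catalog: pd.DataFrame) -> pd.DataFrame:
    """Rank catalog signatures by cosine similarity to a query spectrum.

    ``fractions`` and the catalog rows must be indexed by the same 96 context
    labels (COSMIC layout: one row per label, one column per signature).
    Returns a frame with columns ``signature, similarity, band`` sorted by
    descending similarity, ties broken by name.
    """
    missing = [lbl for lbl in CONTEXTS_96 if lbl not in catalog.index]
    missing += [lbl for lbl in CONTEXTS_96 if lbl not in fractions.index]
    if missing:
        raise ValueError(f"missing context labels: {sorted(set(missing))}")
    q = fractions.reindex(CONTEXTS_96).to_numpy()
    rows = []
    for name in catalog.columns:
        sim = cosine_similarity(q, catalog[name].reindex(CONTEXTS_96).to_numpy())
        rows.append({"signature": name, "similarity": sim, "band": similarity_band(sim)})
    out = pd.DataFrame(rows).sort_values(
        ["similarity", "signature"], ascending=[False, True], ignore_index=True
    )
    return out
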