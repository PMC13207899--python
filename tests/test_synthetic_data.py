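import numpy as np
import pandas as pd
import pytest
from scipy import stats

import azcma
from azcma import synthetic_data as sd
from azcma.genome import BASES, decode_seq
from azcma.variant_filter import SIX_CLASSES, class_alt_map


def test_generation_deterministic_under_fixed_seed(small_spec, small_bundle):
    again = azcma.generate_genome(small_spec)
    for chrom in small_bundle.sequences:
        assert np.array_equal(small_bundle.sequences[chrom], again.sequences[chrom])
    assert small_bundle.pr == again.pr
    assert small_bundle.h3k9me3 == again.h3k9me3
    assert [t.parts for t in small_bundle.transcripts] == [t.parts for t in again.transcripts]


def test_structural_invariants(small_bundle):
    # PR nested in heterochromatin domains
    assert small_bundle.pr.subtract(small_bundle.h3k9me3).total_bp == 0
    # CDS models do not overlap each other
    by_chrom = {}
    for t in small_bundle.transcripts:
        for s, e in t.parts:
            for s2, e2 in by_chrom.get(t.chrom, []):
                assert e <= s2 or s >= e2
            by_chrom.setdefault(t.chrom, []).append((s, e))
        assert t.coding_length % 3 == 0


def test_pr_fraction_zero_gives_empty_pr():
    spec = azcma.GenomeSpec(
        chromosome_lengths=[("chr1", 50_000)], pr_fraction=0.0,
        h3k9me3_genome_fraction=0.2, cds_count=2, seed=1,
    )
    bundle = azcma.generate_genome(spec)
    assert bundle.pr.total_bp == 0


def test_gc_content_recovered():
    spec = azcma.GenomeSpec(
        chromosome_lengths=[("chr1", 1_000_000)], cds_count=0, gc_content=0.5, seed=3,
    )
    bundle = azcma.generate_genome(spec)
    from azcma.genome import gc_fraction

    assert abs(gc_fraction(bundle.sequences["chr1"]) - 0.5) < 0.01


def test_cds_demand_sizing_error():
    with pytest.raises(ValueError, match="CDS demand"):
        azcma.generate_genome(
            azcma.GenomeSpec(chromosome_lengths=[("chr1", 10_000)],
                             cds_count=50, cds_length_mean=900)
        )


# ---------------------------------------------------------------------------
# mutation injection
# ---------------------------------------------------------------------------


def test_zero_rates_give_empty_truth(small_bundle):
    model = azcma.MutagenesisModel(
        rates={s: 0.0 for s in azcma.STRATA}, seed=5)
    res = azcma.inject_mutations(small_bundle, model)
    assert res.truth.empty
    assert all(len(v) == 0 for v in res.variants.values())


def test_truth_consistency(small_bundle, small_injection):
    _, res = small_injection
    truth = res.truth
    # ref matches the genome, alt differs
    for row in truth.itertuples():
        assert small_bundle.base_at(row.chrom, row.pos) == row.ref
        assert row.alt != row.ref
    # positions unique per line
    assert not truth.duplicated(["line_id", "chrom", "pos"]).any()
    # every entry sits in exactly one stratum and labels agree with geometry
    df = azcma.assign_strata(truth, azcma.RegionAnnotation.from_bundle(small_bundle))
    assert (df["stratum"] == truth["stratum"]).all()


def test_injected_count_within_poisson_bound(small_bundle):
    rate, days, n_lines = 1.0e-5, 18.0, 4
    bp = azcma.RegionAnnotation.from_bundle(small_bundle).stratum_bp()["non_H3K9me3"]
    mean = rate * bp * n_lines * days
    for seed in range(3):
        model = azcma.MutagenesisModel(
            rates={"PR": 0.0, "nonPR_H3K9me3": 0.0, "non_H3K9me3": rate},
            n_lines=n_lines, days=days, seed=seed,
        )
        res = azcma.inject_mutations(small_bundle, model)
        assert abs(len(res.truth) - mean) <= 3 * np.sqrt(mean)
        assert set(res.truth["stratum"]) == {"non_H3K9me3"}


def test_degenerate_spectrum_forces_transversion_partner(small_bundle):
    model = azcma.MutagenesisModel(
        rates={"PR": 1e-5, "nonPR_H3K9me3": 1e-5, "non_H3K9me3": 1e-5},
        spectrum={"C:G>G:C": 1.0}, seed=2,
    )
    res = azcma.inject_mutations(small_bundle, model)
    assert len(res.truth) > 50
    partner = class_alt_map("C:G>G:C")
    for row in res.truth.itertuples():
        assert row.alt == partner[row.ref]


def test_six_class_composition_matches_spectrum_chisq(small_bundle):
    """Injected class counts converge on the configured spectrum
    (chi-square goodness of fit not rejected at alpha=0.01)."""
    spectrum = sd.WT_5AZC_SPECTRUM
    expected_p = np.array([spectrum[c] for c in SIX_CLASSES])
    rejections = 0
    for seed in range(20):
        model = azcma.MutagenesisModel(
            rates={"PR": 1.5e-3, "nonPR_H3K9me3": 1.5e-3, "non_H3K9me3": 1.5e-3},
            n_lines=2, days=18.0, seed=seed,
        )
        res = azcma.inject_mutations(small_bundle, model)
        assert len(res.truth) >= 10_000
        counts = res.truth["six_class"].value_counts().reindex(SIX_CLASSES, fill_value=0)
        p = stats.chisquare(counts, expected_p * counts.sum()).pvalue
        rejections += p < 0.01
    assert rejections <= 2  # alpha=0.01, 20 trials: >2 rejections is off-model


def test_rate_too_high_raises():
    spec = azcma.GenomeSpec(chromosome_lengths=[("chr1", 2_000)], cds_count=0,
                            pr_fraction=0, h3k9me3_genome_fraction=0, seed=0)
    bundle = azcma.generate_genome(spec)
    model = azcma.MutagenesisModel(
        rates={"PR": 0, "nonPR_H3K9me3": 0, "non_H3K9me3": 0.5}, n_lines=1, seed=0)
    with pytest.raises(ValueError, match="rate too high"):
        azcma.inject_mutations(bundle, model)


def test_corruption_mode_labels(small_bundle):
    model = azcma.MutagenesisModel(
        rates={"PR": 5e-6, "nonPR_H3K9me3": 5e-6, "non_H3K9me3": 5e-6}, seed=9)
    res = azcma.inject_mutations(
        small_bundle, model,
        corruptions={k: 2 for k in sd.CORRUPTION_KINDS},
    )
    assert len(res.corruptions) == 2 * len(sd.CORRUPTION_KINDS) * model.n_lines
    assert set(res.corruptions["kind"]) == set(sd.CORRUPTION_KINDS)


# ---------------------------------------------------------------------------
# epigenetic tracks
# ---------------------------------------------------------------------------


def test_methylation_zero_level_all_unmethylated(small_bundle):
    epi = sd.EpiTrackModel(
        meth_levels={"PR": 0.0, "nonPR_H3K9me3": 0.0, "non_H3K9me3": 0.0}, seed=1)
    calls = sd.emulate_methylation(small_bundle, epi)
    assert (calls["methylated"] == 0).all()
    assert (calls["unmethylated"] >= 1).all()


def test_methylation_proportional_reduction(small_bundle):
    """Treated level is K x untreated: 0.306 with K=0.5 gives ~0.153."""
    epi = sd.EpiTrackModel(
        meth_levels={s: 0.306 for s in azcma.STRATA}, k_factor=0.5, seed=4)
    treated = sd.emulate_methylation(small_bundle, epi, treated=True)
    w = azcma.window_methylation(treated)
    mean = azcma.epi_signal.mean_level(w)
    assert abs(mean - 0.153) < 0.005


def test_methylation_k_one_is_identity(small_bundle):
    epi = sd.EpiTrackModel(k_factor=1.0, seed=6)
    un = azcma.epi_signal.mean_level(
        azcma.window_methylation(sd.emulate_methylation(small_bundle, epi, False)))
    tr = azcma.epi_signal.mean_level(
        azcma.window_methylation(sd.emulate_methylation(small_bundle, epi, True)))
    assert abs(un - tr) < 0.005


def test_methylation_contexts_match_sequence(small_bundle):
    epi = sd.EpiTrackModel(seed=2)
    calls = sd.emulate_methylation(small_bundle, epi).head(2000)
    seq = small_bundle.sequences
    for row in calls.itertuples():
        arr = seq[row.chrom]
        i = row.pos - 1
        base = BASES[int(arr[i])]
        if row.strand == "+":
            assert base == "C"
            nxt = BASES[int(arr[i + 1])] if i + 1 < len(arr) else None
            if nxt == "G":
                assert row.context == "CpG"
        else:
            assert base == "G"


def test_chip_treated_follows_decay_of_untreated(small_bundle):
    epi = sd.EpiTrackModel(chip_noise_sd=0.0, seed=8)
    a, b, c = epi.decay
    un = sd.emulate_chip(small_bundle, epi, treated=False, window_bp=1000)
    tr = sd.emulate_chip(small_bundle, epi, treated=True, window_bp=1000)
    x, y = un["value"].to_numpy(), tr["value"].to_numpy()
    assert np.allclose(y, np.maximum(a - b * np.exp(-c * x), 0.0))
    # asymptote: strong decay constant pushes every treated window to ~a
    epi_fast = sd.EpiTrackModel(chip_noise_sd=0.0, decay=(2.22, 2.5, 50.0), seed=8)
    tr_fast = sd.emulate_chip(small_bundle, epi_fast, treated=True, window_bp=1000)
    assert np.allclose(tr_fast["value"], 2.22, atol=1e-6)


def test_chip_track_deterministic(small_bundle):
    epi = sd.EpiTrackModel(seed=13)
    t1 = sd.emulate_chip(small_bundle, epi, treated=True)
    t2 = sd.emulate_chip(small_bundle, epi, treated=True)
    pd.testing.assert_frame_equal(t1, t2)


def test_decay_curve_printed_point_evaluation():
    # direct evaluation of the treated response at an untreated level of 5.4
    a, b, c = 2.22, 2.5, 0.37
    value = a - b * np.exp(-c * 5.4)
    assert abs(value - 1.881) < 0.001  # frozen from direct evaluation
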