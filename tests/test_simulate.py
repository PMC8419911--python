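"""Synthetic-data generator: enrichment model, monomers, concatemers,
error model."""

import edlib
import numpy as np
import pytest

from concatcall import (
    SimulationConfig, apply_error_model, assemble_concatemers,
    enriched_fraction, revcomp, simulate_monomers, simulate_run,
)
from concatcall.simulate import sample_monomer_counts
from concatcall.synthdata import pick_snv_locus, random_panel


def brute_force_invert_enrichment(vrf, fold, grid=2_000_000):
    """Independent oracle: grid-search the VAF whose enriched fraction is
    closest to the observed VRF."""
    vafs = np.linspace(0.0, 1.0, grid)
    odds = fold * vafs / np.clip(1.0 - vafs, 1e-300, None)
    fracs = odds / (1.0 + odds)
    return vafs[np.argmin(np.abs(fracs - vrf))]


class TestEnrichedFraction:
    def test_identity_at_unit_fold(self):
        assert enriched_fraction(0.3, 1.0) == pytest.approx(0.3)

    @pytest.mark.parametrize("fold", [0.5, 1.0, 199.0, 1e6])
    def test_boundary_conservation(self, fold):
        assert enriched_fraction(0.0, fold) == 0.0
        assert enriched_fraction(1.0, fold) == 1.0

    def test_half_fraction_at_odds_balancing_fold(self):
        # E=199 exactly cancels the 1:199 odds of a 0.5% VAF sample.
        assert enriched_fraction(0.005, 199.0) == pytest.approx(0.5, abs=1e-12)
        # Cross-check by brute-force inversion of the forward map.
        assert brute_force_invert_enrichment(0.5, 199.0) == pytest.approx(
            0.005, abs=1e-5)

    def test_strictly_increasing_in_vaf_and_fold(self, rng):
        for _ in range(50):
            v = float(rng.uniform(0.01, 0.99))
            e = float(10 ** rng.uniform(-1, 3))
            dv, de = 1e-6, 1e-3
            assert enriched_fraction(v + dv, e) > enriched_fraction(v, e)
            assert enriched_fraction(v, e + de) > enriched_fraction(v, e)

    def test_vaf_outside_range_rejected(self):
        with pytest.raises(ValueError):
            enriched_fraction(1.2, 10.0)


class TestSimulateMonomers:
    def test_vaf_one_gives_all_variant(self, small_panel, rng):
        locus = pick_snv_locus(small_panel, "AMP00")
        cfg = SimulationConfig(true_vaf={locus: 1.0}, enrichment_fold=5.0)
        monomers, truth = simulate_monomers(small_panel, cfg, 100, rng)
        for mid, m in truth.monomers.items():
            if m.amplicon == "AMP00":
                assert m.variants == (locus,)

    def test_variant_fraction_matches_enrichment_model(self, small_panel, rng):
        """VAF 0.5% at E=199 -> expected fraction 1/2; the realized count
        over 10,000 monomers stays inside a 5-sigma binomial band."""
        locus = pick_snv_locus(small_panel, "AMP00")
        cfg = SimulationConfig(true_vaf={locus: 0.005}, enrichment_fold=199.0)
        # Restrict to one amplicon for a clean binomial count.
        sub = random_panel(n_amplicons=1, seed=1)
        locus1 = pick_snv_locus(sub, "AMP00")
        cfg = SimulationConfig(true_vaf={locus1: 0.005}, enrichment_fold=199.0)
        monomers, truth = simulate_monomers(sub, cfg, 10_000, rng)
        n_var = sum(bool(m.variants) for m in truth.monomers.values())
        sigma = np.sqrt(10_000 * 0.25)
        assert abs(n_var - 5_000) < 5 * sigma
        assert truth.expected_fraction[locus1] == pytest.approx(0.5)

    def test_minus_strand_is_reverse_complement(self, small_panel, rng):
        cfg = SimulationConfig()
        monomers, truth = simulate_monomers(small_panel, cfg, 200, rng)
        seqs = {a.name: a.sequence for a in small_panel.amplicons}
        seen_minus = 0
        for read in monomers:
            m = truth.monomers[read.id]
            if m.strand == "-":
                assert read.sequence == revcomp(seqs[m.amplicon])
                seen_minus += 1
            else:
                assert read.sequence == seqs[m.amplicon]
        assert seen_minus > 50  # about half

    def test_primer_region_variant_rejected(self, small_panel, rng):
        amp = small_panel.get("AMP00")
        pos = 5  # inside the forward primer
        ref = amp.sequence[pos]
        cfg = SimulationConfig(true_vaf={("AMP00", pos, f"{ref}>A" if ref != "A"
                                          else "A>G"): 0.5})
        with pytest.raises(ValueError, match="primer"):
            simulate_monomers(small_panel, cfg, 10, rng)


class TestAssembleConcatemers:
    def test_fixed_count_gives_expected_junctions(self, small_panel, rng):
        cfg = SimulationConfig(monomer_distribution="fixed", monomer_mean=3)
        monomers, truth = simulate_monomers(small_panel, cfg, 30, rng)
        concats, truth = assemble_concatemers(
            monomers, truth, small_panel.junction_adapter, cfg, rng)
        assert len(concats) == 10
        for read in concats:
            # leading adapter + 2 internal junctions = 3 occurrences
            assert read.sequence.count(small_panel.junction_adapter) == 3
            assert len(truth.reads[read.id]) == 3

    def test_truncated_geometric_mean_in_observed_range(self, small_panel):
        """Mean monomers per concatemer lands in the 12-15 band measured
        for real ligation products when targeting 13.5."""
        cfg = SimulationConfig(monomer_mean=13.5)
        counts = sample_monomer_counts(cfg, 2_000, np.random.default_rng(3))
        assert 12.0 <= counts.mean() <= 15.0
        assert counts.min() >= 1 and counts.max() <= 40

    def test_single_amplicon_layout_exact(self, rng):
        panel = random_panel(n_amplicons=1, seed=4)
        cfg = SimulationConfig(monomer_distribution="fixed", monomer_mean=3)
        monomers, truth = simulate_monomers(panel, cfg, 3, rng)
        concats, truth = assemble_concatemers(
            monomers, truth, panel.junction_adapter, cfg, rng)
        read = concats[0]
        j = panel.junction_adapter
        mids = truth.reads[read.id]
        by_id = {m.id: m for m in monomers}
        expected = "".join(j + by_id[mid].sequence for mid in mids)
        assert read.sequence == expected

    def test_concatemer_length_tracks_layout(self, small_panel, rng):
        cfg = SimulationConfig(monomer_mean=10)
        monomers, truth = simulate_monomers(small_panel, cfg, 500, rng)
        concats, truth = assemble_concatemers(
            monomers, truth, small_panel.junction_adapter, cfg, rng)
        adapter = len(small_panel.junction_adapter)
        amp_len = {a.name: len(a) for a in small_panel.amplicons}
        for read in concats:
            expected = sum(adapter + amp_len[truth.monomers[m].amplicon]
                           for m in truth.reads[read.id])
            assert len(read) == expected

    def test_empty_pool_rejected(self, small_panel, rng):
        from concatcall.reads import ReadSet
        from concatcall.simulate import GroundTruth
        with pytest.raises(ValueError, match="empty"):
            assemble_concatemers(ReadSet(), GroundTruth(),
                                 small_panel.junction_adapter,
                                 SimulationConfig(), rng)


class TestErrorModel:
    def test_zero_rates_identity(self, small_panel, rng):
        cfg = SimulationConfig(error_rates=(0.0, 0.0, 0.0))
        monomers, _ = simulate_monomers(small_panel, cfg, 20, rng)
        out = apply_error_model(monomers, cfg, rng)
        for a, b in zip(monomers, out):
            assert a.sequence == b.sequence
            assert np.array_equal(a.qualities, b.qualities)

    def test_realized_error_rate_near_configured(self, small_panel, rng):
        """Edit distance to the clean read over ~1e5 bases matches the 7%
        configured total rate within half a percent."""
        cfg = SimulationConfig(error_rates=(0.04, 0.015, 0.015),
                               homopolymer_del_multiplier=1.0)
        monomers, _ = simulate_monomers(small_panel, cfg, 400, rng)
        noisy = apply_error_model(monomers, cfg, rng)
        edits = bases = 0
        for clean, corrupt in zip(monomers, noisy):
            edits += edlib.align(corrupt.sequence, clean.sequence,
                                 mode="NW", task="distance")["editDistance"]
            bases += len(clean)
        assert bases > 90_000
        assert edits / bases == pytest.approx(0.07, abs=0.005)

    def test_emitted_quality_matches_total_rate(self, small_panel, rng):
        cfg = SimulationConfig(error_rates=(0.05, 0.025, 0.025))  # 10% -> Q10
        monomers, _ = simulate_monomers(small_panel, cfg, 5, rng)
        out = apply_error_model(monomers, cfg, rng)
        assert set(np.concatenate([r.qualities for r in out])) == {10}

    def test_homopolymer_deletions_inflated(self, rng):
        from concatcall.reads import Read, ReadSet
        seq = "ACGT" * 2500 + "A" * 10_000
        reads = ReadSet([Read("r", seq, np.full(len(seq), 40))])
        cfg = SimulationConfig(error_rates=(0.0, 0.0, 0.02),
                               homopolymer_del_multiplier=3.0)
        out = apply_error_model(reads, cfg, np.random.default_rng(0))
        # Deletions only: compare retained length per half.
        n = len(out[0].sequence)
        lost = len(seq) - n
        # Expected: 10000*0.02 (mixed) + 10000*0.06 (homopolymer) = 800
        assert 600 < lost < 1000

    def test_fixed_seed_deterministic(self, small_panel):
        cfg = SimulationConfig(true_vaf={}, n_reads=30, seed=9)
        r1, t1 = simulate_run(small_panel, cfg)
        r2, t2 = simulate_run(small_panel, cfg)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert t1.reads == t2.reads

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(error_rates=(0.5, 0.3, 0.3))
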