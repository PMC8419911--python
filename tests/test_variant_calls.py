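"""VRF profiles, ΔVRF z-scores, confidence scoring, and the dual gate."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from concatcall import (
    GateConfig, LlrScoreProvider, SimulationConfig, VcfScoreProvider,
    align_readset, apply_error_model, build_pileup, call_variants,
    confidence_score, delta_vrf, simulate_monomers, vrf_profile,
)
from concatcall.align import EVENT_ROWS, PileupMatrix
from concatcall.calls import VrfProfile
from concatcall.synthdata import pick_snv_locus, random_panel


@pytest.fixture(scope="module")
def panel():
    return random_panel(n_amplicons=1, seed=8)


class TestVrfProfile:

    def test_top_variant_and_vrf(self, panel):
        amp = panel.get("AMP00")
        pos = 60
        ref = amp.sequence[pos]
        alt = "G" if ref != "G" else "A"
        pileup = PileupMatrix.zeros(panel)
        c = pileup.counts["AMP00"]
        for p, base in enumerate(amp.sequence):
            c[EVENT_ROWS[base], p] = 100
        c[EVENT_ROWS[ref], pos] = 90
        c[EVENT_ROWS[alt], pos] = 10
        prof = vrf_profile(pileup, panel)
        assert prof.top_variant["AMP00"][pos] == f"{ref}>{alt}"
        assert prof.vrf["AMP00"][pos] == pytest.approx(0.10)
        assert prof.depth["AMP00"][pos] == 100

    def test_all_reference_vrf_zero(self, panel):
        amp = panel.get("AMP00")
        pileup = PileupMatrix.zeros(panel)
        c = pileup.counts["AMP00"]
        for p, base in enumerate(amp.sequence):
            c[EVENT_ROWS[base], p] = 50
        prof = vrf_profile(pileup, panel)
        assert (prof.vrf["AMP00"] == 0).all()

    def test_tie_broken_by_event_order(self, panel):
        """Equal G and T counts at a non-G/T reference position pick G
        (substitutions rank alphabetically before ins/del)."""
        amp = panel.get("AMP00")
        pos = next(p for p, b in enumerate(amp.sequence) if b == "A")
        pileup = PileupMatrix.zeros(panel)
        c = pileup.counts["AMP00"]
        for p, base in enumerate(amp.sequence):
            c[EVENT_ROWS[base], p] = 80
        c[EVENT_ROWS["G"], pos] = 10
        c[EVENT_ROWS["T"], pos] = 10
        prof = vrf_profile(pileup, panel)
        assert prof.top_variant["AMP00"][pos] == "A>G"

    def test_zero_depth_flagged_not_dropped(self, panel):
        pileup = PileupMatrix.zeros(panel)
        prof = vrf_profile(pileup, panel)
        assert math.isnan(prof.vrf["AMP00"][0])
        assert prof.low_coverage["AMP00"].all()

    def test_primer_positions_masked(self, panel):
        pileup = PileupMatrix.zeros(panel)
        prof = vrf_profile(pileup, panel)
        region = prof.region["AMP00"]
        amp = panel.get("AMP00")
        assert (region[:amp.forward_primer_span[1]] == "primer").all()
        s, e = amp.enrichment_region
        assert (region[s:e] == "enrichment").all()


def _flat_profile(L, vrf_values, normal=False):
    """Hand-built single-amplicon profile over a C-homogeneous reference
    with a C>T top variant everywhere."""
    prof = VrfProfile()
    amp = "A1"
    counts = np.zeros((6, L), dtype=np.int64)
    counts[EVENT_ROWS["C"]] = 500
    counts[EVENT_ROWS["T"]] = 500
    prof.counts = {amp: counts}
    prof.depth = {amp: counts[:5].sum(axis=0)}
    prof.vrf = {amp: np.asarray(vrf_values, dtype=float)}
    prof.top_variant = {amp: np.array(["C>T"] * L, dtype=object)}
    prof.top_count = {amp: (prof.vrf[amp] * 1000).astype(int)}
    prof.region = {amp: np.array(["enrichment"] * L, dtype=object)}
    prof.low_coverage = {amp: np.zeros(L, dtype=bool)}
    prof.ref = {amp: "C" * L}
    return prof


class TestDeltaVrf:
    def test_identical_profiles_zero_delta(self):
        prof = _flat_profile(50, np.full(50, 0.5))
        df = delta_vrf(prof, prof)
        assert np.allclose(df["delta_vrf"], 0.0)

    def test_spike_on_gaussian_background_z_near_ten(self):
        """ΔVRF of +0.05 over Normal(0, 0.005) background noise across 200
        positions scores z ~ 10 (robust, leave-one-out)."""
        rng = np.random.default_rng(21)
        noise = rng.normal(0.0, 0.005, size=200)
        tumor_vrf = 0.5 + noise
        tumor_vrf[100] += 0.05
        tumor = _flat_profile(200, tumor_vrf)
        normal = _flat_profile(200, np.full(200, 0.5))
        df = delta_vrf(tumor, normal)
        z = df["z"].to_numpy()
        assert z[100] == pytest.approx(10.0, abs=3.0)
        assert np.nanmax(np.abs(np.delete(z, 100))) < 6

    def test_simulated_spikein_vs_matched_normal_top_z(self, rng):
        """5% VAF spike-ins (no enrichment) against a matched normal: the
        two spiked loci carry the two largest z-scores panel-wide."""
        panel = random_panel(n_amplicons=2, seed=31)
        l1 = pick_snv_locus(panel, "AMP00")
        l2 = pick_snv_locus(panel, "AMP01", offset=11)
        err = (0.012, 0.004, 0.004)  # 2% total
        tcfg = SimulationConfig(true_vaf={l1: 0.05, l2: 0.05},
                                enrichment_fold=1.0, error_rates=err)
        ncfg = SimulationConfig(true_vaf={}, error_rates=err)
        profiles = []
        for cfg in (tcfg, ncfg):
            monomers, _ = simulate_monomers(panel, cfg, 3000, rng)
            noisy = apply_error_model(monomers, cfg, rng)
            alns, _ = align_readset(noisy, panel)
            profiles.append(vrf_profile(build_pileup(alns, panel), panel))
        df = delta_vrf(profiles[0], profiles[1])
        top2 = df.nlargest(2, "z")[["amplicon", "position"]]
        found = {(r.amplicon, int(r.position)) for r in top2.itertuples()}
        assert found == {(l1[0], l1[1]), (l2[0], l2[1])}

    def test_mismatched_amplicons_rejected(self):
        a = _flat_profile(50, np.full(50, 0.5))
        b = _flat_profile(50, np.full(50, 0.5))
        b.vrf = {"OTHER": b.vrf["A1"]}
        with pytest.raises(ValueError, match="different amplicons"):
            delta_vrf(a, b)


class TestConfidenceScore:
    def test_high_vrf_high_depth_clears_gate(self):
        # VRF 0.9 at depth 150 against a 7% error null.
        assert confidence_score(135, 150, error_rate=0.07) > 180

    def test_gate_operating_point_attainable(self):
        assert confidence_score(10, 50, error_rate=0.1) >= 180

    def test_zero_vrf_minimal(self):
        assert confidence_score(0, 150) == 0.0

    def test_provider_fails_closed_below_coverage(self):
        provider = LlrScoreProvider(min_coverage=50)
        assert provider.score("A", 1, "C>T", 9, 10) is None

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 148), st.integers(1, 150))
    def test_monotone_in_variant_count(self, k, depth):
        if k + 1 > depth:
            depth = k + 1
        assert confidence_score(k + 1, depth) >= confidence_score(k, depth)

    def test_homopolymer_indel_null_inflated(self):
        """With panel context the deletion null inside a homopolymer run
        scales with run length, so a ~20% deletion VRF there no longer
        clears the gate while the same VRF elsewhere does."""
        from concatcall.panel import Amplicon, AmpliconPanel
        seq = ("ACGT" * 20 + "AAAAA" + "CGTA" * 20).replace("", "")
        amp = Amplicon("H1", seq, (0, 10), (len(seq) - 10, len(seq)),
                       (15, len(seq) - 15))
        panel = AmpliconPanel([amp], enrichment_fold={"H1": 10.0})
        provider = LlrScoreProvider(panel=panel)
        run_pos = 80  # inside the AAAAA run
        assert seq[run_pos] == "A" and seq[run_pos:run_pos + 3] == "AAA"
        in_run = provider.score("H1", run_pos, "del", 30, 150)
        outside = provider.score("H1", 20, "del", 30, 150)
        assert outside > 180
        assert in_run < outside
        assert in_run < 180


class TestCallVariants:
    def _profile(self, panel, vrf, depth=100, pos=None):
        amp = panel.get("AMP00")
        if pos is None:
            pos = amp.enrichment_region[0] + 3
        ref = amp.sequence[pos]
        alt = "T" if ref != "T" else "G"
        pileup = PileupMatrix.zeros(panel)
        c = pileup.counts["AMP00"]
        for p, base in enumerate(amp.sequence):
            c[EVENT_ROWS[base], p] = depth
        k = int(round(vrf * depth))
        c[EVENT_ROWS[ref], pos] = depth - k
        c[EVENT_ROWS[alt], pos] = k
        return vrf_profile(pileup, panel), pos, f"{ref}>{alt}"

    def test_both_gates_pass_called(self, panel):
        prof, pos, var = self._profile(panel, 0.25)
        table = call_variants(prof, LlrScoreProvider(panel=panel),
                              GateConfig(), panel)
        row = table.df.iloc[0]
        assert (row["position"], row["variant"]) == (pos, var)
        assert row["called"] and row["pass_vrf"] and row["pass_score"]

    def test_score_gate_failure_blocks_call(self, panel):
        class FixedScore:
            def score(self, *a):
                return 100.0
        prof, pos, var = self._profile(panel, 0.25)
        table = call_variants(prof, FixedScore(), GateConfig(), panel)
        row = table.df.iloc[0]
        assert row["pass_vrf"] and not row["pass_score"]
        assert not row["called"]

    def test_blacklisted_locus_not_called(self, panel):
        prof, pos, var = self._profile(panel, 0.9)
        panel.blacklist.add(("AMP00", pos, var))
        try:
            table = call_variants(prof, LlrScoreProvider(panel=panel),
                                  GateConfig(), panel)
            row = table.df.iloc[0]
            assert row["blacklisted"] and not row["called"]
        finally:
            panel.blacklist.clear()

    def test_low_coverage_blocks_call(self, panel):
        prof, pos, var = self._profile(panel, 0.5, depth=30)
        table = call_variants(prof, LlrScoreProvider(panel=panel),
                              GateConfig(), panel)
        row = table.df.iloc[0]
        assert not row["pass_coverage"] and not row["called"]

    def test_outside_enrichment_region_not_called(self, panel):
        amp = panel.get("AMP00")
        pos = amp.forward_primer_span[1] + 1  # between primer and region
        prof, pos, var = self._profile(panel, 0.5, pos=pos)
        table = call_variants(prof, LlrScoreProvider(panel=panel),
                              GateConfig(), panel)
        row = table.df.iloc[0]
        assert not row["in_enrichment"] and not row["called"]

    def test_raising_variant_count_never_uncalls(self, panel):
        """Monotonicity: more variant reads at fixed depth keeps a called
        locus called."""
        called_flags = []
        for vrf in (0.25, 0.4, 0.6, 0.8, 1.0):
            prof, pos, var = self._profile(panel, vrf)
            table = call_variants(prof, LlrScoreProvider(panel=panel),
                                  GateConfig(), panel)
            called_flags.append(bool(table.df.iloc[0]["called"]))
        assert called_flags == sorted(called_flags)
        assert called_flags[0]

    def test_vrf_exactly_at_threshold_is_called(self, panel):
        """The 20% VRF gate is inclusive: a locus at exactly 0.20
        passes."""
        prof, pos, var = self._profile(panel, 0.20)
        table = call_variants(prof, LlrScoreProvider(panel=panel),
                              GateConfig(), panel)
        assert bool(table.df.iloc[0]["pass_vrf"])

    def test_vcf_score_provider_roundtrip(self, panel, tmp_path):
        from concatcall import write_calls
        prof, pos, var = self._profile(panel, 0.5)
        table = call_variants(prof, LlrScoreProvider(panel=panel),
                              GateConfig(), panel)
        path = tmp_path / "ext.vcf"
        write_calls(table, path, "vcf-like", panel=panel)
        provider = VcfScoreProvider(path)
        score = provider.score("AMP00", pos, var, 0, 0)
        assert score == pytest.approx(float(table.df.iloc[0]["score"]),
                                      abs=1.0)
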