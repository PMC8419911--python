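# concatcall

Somatic variant detection and VAF quantitation for **allele-enriched,
concatemerized amplicon nanopore sequencing**.

## The problem

Nanopore sequencing is fast and cheap but has two obstacles for somatic
mutation panels: short amplicons sequence inefficiently (low throughput,
poor per-read quality), and raw error rates of 7–10% drown out low-VAF
variants. Two wet-lab tricks fix both — and create the computational
problems this package solves:

1. **Allele enrichment** (blocker-displacement PCR): a wildtype-binding
   blocker suppresses wildtype amplification, so a variant at sample VAF
   *v* is sequenced at a much higher *variant read fraction* (VRF).
   Enrichment acts multiplicatively on allele odds with a calibratable
   fold *E*:

   ```
   VRF = E·v/(1−v) / (1 + E·v/(1−v))
   ```

2. **Stochastic amplicon ligation**: short amplicons are ligated into
   long concatemers (typically 12–15 monomers per read) joined by a fixed
   junction adapter, recovering nanopore's long-read throughput.

`concatcall` implements the downstream pipeline: simulate such reads
(with ground truth), **deconcatenate** them by approximate junction
matching, align monomer segments to the panel and build a per-position
event **pileup**, compute **VRF / ΔVRF** statistics, call variants with a
**dual gate** (VRF ≥ 20% *and* confidence score ≥ 180, at ≥ 50× coverage,
after downsampling below 150×), back-calculate sample **VAF** through the
calibrated fold *E* (with saturation handling above 90% VRF), and score
call sets against a comparator assay (2×2 concordance, precision–recall,
AUC).

## Worked example

```bash
python examples/01_simulate_and_call.py
```

```
spiking C>T at AMP00:35 with VAF 1%, E=1000
300 concatemers -> 3782 segments, 3782 aligned, 596 after <150x cap
amplicon  position variant      vrf  coverage  score  called  estimated_vaf classification
   AMP00        35     C>T 0.765101       149  999.0    True       0.003247        low-VAF
   AMP03        98     del 0.208054       149    0.0   False       0.000263        low-VAF
   AMP03       122     del 0.201342       149    0.0   False       0.000252        low-VAF
```

The 1% spike-in is enriched to a ~77% VRF and passes both gates. The two
deletion rows are homopolymer error pileups: they clear the 20% VRF gate
but the context-aware confidence score rejects them — exactly the error
mode the dual gate exists for. `estimated_vaf` inverts the odds model
through the calibrated fold (quantitation below a few per mill is
depth-limited after the coverage cap; see `docs/methods.md`).

The other examples cover deconcatenation (`02`), fold calibration and
saturation (`03`), and concordance/PR evaluation (`04`). A thin CLI
mirrors the library: `concatcall simulate | deconcat | align | call |
quantify | compare | run-all`.

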