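# cfmir

Analysis toolkit for **cell-free small-RNA profiling across plasma
fractions**: whole plasma (WP), extracellular vesicles (EV) and EV-depleted
plasma (EVD), sequenced in a case/control cohort (PTSD+ / PTSD−). Circulating
miRNAs travel both inside vesicles and bound to protein complexes, and the two
pools can carry different disease signatures; this package implements the full
computational chain needed to compare them — and a synthetic cohort generator
that makes every stage testable without access to cohort data.

The chain:

1. **Reliable-detection filtering** — keep features with ≥ 5 reads in more
   than 50% of a fraction's samples; detection-set Venn accounting across
   fractions; RNA-type composition comparison (rank tests on per-sample read
   shares).
2. **Differential abundance** — TMM normalization (weighted trimmed mean of
   M-values), a common negative-binomial dispersion φ estimated by
   conditional maximum likelihood on library-size-equalized pseudo-counts
   (Var = μ + φμ²), and a two-sided conditional **exact test** per feature;
   calls at *p* < 0.05 and fold-change > 1.5. The same machinery partitions
   features into EV-enriched / EV-underrepresented sets and the 3' ends of
   mature sequences are scanned for the GGAG/GGCU EV-sorting motifs.
3. **qPCR validation** — sequencing-guided reference selection (fold-change
   < 1.1, *p* > 0.05, CV < 0.05 in every fraction, ranked by abundance),
   ΔCq normalization against the geometric mean of the reference quantities,
   Welch's *t*-test on −ΔCq, and sequencing-vs-qPCR direction concordance.
4. **Target enrichment** — hypergeometric term overrepresentation of a
   miRNA's target genes (selected at *p* < 0.1 with ≥ 3 target genes) and the
   **fold-enrichment score** FES = (a/b)/(c/d), where a = the miRNA's targets
   in the term, b = its targets in the annotation universe, c = the term's
   genes, d = all annotated genes; each score is ranked against the empirical
   FES distribution of all non-altered miRNAs (flagged when fewer than 5%
   score higher).

## Worked example

Simulate a three-fraction cohort (12 subjects per group) with one planted
EV-specific marker (4-fold up) and one EVD-specific marker (3-fold down), and
run the whole pipeline:

```python
import cfmir as m

sim = m.SimConfig(
    de_spec=[m.PlantedEffect("miR-sim-0100", "EV", 4.0, "up"),
             m.PlantedEffect("miR-sim-0150", "EVD", 3.0, "down")],
    lib_size_mean=2e5)
summary = m.run_pipeline(m.RunConfig(simulation=sim, seed=1, outdir="demo"))

for frac, s in summary["fractions"].items():
    print(f"{frac}: {s['n_detected']} features detected, "
          f"{s['n_called']} called (phi = {s['dispersion']:.3f})")
print("common miRNAs:", summary["venn"]["regions"]["EV&EVD&WP"])
print("references:", summary["reference_mirnas"])
print("validated:", summary["validated_candidates_all"])
for e in summary["fes"]:
    print(f"{e['mirna']}: {e['n_targets']} targets, "
          f"planted term in top-5% tail: {e['planted_term'] in e['top5_terms']}")
```

prints

```
WP: 427 features detected, 8 called (phi = 0.099)
EV: 360 features detected, 4 called (phi = 0.099)
EVD: 423 features detected, 7 called (phi = 0.097)
common miRNAs: 172
references: ['miR-sim-0003', 'miR-sim-0004', 'miR-sim-0001', 'miR-sim-0005']
validated: ['miR-sim-0100', 'miR-sim-0150']
miR-sim-0100: 132 targets, planted term in top-5% tail: True
miR-sim-0150: 148 targets, planted term in top-5% tail: True
```

Reading this: the detection filter keeps ~360–430 of 490 simulated features
per fraction (fewest in EV, whose reads are spread across more RNA classes);
the estimated dispersion recovers the simulated φ = 0.1; 172 miRNAs are
detected in all three fractions; four stable, abundant miRNAs are selected as
qPCR references; both planted markers are called in sequencing, confirmed by
the simulated qPCR validation cohort, and their planted annotation terms score
in the top 5% of the background FES distribution — the full discovery →
validation → interpretation loop closes on the planted truth. The few extra
calls per fraction are the expected false positives of unadjusted *p* < 0.05
calling across ~400 features.

All intermediates (count tables, DE results, TMM factors, Cq tables,
enrichment and FES records, run summary) are written to `demo/` as TSV/CSV/
JSON. The same run is available from the shell:

```bash
cfmir run --seed 1 --outdir demo
cfmir simulate --outdir sim --seed 7        # cohort + ground truth only
cfmir de --counts sim/counts_EV.tsv --samples sim/samples.tsv --out de_EV.tsv
```

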