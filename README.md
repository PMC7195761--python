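# duohit

Candidate-gene discovery for familial cancer from an affected-relative duo:
shared germline variant prioritization plus a tumour loss-of-heterozygosity
(LOH) "second hit" overlay.

## The problem

When two relatives both develop a rare tumour — here, appendiceal mucinous
tumours with pseudomyxoma peritonei — a plausible explanation is a shared
rare germline variant in a predisposition gene. With only two affected
exomes there is no power for formal linkage or burden testing; instead the
field uses an ordered filter cascade to shrink each exome's ~tens of
thousands of coding calls to a handful of shared, rare, predicted-deleterious
candidates, and then looks to the tumours for corroborating somatic
evidence. Under the two-hit model of tumour-suppressor inactivation, a true
predisposition variant should be accompanied in tumour tissue by loss of the
remaining wild-type allele, most visibly as LOH over the locus.

`duohit` implements both halves as a tested, reusable pipeline:

1. **Filter cascade** (per individual, then shared). Keep calls with Phred
   quality > 30 and variant allele fraction (VAF) in the inclusive
   heterozygous band [0.15, 0.8], restricted to loss-of-function (LoF:
   nonsense, truncating frameshift, essential splice) and missense; drop
   anything present in the discovery control cohorts; intersect the two
   individuals' survivors on normalized variant identity
   (chrom, pos, ref, alt); remove curator-blacklisted artefact calls; keep
   LoF unconditionally and missense only with scaled CADD ≥ 10; finally
   drop anything with verification-cohort (gnomAD-style) frequency
   > 1 × 10⁻⁴. Every step's survivor count is recorded in a
   machine-readable ledger.
2. **LOH segment algebra and two-hit overlay.** Parse per-tumour
   copy-number/LOH segment tables (SEG/BED/plain table), take each tumour's
   LOH-bearing view, intersect the views across tumours, compute genome
   fractions, and classify each surviving candidate as lying in shared LOH,
   in LOH private to one tumour, or in none — then combine with tumour
   allele observations to call each candidate `supported`, `contradicted`
   (mutant allele lost somatically), or `unresolved`.

A seeded synthetic-duo generator (`duohit.synthetic_data`) produces complete
inputs bundles — VCFs, annotation sidecars, cohort panels, segment tables,
blacklist — with recorded ground truth, so the whole pipeline is testable
end to end without access to the original exomes, which were never
deposited.

## Worked example

The published evidence tables of the study this package models are bundled
in `duohit.datasets`: the fifteen validated shared candidates and the two
tumours' segment tables.

```python
from duohit import CohortPanel, FilterConfig, run_cascade, intersect_sets, loh_view, mb
from duohit import datasets
from duohit.two_hit import classify_two_hit, variants_in_segments

candidates = datasets.candidate_variants()
gnomad = CohortPanel("gnomad", frequencies={v.key: v.cohort_freqs["gnomad"]
                                            for v in candidates})
final, ledger = run_cascade(candidates, candidates, panels=[],
                            config=FilterConfig(), verification_cohort=gnomad)
print(f"{final.n_total} candidates ({final.n_lof} LoF, {final.n_missense} missense)")

p1, p2 = datasets.tumour_segments("P1"), datasets.tumour_segments("P2")
shared = intersect_sets(loh_view(p1), loh_view(p2))
for s in shared:
    print(f"shared LOH: chr{s.chrom}:{s.start}-{s.end} ({mb(s.length):.2f} Mb)")

zones = variants_in_segments(final, {"P1": p1, "P2": p2})
calls = classify_two_hit(zones, datasets.tumour_allele_observations())
for c in calls:
    if c.zone.kind != "none":
        print(f"{c.gene}: {c.zone.kind}({c.zone.sample_id}) "
              f"{c.allele_status} -> {c.candidacy}")
```

prints

```
15 candidates (1 LoF, 14 missense)
shared LOH: chr2:241428066-243199373 (1.77 Mb)
TNFRSF1B: loh_in_one(P1) heterozygous_retained -> unresolved
RANBP2: loh_in_one(P1) mutant_lost -> contradicted
EXOG: loh_in_one(P1) heterozygous_retained -> unresolved
RANBP6: loh_in_one(P1) heterozygous_retained -> unresolved
```

Reading: all fifteen published candidates survive the final CADD and
frequency filters (one LoF — the REEP5 nonsense variant — and fourteen
missense); the only LOH region common to both tumours is a 1.77 Mb interval
on chromosome 2q (which contains none of the candidates); four candidates
sit in LOH private to P1's tumour, and tumour sequencing rules out RANBP2
because the tumour lost the *mutant* allele rather than the wild type.

## Command line

A thin CLI wraps the library: `duohit simulate` (synthetic inputs bundle
with truth), `duohit prioritize` (cascade + ledger from a YAML run
configuration), `duohit loh` (segment intersection/fractions), and
`duohit overlay` (two-hit annotation of a candidate table). See
`duohit <cmd> --help`.

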