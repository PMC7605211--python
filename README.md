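# trisnp

Triallelic SNP panels for yak husbandry and conservation: marker
discovery, animal identification, one-parent parentage exclusion, and
detection of recent cattle introgression.

Domestic yak (*Bos grunniens*) hybridize readily with cattle
(*B. taurus*), and breeders need a single affordable marker panel that
can (1) fingerprint individual animals, (2) verify parentage when only
one candidate parent is genotyped, and (3) flag animals with an F1
yak × cattle hybrid in their recent pedigree. Triallelic SNPs do all
three at once: each marker carries a *Bos* ancestral allele (A1) and a
yak-associated allele (A2) that segregate in yak and power
identity/parentage testing, plus a *B. taurus*-associated allele (A3)
that is nearly fixed in cattle but rare in yak, so its count in an
animal tracks how many generations separate it from a hybridization
event.

`trisnp` implements the full workflow for this marker class:

- **discovery** — filter multi-species VCF genotypes down to usable
  triallelic markers: a coarse species filter (reference yaks
  heterozygous A1/A2, outgroup species homozygous A1, A1 differing from
  the reference base), a fine filter requiring near-fixation of the
  reference allele in a beef-cattle diversity panel (≥183 of 192
  alleles), flank extraction with masking of disruptive neighboring
  variants, a unique-mapping filter, removal of markers monomorphic in
  the genotyped population, and greedy assignment into genomic bins
  (<1 Mb clusters, ~5 Mb target spacing).
- **stats** — closed-form statistics under Hardy–Weinberg proportions:
  per-marker probability of identity `P_I = χ₁₁² + χ₁₂² + χ₂₂²` and
  one-parent probability of exclusion `P_E = 2p²q²` (opposing
  homozygotes), combined panel values, relatedness adjustment, and the
  "how many bulls / how many SNPs" design calculations.
- **exclusion** — the triallelic exclusion calculus: an adult is
  excluded when it shares no allele with the calf (so heterozygous
  sites become informative through A3), obligate paternal alleles when
  the dam is genotyped, and an error-tolerant verdict.
- **simulate** — Monte-Carlo power studies: exclusion-count
  distributions for random pairs, false exclusions in true parents
  under allelic dropout, cattle-allele decay across backcross
  generations, and a maximum-likelihood introgression classifier.
- **synthetic** — generators for every input above (discovery cohorts
  with truth tables, HW population matrices, hybrid pedigrees), so the
  whole pipeline runs without any external data.

## Worked example

```python
from trisnp import synthetic, discovery, stats, simulate

# a synthetic discovery cohort: 20 true markers + 6 decoys per filter class
bundle = synthetic.generate_discovery_cohort(
    synthetic.CohortSpec(n_markers=20, n_decoys_per_class=6, seed=7))
res = discovery.run_discovery(
    bundle.cohort, bundle.population, bundle.hits,
    reference=bundle.reference, flank_variants=bundle.flank_variants)
print(res.stage_counts)
# {'input': 50, 'coarse': 44, 'fine': 38, 'mask': 32, 'unique': 26,
#  'monomorphic': 20, 'binned': 20}
```

Each filter stage removes exactly the six decoys built to violate it,
and the 20 planted markers survive to the binned panel.

```python
print(f"{stats.pi_single(0.296):.3f}")   # 0.427
print(f"{stats.pe_single(0.296):.3f}")   # 0.087
print(stats.bulls_excludable(5.3e-4, 0.99))  # 19
print(simulate.classify_introgression(11, 87).label)  # B3
```

At the panel-average minor allele frequency of 0.296, two random yaks
match genotypes at an average marker with probability 0.427 (so ~29
independent markers suffice for a globally unique fingerprint), a
random non-parent is excluded at a single marker with probability
0.087, and a panel whose per-bull non-exclusion probability is
5.3 × 10⁻⁴ can exclude 19 random bulls simultaneously at 99%
confidence. An animal carrying 11 cattle-associated alleles at 87
genotyped sites is most consistent with a third-generation backcross
(B3, one F1 great-grandparent).

The same operations are available from the shell:

```bash
trisnp synth --n-markers 20 --n-decoys-per-class 6 --seed 7 --out-dir demo/
trisnp discover --vcf demo/cohort.vcf --roles demo/roles.tsv \
    --fasta demo/reference.fa --hits demo/hits.tsv \
    --flank-variants demo/flank_variants.tsv \
    --population demo/population.tsv --markers demo/markers.tsv \
    --out-panel demo/panel.tsv --out-bed demo/loci.bed
trisnp simulate backcross --panel-size 87 --seed 1 --out-prefix demo/bc
```

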