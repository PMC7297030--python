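# afddmap

Mapping recessive traits from pooled genome sequencing of an outcrossing F1
cross, by allele-frequency directional difference and density (AFDDD)
scanning of segregation-type-informative SNVs — together with a seeded
forward simulator of the whole experiment so every stage can be exercised
and validated on a desk-top machine without any sequencing data.

## The problem

In a cross between two heterozygous (outcrossing) parents, a recessive trait
— here the suppression of the dominant columnar growth habit in apple by
recessive suppressor loci — cannot be mapped with the usual
dominant-trait bulked-segregant recipes.  The information lives in SNVs whose
*phase-resolved segregation type* predicts a different variant allele
frequency (AF) in a pool of recessive-phenotype offspring than in a pool of
dominant-phenotype offspring.  Writing each parent as an ordered allele pair
with the first allele on the haplotype carrying the recessive trait allele
(V = variant with respect to the reference, R = reference), five of the
twelve phase-resolved derivatives of the outcrossing marker types
⟨hk × hk⟩, ⟨lm × ll⟩ and ⟨nn × np⟩ are informative:

| type | configuration | AF recessive pool | AF dominant pool (1 / 2 genes) | AFDD (pp) |
|------|---------------|-------------------|--------------------------------|-----------|
| A | (V\|R, V\|R) | 100% | 33.3% / 46.7% | 66.7 / 53.3 |
| B | (V\|R, V\|V) | 100% | 66.7% / 73.3% | 33.3 / 26.7 |
| C | (V\|V, V\|R) | 100% | 66.7% / 73.3% | 33.3 / 26.7 |
| D | (V\|R, R\|R) | 50%  | 16.7% / 23.3% | 33.3 / 26.7 |
| E | (R\|R, V\|R) | 50%  | 16.7% / 23.3% | 33.3 / 26.7 |

AFDD = AF(recessive pool) − AF(dominant pool) in percentage points; only a
positive difference is informative.  The pipeline:

1. **QC** of per-pool variant tables (caller floor: coverage ≥ 10, variant
   reads ≥ 2; then drop reference calls, non-SNVs, coverage < 20× or > 200×);
2. **partition** into pool-specific and pool-common SNVs and **zygosity
   grouping** of common SNVs (heterozygous 15% ≤ AF < 85%, homozygous
   AF ≥ 85%) into Ho-R/He-D, He-R/He-D, He-R/Ho-D, Ho-R/Ho-D;
3. **informative-SNV filters** per type set — A: AF(rec) ≥ 85%, AFDD ≥ 43.3;
   B/C: AF(rec) ≥ 85%, 16.7 ≤ AFDD < 43.3; D/E: 35 ≤ AF(rec) ≤ 65,
   16.7 ≤ AFDD ≤ 43.3 — bracketing the expectations of both recessive models;
4. **scan**: informative-SNV counts in 1-Mb windows, standard-score test
   against the genome-average density, LODz = −log₁₀(two-tailed p), peak
   regions where LODz > 2.5 with z > 0.

The synthetic-data module simulates the full experiment: a biparental cross
with a dominant Co-like locus and one or two linked recessive suppressors,
recombination under the Haldane model, age-dependent incomplete penetrance,
phenotype-based pooling (16 recessive vs 18 dominant carriers by default),
and pooled allele counts at mean depths 22.5×/34.6×.

## Worked example

```python
import afddmap as am

# exact expectations for every phase-resolved derivative x model
table = am.expectation_table()
print(table[table.informative].round(1))

# a full synthetic experiment and scan at the default study scale
result = am.simulate_experiment(seed=1)
scan = am.scan_pools(result.recessive_reads, result.dominant_reads,
                     result.config.genome.lengths)
print(scan.informative_counts)
print(scan.peaks)
print(result.truth_loci)
```

With seed 1 this prints the expectation table shown above, then:

```
informative SNVs: {'A': 21, 'B/C': 325, 'D/E': 488}
chrom    start      end  apex_start  apex_lodz contributing_types
 chr1 22000000 23000000    22000000       2.97                D/E
 chr1 26000000 29000000    27000000      13.01              A,B/C
 chr2 15000000 18000000    17000000       7.63                B/C
 ...
true loci:
chrom      pos           name
 chr1 28000000 dominant_locus
 chr1 26500000    suppressor1
 chr2 14500000    suppressor2
```

The strongest region (chr1:26–29 Mb, apex LODz 13.0, driven by type A and
B/C SNVs) contains the simulated suppressor locus at chr1:26.5 Mb; the
chr2 region covers the second, weaker suppressor (heterozygous in one parent
only), and the remaining small regions are linkage shoulders or noise at the
LODz 2.5 cutoff.  `result.truth_loci` gives the ground truth to compare
against.

The same run from the shell:

```
afddmap simulate --seed 1 --out run/
afddmap scan --recessive run/pool_recessive.vcf --dominant run/pool_dominant.vcf \
             --genome run/genome_lengths.tsv --out run/scan/
afddmap stats --individuals run/individuals.tsv --out run/stats/
```

Every command writes a `manifest.json` (config, seed, version, input/output
checksums) sufficient to reproduce its outputs byte-identically.

## Layout

- `afddmap.segregation` — exact pool-AF expectations, the 12 phase-resolved
  derivatives, the published filter windows;
- `afddmap.simulate` — the seeded cross/phenotype/pool/read generator;
- `afddmap.classify` — QC, pool partition, zygosity grouping;
- `afddmap.scan` — informative-SNV selection, window densities, LODz, peaks;
- `afddmap.stats` — segregation chi-squares, allele-distortion tests,
  genotype-class phenotype frequencies, score-on-genotype regression;
- `afddmap.cli` — `simulate` / `scan` / `stats` subcommands.

See `docs/methods.md` for the model, parameter choices and known limits.
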