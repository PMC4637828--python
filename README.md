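# migranet

Population-genetic and stable-isotope analyses for baleen-whale migratory
networks, built around the southern right whale (*Eubalaena australis*) study
design: biopsy-based DNA profiles (genetic sex, ~500 bp mtDNA control-region
haplotype, up to 17 microsatellite loci) plus skin δ13C/δ15N values, sampled
on winter calving grounds and coastal migratory corridors.

The package answers three questions a whale population geneticist asks of such
data:

1. **Are calving grounds / management units genetically differentiated?**
   Haplotype (h) and nucleotide (π) diversity, AMOVA-based F_ST and Φ_ST for
   mtDNA, Weir & Cockerham's (1984) θ̂ and Jost's (2008) D_est for
   microsatellites, permutation and Markov-chain exact tests, and factorial
   correspondence analysis for visual overlap — plus the genotype QC in front
   of all of it (per-allele error rate, probability of identity P_ID,
   duplicate detection with one-copy-per-location retention, Hardy–Weinberg
   exact tests).

2. **Is there maternally directed fidelity to feeding grounds ("migratory
   culture")?**  Kruskal–Wallis tests of δ13C across haplotypes, AIC/Akaike
   weighting of linear models in {haplotype, sex, state} with interactions, a
   matriline randomization F-ratio test, Ritland and Lynch–Ritland pairwise
   relatedness, and Mantel tests of relatedness against isotopic Euclidean
   distance.

3. **How large were these populations historically?**  Monte-Carlo
   propagation of coalescent diversity θ = 2·N_e(f)·μ to female effective
   size N_e(f), mature females N_T(f) = 2·N_e(f), and census size
   N_C = c·N_T(f), with generation span G ~ U(18.1, 28.8) yr, maturity factor
   c ~ U(2.5, 4.71) and μ = 2.0×10⁻⁸ bp⁻¹yr⁻¹.

A first-class synthetic-data module generates profiles with all the structure
these analyses assume — island-model differentiation at a targetable F_ST
(Balding–Nichols allele frequencies), matriline-structured δ13C with
unstructured δ15N, pedigree pairs of known relatedness, injected duplicate
samples and allele-call errors — with full ground truth, so the whole pipeline
runs and validates itself with no field data.

## Worked example

```python
import numpy as np
from migranet import simulate, popgen, culture, abundance

# two management units, 50 whales each, moderate differentiation
cfg = simulate.SimConfig(n_regions=2, n_per_region=50, n_loci=17,
                         target_fst=0.05, seed=11)
profiles, truth = simulate.simulate_island_model(cfg)
iso, _ = simulate.simulate_matriline_isotopes(profiles, cfg, truth)

print(popgen.weir_cockerham_fst(profiles).estimate)
# 0.04429... — the multi-locus Weir–Cockerham estimate of the simulated F_ST

d13 = {i.sample_id: i.d13C for i in iso}
vals = [d13[p.sample_id] for p in profiles]
groups = [(p.haplotype, p.management_unit) for p in profiles]
f, p = culture.matriline_randomization_test(vals, groups, n_rand=10_000, seed=1)
print(f, p)
# 75.326... 0.0 — between-matriline mean squares dwarf within-matriline ones;
# no random relabelling reached the observed F, so maternal fidelity to
# feeding areas would be inferred for these synthetic whales

est = abundance.ThetaEstimate("WA", point=4.72e-3, hpd_low=8.31e-5, hpd_high=0.0115)
res = abundance.abundance_from_estimate(est, n_draws=2000, seed=2)
print(round(res.ne_f[0]), round(res.nc[0]))
# 11593 83587 — mean female effective size and mean census size implied by a
# log-normal θ stand-in fitted to the point estimate and 95% HPD interval
# (the wide, asymmetric interval puts the fitted mean far above the median)
```

There is also a CLI covering each stage and a one-shot pipeline:

```sh
migranet simulate --seed 1 --outdir sim
migranet qc --samples sim/samples.csv
migranet structure --samples sim/samples.csv --fasta sim/haplotypes.fasta
migranet run --config run.yaml --outdir out
```

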