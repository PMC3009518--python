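# fhapminer

Family-based haplotype association mapping for candidate-gene regions of
tightly linked SNPs.

Family designs are robust to population stratification, and pedigrees make
haplotype phase nearly unambiguous — but classical family tests (the
transmission disequilibrium test, TDT) look at one marker at a time and treat
every haplotype as an unrelated allele. `fhapminer` implements an
alternative that exploits haplotype *similarity*:

1. **Phase** every pedigree under the zero-recombination assumption (no
   recombination inside a candidate region within a family). Genotype
   constraints become a linear system over GF(2) in one inheritance variable
   per parent–child edge and one phase variable per undetermined founder
   locus; the solver returns the complete solution space and can enumerate
   or sample configurations uniformly.
2. **Score** each founder haplotype *h<sub>ik</sub>* of family *i* with
   *s<sub>ik</sub>* = Σ<sub>j</sub> c<sub>ij</sub>(Y<sub>ij</sub> − Ȳ<sub>i</sub>),
   where c<sub>ij</sub> ∈ {0,1,2} counts the copies of the haplotype carried
   by member *j* and Ȳ<sub>i</sub> is the family phenotype mean — haplotypes
   riding in affected members score high, and scores sum to zero exactly
   within each family.
3. **Scan**: pool founder haplotypes across families (they are independent
   draws from the population), and at every marker cluster the windowed
   segments with a density-based (DBSCAN) algorithm under a
   position-weighted similarity S = w<sub>L</sub>·L + w<sub>N</sub>·N
   (L = shared run through the focal marker, N = matching alleles in the
   window). Each cluster's scores are tested with a Q-score — a t statistic
   for the deviation of the cluster's mean from the overall mean — and the
   max-|Q| cluster per marker is reported with Bonferroni or permutation
   control of the family-wise error.

The package also contains the surrounding study machinery: a single-locus
TDT baseline ((b−c)²/(b+c) over full pedigrees), a pedigree simulator
(CEPH-like 2–3 generation structures, gene dropping from a haplotype
frequency table, penetrance-model phenotypes with ascertainment on ≥1
affected), closed-form penetrance analytics (prevalence, genotype
distribution among the affected, genotype relative risks λ₁ = f₁/f₀,
λ₂ = f₂/f₀), and experiment runners for type-I error, per-SNP and
rare-haplotype power, and mapping precision.

## Worked example

Simulate 50 ascertained families on a synthetic 29-haplotype / 19-SNP panel,
make SNP 13 (minor allele frequency 0.126) the risk locus with penetrances
(0.05, 0.30, 0.50), remove it from the data, and ask both methods to find
the signal from the flanking LD:

```python
import numpy as np
from fhapminer import (
    PENETRANCE_SETS, PenetranceModel, DiseaseMode,
    synthetic_frequency_table, simulate_dataset,
    fhapminer_scan, tdt_scan, mapping_precision,
)
from fhapminer.fam_sim import substream

table = synthetic_frequency_table(0)            # 29 haplotypes, 19 SNPs
allele, maf = table.minor_allele(12)            # SNP 13, 1-based
model = PenetranceModel(*PENETRANCE_SETS["C"], mode=DiseaseMode.SINGLE_LOCUS,
                        risk_snp=12, risk_allele=allele)
data = simulate_dataset(table, n_families=50, model=model, seed=11)

scan = fhapminer_scan(data.pedigrees, rng=substream(11, "analysis"))
tdt = tdt_scan(data.pedigrees)
best = int(np.argmin(scan.p_values()))
print(f"scan: best marker {best + 1}, adjusted p = {scan.p_values()[best]:.2e}, "
      f"significant markers: {sum(scan.significant)}")
d, _ = mapping_precision(scan.raw_p_values(), data.marker_map, data.removed_marker)
print(f"mapping precision: {d:.2f} cM from the true risk locus")
d_tdt, _ = mapping_precision(tdt.p_raw, data.marker_map, data.removed_marker)
print(f"TDT: min adjusted p = {min(tdt.p_adjusted):.2e}, precision {d_tdt:.2f} cM")
```

Output:

```
scan: best marker 15, adjusted p = 4.71e-05, significant markers: 3
mapping precision: 0.03 cM from the true risk locus
TDT: min adjusted p = 1.71e-04, precision 0.03 cM
```

Both methods localize the (removed) risk SNP to 0.03 cM; the cluster scan
reports a stronger adjusted p at its best marker. Power and error rates are
estimated by repeating this over replicates (`fhapminer.run_type1`,
`fhapminer.run_power_single_locus`, `fhapminer.run_power_rare_hap`).

## Command line

A thin CLI wraps the library:

```sh
fhapminer simulate --model single-locus --penetrance C --risk-snp 13 \
    --n-families 50 --seed 11 --out demo       # demo.ped, demo.map, demo.truth.json
fhapminer phase --ped demo.ped --seed 1        # phased haplotypes + founder labels
fhapminer score --ped demo.ped --seed 1 --out demo.scores
fhapminer scan  --scores demo.scores --map demo.map --window 1
fhapminer tdt   --ped demo.ped --map demo.map
fhapminer power --config experiment.yaml --out results/
```

Input formats are the pre-makeped LINKAGE PED dialect (six leading columns,
two allele columns per SNP, phenotype 1/0 affected/normal, missing −9), a
four-column MAP file, and a two-column haplotype-frequency TSV.

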