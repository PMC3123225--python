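# microinv

Detection, phylogenetic mapping and rate modelling of **microinversions** —
short (5–400 bp) segments of DNA that appear reverse-complemented relative to
their homologs. Microinversions are rare genomic changes (RGCs): they
accumulate orders of magnitude more slowly than point substitutions, which
makes them attractive low-homoplasy characters for difficult phylogenetic
problems such as the basal radiation of Neoaves, but also makes them hard to
find and easy to confuse with palindromic false positives.

The package is aimed at molecular evolutionists working with multi-taxon
non-coding alignments (introns, UTRs) and a dated phylogeny. It provides:

- **detect** — all-pairs complementary-strand Smith–Waterman over an
  alignment, projection of hits to alignment columns, clustering of nearby
  hits into candidate regions, and automated validation by *re-inversion*:
  flipping the putative carriers' tract must raise their identity to the
  non-carriers. Palindromic tracts (their own reverse complement) are flagged
  and rejected.
- **characters** — inversion calls coded as binary presence/absence
  characters; minimum change counts by Fitch parsimony (Sankoff/Hartigan
  form, so polytomies and `?` states are handled); DELTRAN/ACCTRAN branch
  placements; per-character and ensemble retention index
  RI = (g−s)/(g−m); a χ² test of whether events concentrate on terminal
  branches beyond their share of the treelength.
- **rates** — per-locus counts c_i over exposures E_i = L_i(Mb)·T_i(MY)
  modelled as c_i ~ Poisson(λE_i), with among-locus heterogeneity
  ("hotspots") as a gamma-mixed Poisson (NB2: variance λE + (λE)²/k). A
  likelihood-ratio test of Poisson vs NB2 against χ²(1) detects hotspot
  loci; exact (Garwood) CIs quantify rate uncertainty. λ is reported in
  inversions·Mb⁻¹·MY⁻¹ throughout.
- **power** — closed forms: P(≥1 inversion) = 1 − exp(−λLt) and the
  sequence length L = −ln(1−P)/(λt·n) needed to resolve short branches.
- **simulate** — a truth-aware generator that evolves sequences down a
  dated tree with substitutions, indels and Poisson inversion events
  (lengths 5–40 bp, median ≈22), optional gamma hotspot multipliers, and a
  registry of every planted event so the whole pipeline can be validated
  end to end without any external data.

A packaged 17-locus avian survey table (locus, mean non-coding length,
treelength, inversion count) drives the worked examples below.

## Worked example

```python
from microinv import (InversionRateModel, packaged_locus_table,
                      poisson_exact_ci, pooled_rate)

records = packaged_locus_table()          # 17 loci, 54 inversions
model = InversionRateModel.from_records(records)
lrt = model.lrt_overdispersion()
print(f"pooled rate = {pooled_rate(records):.4f} /Mb/MY")
print(f"Poisson vs NB2: 2dlnL = {lrt.stat:.2f}, p = {lrt.p:.2g}")

nohot = InversionRateModel.from_records(records, exclude=("CLTC", "CLTCL1"))
print(nohot.fit("poisson").summary())
```

prints

```
pooled rate = 0.3951 /Mb/MY
Poisson vs NB2: 2dlnL = 27.55, p = 1.5e-07
Microinversion rate model
==============================================
model:            Poisson
loci:             15
total count:      30
total exposure:   121.3235 Mb*MY
lambda_hat:       0.2473 inversions/Mb/MY  (s.e. 0.0451)
exact 95% CI:     (0.1668, 0.3530)
log-likelihood:   -27.8404
==============================================
```

The LRT rejects genome-wide rate homogeneity decisively: the two clathrin
heavy-chain loci (CLTC, CLTCL1) are inversion hotspots. Excluding them, the
remaining 15 loci are compatible with a single rate of ≈0.25 /Mb/MY
(2δlnL = 2.29, p = 0.13), and the power module shows what that rate implies
for phylogenetics:

```bash
$ microinv power --rate 0.25
required length: 11.98 Mb per taxon (P(>=1) = 0.95 on a 1.0 MY branch, n_branches = 1)
```

i.e. ~12 Mb of non-coding sequence per taxon to have a 95% chance of one
inversion on a specific 1 MY branch.

The same CLI exposes the full pipeline (`scan`, `call`, `chars`, `map`,
`rates`, `power`, `simulate`, `pipeline`); e.g. a fully synthetic round trip:

```bash
microinv simulate --seed 7 --n-taxa 12 --n-loci 4 --lambda-mi 2 --out sim/
microinv pipeline --tree sim/tree.nwk --alignment sim/locus0.fasta \
    --alignment sim/locus1.fasta --out run/
```

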