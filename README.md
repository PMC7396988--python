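# popgenkit

Population-genetics toolkit for haplotype-based selection scans on phased
biallelic data, built around three pieces:

* **Selection statistics** (`popgenkit.core_stats`) — Hudson FST (per site,
  scans, per-window means), nucleotide diversity with z-tests, Tajima's D
  and normalized Fay & Wu's H with coalescent-simulated null p-values, H12
  (point and sliding windows), EHH, nSL, PBS, pairwise D'/r², D'-chained LD
  block detection, r²-based core-region selection, and Benjamini–Hochberg
  FDR.
* **2D-SFS intra-allelic variability sweep tests** (`popgenkit.sfs2d`) —
  the joint spectrum `Phi[i, j]` of linked-variant carrier counts inside vs
  outside the group carrying a focal derived allele, summary statistics
  (F_c, G_c0, L_c0, G*_c0, γ*(10), i_max, i*_max) with neutral-coalescent
  null distributions and q-values, subhaplotype classification by two tag
  SNPs, recombinant removal, hard/soft/hardening sweep-mode calls, and
  diversity-based dating (divergence time, within-group TMRCA).

  *Note:* the exact published formulas for F_c, G_c0, L_c0 and the starred
  statistics live in cited prior work; this package uses documented
  fallback definitions (see the `iav_stats` docstring) that preserve their
  ranges and monotone response to sweep strength. They are isolated in one
  function so they can be swapped without touching callers.
* **Forward Wright–Fisher admixture simulator** (`popgenkit.dualsim`) — a
  haploid two-lineage model: an isolated island population and a
  continental population diverge for `t1` generations, admix with
  proportion `r` to found the first study population, then drift `t2` more
  generations; optional selection favoring the non-focal allele on the
  continental lineage. Includes the full 570-combination parameter grid,
  weighted FST distributions, two-sample KS comparison, and success-case
  counting against FST/frequency thresholds.

Supporting modules: `popgenkit.ancient` (distinct-haplotype census by
population and per-sample ancient-DNA site-filter policies with consensus
haploidization and ancient-singleton removal), `popgenkit.synth`
(msprime-backed neutral coalescent panels, sweep/subhaplotype fixtures
with truth labels, FST-tuned two-population panels, surrogate genome-wide
FST distributions, VCF round-trip I/O, ms-format export) and
`popgenkit.pipeline` (staged end-to-end runs with a reproducible
manifest).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the binding end-to-end checks (worked
examples, simulator properties, a reduced-grid mechanism check, statistic
oracles, fixture behavior, and null-calibration uniformity); the other
files are unit/property tests per module.

## CLI

Three entry points (all support `--help`):

```sh
# statistics on a phased VCF (INFO/AA ancestral annotation required)
popgen fst data.vcf --panel panel.tsv --pops pop1,pop2 --out fst.tsv
popgen ld-block data.vcf --anchor rs123 --dprime-min 0.98
popgen ehh data.vcf --core rs123 --allele 1 --maf-min 0.05
popgen nsl data.vcf --maf-min 0.01 --max-window 100
popgen h12 data.vcf --window-snps 125
popgen sfs-tests data.vcf --region 8:143,752,235-143,774,193 --seed 1
popgen sfs2d data.vcf --core rs123 --tags rsA,rsB
popgen pbs --fst-ab 0.1 --fst-ao 0.1 --fst-bo 0.0
popgen census data.vcf --panel panel.tsv --core rs123
popgen ancient-filter records.tsv --policy IK002
popgen pipeline --seed 1 --outdir out/          # synthetic end-to-end run

# forward simulation grid
dualsim run --reps 1000 --selection 0 --seed 1 --max-combos 30 --out grid.tsv
dualsim trajectories --t1 875 --r 0.4 --n-jmn 1000 --n-acnt 4000 --plot paths.png

# synthetic data
synth coalescent --n 50 --theta 10 --seed 1 --vcf-out coal.vcf
synth fixture --n-total 206 --n-derived 155 --split 75,80 --vcf-out fix.vcf
synth panel --target-fst 0.25 --vcf-out panel.vcf --panel-out panel.tsv
```

Population panels are TSVs with `sample_id` and `pop` columns; regions are
1-based inclusive `chrom:start-end` strings (thousands separators
tolerated). All randomized operations take a `--seed` and are
bit-reproducible under it.
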