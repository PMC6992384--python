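# ibsleak

Simulation and analysis of genotype-leakage attacks on genetic-genealogy
relative-matching databases that accept user uploads.

Consumer genealogy services find putative relatives by detecting long
identical-by-state (IBS) segments — runs where two genomes share at least
one allele at (nearly) every genotyped SNP.  Services that detect IBS on
*unphased* genotypes do so by scanning for runs free of *incompatible
homozygous sites* (one kit AA, the other GG).  That design, together with
segment-location reporting, lets an adversary who can upload kits read
genotypes back out of the database.  `ibsleak` implements the three
attacks end to end against a fully simulated database, plus the
countermeasures that defeat them:

- **IBS tiling** — upload many real genomes; union the reported segments
  into per-haplotype coverage of a target (IBS1 / IBS2 / IBS1+), and
  read off the target's alleles wherever a covering upload is homozygous.
- **IBS probing** — embed a real haplotype window around a focal allele
  (e.g. a disease-risk SNP) in "IBS-inert" filler sampled *against*
  population allele frequencies; any match then implies the matched
  person carries the haplotype of interest, even if the service hides
  match locations.
- **IBS baiting** — upload artificial kits whose runs of heterozygosity
  can never contain an incompatible homozygous site.  A pair of kits that
  differ only at chosen *key sites* (one homozygous major, one
  homozygous minor) decodes every target's genotype at those sites from
  the break pattern of reported segments; a third kit with the key site
  missing separates heterozygous from missing targets via the reported
  SNP counts.

For a reporting threshold of t cM on a chromosome of c cM, one bait pair
can carry up to `2c/t − 1` key sites (placed at t/2, t, 3t/2, …, c − t/2,
so that the distances from each key site to its flanking key sites or
chromosome ends sum to at least t).  At t = 1 cM, 100 uploads therefore
reveal ≈100 genotypes per cM — enough for genome-wide imputation.

Everything runs on synthetic data from a built-in generator that records
a ground-truth ledger of copied haplotype segments, so sensitivity,
precision, and decoding accuracy are all measured against known truth.

## Worked example

The `demo` subcommand recreates the proof-of-concept baiting experiment
on a synthetic two-chromosome panel: four key SNPs on a chromosome
labeled 22, a triple bait set (0.6-cM flanks holding 22 heterozygous
SNPs per side interspersed with missing calls, anti-frequency filler
elsewhere), and four targets that are homozygous-major, heterozygous,
homozygous-minor, and missing at every key site.  Matching uses a strict
phase-unaware detector at 0.7 cM / 25 SNPs.

```bash
$ ibsleak demo --seed 0 --out-dir demo_out
demo: 4 key sites on chrom 22; 40 reported segments (0 off chromosome 22); decode correct for all targets: True
```

`demo_out/match_table.tsv` begins:

```
target  bait        chrom  left_bp   right_bp  cM    n_snps
T1      bait_B1     22     3044042   4333032   1.31  56
T1      bait_B1     22     6475206   7560876   1.25  48
...
T1      bait_Bmiss  22     3044042   4333032   1.31  55
```

Each bait region produces a ≈1.2-cM reported segment.  The homozygous
targets match only the bait carrying their allele; the heterozygous
target matches both; and the missing-key bait's segment spans exactly
one fewer jointly-called SNP (55 vs 56) than the called bait's — the
signal that distinguishes heterozygous from missing target calls.  No
segment is reported on the chromosome without bait regions.

Other entry points: `ibsleak simulate-panel` (panel, genetic map, raw
kits, truth ledger), `ibsleak match` (1-to-1 segment report between two
raw kits), `ibsleak tile` / `ibsleak probe` / `ibsleak bait` (attack
drivers), `ibsleak screen` (upload screens; exit code 3 on rejection),
and `ibsleak report` (countermeasure-effectiveness matrix).

## Layout

- `src/ibsleak/genotype_io.py` — raw-kit dialect, site panels, genetic maps
- `src/ibsleak/simdata.py` — synthetic panels, haplotype pools, truth ledger
- `src/ibsleak/ibs_engine.py` — phase-unaware/-aware detectors, mock database
- `src/ibsleak/tiling.py`, `probing.py`, `baiting.py` — the three attacks
- `src/ibsleak/screening.py` — upload screens and countermeasure report
- `src/ibsleak/cli.py` — command-line interface
- `docs/methods.md` — models, parameters, and design choices
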