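# polyclust

Density-based genotype calling for polyploid SNP-array intensity data,
with a dosage-aware simulator that makes the whole pipeline testable
without proprietary array exports.

## Why

Genotyping allopolyploid wheat on a two-channel array is hard because a
probe rarely hybridises to just one locus: homoeologous and paralogous
gene copies add constitutive signal.  Plotting each sample at the polar
coordinates

```
theta = (2/pi) · arctan(y/x)      (0 = pure first allele, 1 = pure second)
R     = x + y                      (total hybridisation intensity)
```

the extra copies *compress* the genotype clusters in theta, secondary
polymorphisms in probe annealing sites add clusters beyond the biallelic
AA/AB/BB trio, and gene deletions produce low-R *null* clusters.
Model-based diploid callers break on all three patterns.  `polyclust`
implements the model-free alternative: density-based clustering (DBSCAN
and OPTICS, written from scratch with deterministic tie rules) driven by
two parameters — cluster distance and minimum points per cluster — in a
three-step protocol:

1. DBSCAN (cluster distance 0.07, minimum 10 points) + filters on cluster
   count, call rate and MAF (0.35 for mapping populations, 0.05 for
   diverse accessions);
2. single-cluster assays re-clustered by OPTICS with a forced two-cluster
   extraction from the reachability profile (the compressed-cluster
   rescue);
3. remaining assays re-clustered by DBSCAN at 0.09 (broad clusters).

Samples are assigned to clusters with a Gaussian-responsibility
confidence (called only at ≥ 0.8), clusters are named `C1..Cn` by
ascending theta (`AA/AB/BB` when exactly three non-null clusters remain),
low-intensity clusters are flagged as null alleles (presence-absence
variation), and assays with more than three clusters are resolved into
biallelic loci by tracking which cluster pairs segregate within
bi-parental populations.  A small statistics layer covers MAF spectra,
heterozygosity, shared polymorphism counts, Weir-Cockerham F_ST and LD
r².  Audience: anyone building or re-analysing polyploid array genotyping
pipelines, from Python or the shell.

## Worked example

`examples/04_multilocus_resolution.py` simulates an assay whose probe
anneals to two genomes — the target SNP on one, a silencing secondary SNP
on the other — genotyped in two doubled-haploid crosses:

```
NTS0000: 3 clusters fitted
population P1 segregates C2 vs C3 (46:54, 1:1 chi-square p=0.42)
population P2 segregates C1 vs C3 (48:51, 1:1 chi-square p=0.76)
allelic map edges: [('C2', 'C3', 'P1'), ('C1', 'C3', 'P2')]
shared (hub) cluster: ['C3']
```

Each cross segregates between two of the three clusters, near the 1:1 DH
expectation; the cluster both crosses share (`C3`, the silenced-copy
class) is the hub linking two biallelic contrasts on two genomes.
The other examples cover simulation + calling (`01`), splitting a
compressed cluster pair with the forced-k extraction (`02`), null-allele
detection (`03`, flags a cluster at 7% of normal intensity and recovers
100% of the simulated deletion homozygotes) and population statistics
(`05`).

The same workflows are available from the shell:

```sh
polyclust simulate --config sim.yaml --out-dir sim/
polyclust call --panel sim/panel.report.tsv --mode diversity --out-dir called/
polyclust apply --cluster-file called/clusters.json --panel new_panel.tsv --out applied.tsv
polyclust resolve --genotypes called/genotypes.long.tsv --populations pops.tsv --out-dir resolved/
polyclust stats --genotypes called/genotypes.long.tsv --populations pops.tsv --out-dir stats/
```

Input panels are GenomeStudio-style final-report TSVs (polar Theta/R or
raw X/Y channels) or wide theta/R matrices; outputs are TSV, a versioned
JSON cluster file, and optional VCF.

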