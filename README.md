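# virocomp

Compositional analysis of viral genomes and their hosts: per-genome base
composition, codon-position GC, non-coding GC, codon usage, and the
coupling of all of these to the composition of the host.

## The problem

Genomic GC content — the molar fraction of guanine plus cytosine — is
the simplest genomic signature, yet it constrains codon usage, amino
acid frequencies and dinucleotide patterns.  Among viruses two questions
recur.  First, *within* a genome: how does the GC of the three codon
positions (GC1, GC2, GC3) respond to the GC of the non-coding remainder
of the genome?  Because most third-position changes are synonymous while
second-position changes always alter the protein, mutational bias is
expected to move GC3 far more freely than GC2, with GC1 intermediate.
Second, *between* genomes: does a virus's GC track its host's?  Phages
replicate with the machinery of their prokaryotic hosts and are expected
to couple strongly; viruses of animals and plants are not.

`virocomp` implements this analysis battery for anyone with genome
FASTA, CDS annotations (GFF3/BED) and virus/host metadata tables:
deduplicated per-species genome assembly (one representative per TaxID,
segmented genomes pooled by global counts), composition profiling,
64-codon usage tables (stop codons included), virus-host pairing and
stratified statistics — Spearman's ρ, linear fits with adjusted R²,
Hartigans' dip test of unimodality with Monte-Carlo calibration, and
kernel-density mode detection.  Because the real corpora (RefSeq viral
genomes, virus-host association databases, host codon-usage compendia)
are large external downloads, the package ships a statistically
controlled synthetic-data generator that emulates the study system so
the entire pipeline is exercisable and testable offline.

## Core quantities

For each genome, with counts pooled over segments:

* GC = (G+C)/(A+C+G+T/U), ambiguous IUPAC codes excluded;
* GCk = GC at codon position k ∈ {1,2,3} over all in-frame CDS;
* non-coding GC on the complement of the union of CDS intervals;
* a 64-codon usage table, compared to host tables as fractions.

Across genomes and virus-host pairs: Spearman ρ (midranks),
OLS slope and adjR² = 1 − (1−R²)(n−1)/(n−2), the dip statistic
D_n ∈ [1/(2n), 1/4] with bootstrap p-values against the uniform null,
and KDE modes with the nrd0 bandwidth 0.9·min(sd, IQR/1.349)·n^(−1/5).
See `docs/methods.md` for the full model descriptions.

## Worked example

Simulate a small dataset — 30 bacterial and 30 animal hosts, two viruses
each, phage GC programmed to track host GC (slope 0.9, noise 0.045) and
animal-virus GC decoupled — then correlate:

```sh
virocomp simulate --outdir demo --seed 42 \
    --hosts-per-group bacteria:30,animals:30 --viruses-per-host 2
# wrote 120 viruses, 60 hosts, 120 pairs to demo
# programmed prokaryotic rho: 0.912 (n=60)
# programmed eukaryotic rho: -0.002 (n=60)

virocomp correlate --fasta demo/genomes.fasta \
    --annotations demo/annotations.gff3 \
    --virus-meta demo/virus_metadata.tsv \
    --hosts demo/hosts.tsv --map demo/virus_host_map.tsv \
    --outdir demo_out
```

`demo_out/host_virus_gc.tsv` then contains:

```
stratum      n    rho        p            slope      intercept   adj_r2
all          120  0.629081   1.42255e-14  0.523924   0.155385    0.393918
prokaryotic  60   0.9123     3.70547e-24  0.915304   -0.0482394  0.871851
eukaryotic   60   -0.0122307 0.926103     0.00590903 0.456881    -0.0171382
...
```

The pipeline recovers the programmed contrast from the files alone: the
phage stratum returns ρ = 0.912 (exactly the coupling realised among the
generated targets), the eukaryotic stratum is null, and the fitted slope
0.92 with negative intercept reproduces the programmed law — phages
sitting below their hosts' GC.  The within-genome report
(`noncoding_correlations.tsv`) shows the positional responses to
non-coding GC on the same run:

```
stratum  position  n    rho       ...  slope
all      gc1       120  0.98611        0.715909
all      gc2       120  0.974637       0.512857
all      gc3       120  0.990708       1.70235
```

GC3 responds ~3.3× more steeply than GC2, with GC1 intermediate — the
slope ordering the codon-GC model programs via `gc3_amplification`.

`virocomp profile` adds per-genome profile tables, Baltimore-class
censuses and per-class density/dip reports; `virocomp codon` writes the
64-codon virus-host correlation table with median ρ and adjR² per host
domain.  All subcommands are thin wrappers over the library API
(`virocomp.profile_genome`, `virocomp.spearman_rho`,
`virocomp.dip_test`, ...), and every report is a numeric TSV reproduced
byte-identically under a fixed seed.

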