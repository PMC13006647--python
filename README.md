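# osckit

Toolkit for studying how out-of-frame stop codons (OSCs) — hidden TAA/TAG/TGA
triplets in the +1/+2 reading frames of a coding sequence — constrain
frameshift-indel evolution of protein loops. It covers:

- **OSC scanning** and classification (ochre/amber/opal) with
  composition confound checks (GC content, homopolymer runs);
- an **indel engine** that applies insertions/deletions to engineered
  frameshift constructs, classifies translational outcomes
  (frame-restoring gain of function vs premature stop vs frame disruption),
  transplants events between synonymous +OSC/−OSC construct pairs
  (sequence-reconstruction analysis), and tallies mutant spectra;
- **alignment profiling**: column conservation (> 50 % strict-majority rule),
  information content in bits, gap-aware residue↔column mapping,
  anchor-delimited loop-length extraction with taxon stratification, and
  OSC overlay onto alignment columns;
- **codon-space likelihoods** that an amino-acid pair's junction hides a stop
  (uniform or supplied codon usage), with frequency-weighted and
  observed-pair positional summaries;
- **mutation statistics**: stationary-phase cumulative revertant-frequency
  curves, fold changes, and Lea–Coulson method-of-the-median mutation-rate
  estimation for fluctuation tests;
- **seeded synthetic-data generators** for every input: random ORFs,
  synonymous OSC removal, +1 frameshift construction, selectable mutant
  pools, Luria–Delbrück culture counts, SPM series, and toy alignments with
  planted conservation and loop-length structure.

## CLI

All stages are exposed through one entry point (`osckit --help`); every
command writes a `<out>.manifest.json` with input checksums and seeds.

```sh
osckit scan --fasta gene.fa --frames 1,2 --out oscs.tsv
osckit reconstruct --events events.tsv --source minus.fa --host plus.fa --out recon.tsv
osckit spectrum --events events.tsv --fasta strains.fa --out spectrum.tsv
osckit profile --alignment aln.fa --taxa taxa.tsv --out profile.tsv \
    --loop-ref ref --loop-start 36 --loop-end 47 --loop-out loops.tsv
osckit osclik --pair L K
osckit osclik --alignment aln.fa --cols 60 61 --method observed
osckit spm --in spm.tsv --out freq.tsv
osckit fluctuate --in counts.tsv --nt 1e8 --out rate.json
osckit simulate cds --seed 1 --n-codons 100 --gc 0.45 --out gene.fa
osckit simulate pair --fasta gene.fa --region 3 6 --frameshift-codon 6 --out pair.fa
osckit simulate ld --seed 7 --m 2 --out counts.tsv
osckit simulate alignment --seed 3 --config aln.json --out aln.fa --taxa-out taxa.tsv
osckit simulate spm --seed 5 --strain minus:7e-6 --strain plus:2e-6 --out spm.tsv
```

Conventions: internal coordinates are 0-based half-open; everything crossing
an I/O boundary is 1-based inclusive. Translation uses NCBI table 11 with no
start-codon special-casing. Percentages are printed with one decimal; JSON
keeps full precision. Seeds are mandatory on all stochastic subcommands.

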