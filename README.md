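# capsmine

**CAPS / PCR-RFLP marker discovery from variant calls.**

High-throughput genotyping (GBS, RAD-seq, whole-genome resequencing) yields
thousands of SNPs, MNPs and indels, but routine screening of many individuals
is still cheapest with simple PCR assays. A CAPS marker (cleaved amplified
polymorphic sequence; called PCR-RFLP in human and animal genetics) scores a
variant by whether a restriction enzyme cuts the PCR product: the assay works
whenever one allele carries a recognition site and the other does not.

`capsmine` finds such markers directly from standard files. Given

1. a reference genome (FASTA),
2. called variants with per-sample genotypes (VCF — any caller; SNPs, MNPs,
   indels; bi- or multi-allelic), and
3. a restriction-enzyme catalogue (REBASE, GCG flavor),

it embeds every allele between two 40 bp reference flanks, scans each embedded
sequence against every enzyme's IUPAC-degenerate recognition pattern on both
strands, and reports each locus × enzyme pair for which the observed alleles
split into at least one digested (`+`) and one undigested (`-`) allele. Each
sample's genotype is then re-expressed as a *digestion genotype* (`+/+`,
`-/+`, `-/-`, `?/?` for missing) which maps directly to expected gel band
counts (2 / 3 / 1 for a single-cut amplicon).

Three filters narrow the marker list down to assays worth ordering primers for:

* **segregation prefilter** — drop loci that deviate from the expected F2
  ratio (default 1:2:1, Pearson χ² goodness-of-fit, df = 2, α = 0.05; for
  df = 2 the p-value is exactly `exp(-χ²/2)`) or that have more than 5
  missing genotypes;
* **single-cut filter** (`_scf` output) — keep only markers whose enzyme cuts
  the digested allele's display window (500 bp flanks by default) exactly
  once, at the polymorphic site, and the undigested allele's window not at
  all, guaranteeing clean 1–3-band gel profiles;
* **group filter** (`_gf` output) — keep markers whose digestion genotypes
  co-segregate with user-defined sample groups: mode A assigns each of 2–3
  groups to a distinct digestion genotype (co-dominant scoring), mode B
  matches one homozygote class against everything else (a dominant trait in
  an F2), each group with its own tolerated fraction of inconsistent
  individuals (typically 10%).

Marker regions are exportable as FASTA (reference allele, variant centered,
lowercase flanks / uppercase allele) ready for batch primer-design tools.

## Worked example

No real data is needed: the package ships a synthetic-data generator that
plants site-gain/site-loss variants with known ground truth, plus a
six-enzyme REBASE-style catalogue (TaqI, AvaII, AlwI, SspI, BsiWI, ApeKI).

```sh
capsmine fixture --seed 42 --out-dir demo --n-samples 96 --n-decoys 100
capsmine mine --reference demo/reference.fa --vcf demo/variants.vcf \
    --enzymes src/capsmine/data/enzymes_six.gcg --out demo/markers.caps
capsmine filter-single-cut --markers demo/markers.caps
capsmine filter-groups --markers demo/markers.caps --groups demo/groups.json
capsmine export --markers demo/markers_scf.caps --out demo/markers.fasta
```

prints

```
fixture written to demo (177 loci, 96 samples)
177 loci, 6 enzyme groups -> 72 markers -> demo/markers.caps
60 of 72 markers retained -> demo/markers_scf.caps
1 of 72 markers retained -> demo/markers_gf.caps
exported 60 sequences -> demo/markers.fasta
```

The 177 loci comprise 60 planted site-altering variants (two each of
site-loss SNP, site-gain SNP, site-spanning MNP, deletion, insertion per
enzyme), 12 "trap" loci with a second constitutive site in the flank, and
105 decoys. Mining recovers exactly the 72 planted locus × enzyme pairs; the
single-cut filter removes exactly the 12 traps; the group filter, run in
mode B at a 10% threshold against the fixture's carrier/non-carrier
phenotype groups, keeps exactly the planted trait locus:

```
c0001:551 ('AlwI',) GGATCNNNN'
```

A marker record looks like

```
>c0001:551
AlwI	GGATCNNNN'
ref, [0], C, [+], caacca...	alt, [1], T, [-], caacca...
0/0 [+/+] s013 s014 ...	0/1 [-/+] s001 s002 ...	1/1 [-/-] s004 ...	./. [?/?] s052
```

— locus ID; enzyme name(s) and annotated site (apostrophe = top-strand cut,
underscore = bottom-strand cut); per-allele fields (ref/alt tag, allele code,
allele sequence, cut flag, display context); and genotype classes with the
samples carrying each.

The same pipeline is available as library calls (`capsmine.mine`,
`capsmine.single_cut_filter`, …); see the module docstrings.

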