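# epilocus

Locus-scale epigenomic profiling for plant gene-silencing studies: clone-based
bisulfite methylation quantification by cytosine context, small-RNA locus
profiling with size-class-anchored normalization and bin-based siRNA-target
calling, and qPCR/ChIP-qPCR quantification — plus a synthetic-data generator
that plants recoverable ground truth so the whole pipeline is testable without
any sequencing download.

## Who this is for

Epialleles — alleles identical in sequence but differing in heritable
epigenetic state — are dissected by asking, region by region across a single
locus, (i) how DNA methylation in the CG, CHG and CHH contexts (H ∈ {A,C,T})
differs between genotypes, (ii) which regions are targeted by 24-nt
heterochromatic siRNAs (the guides of RNA-directed DNA methylation, RdDM) and
lose them when the siRNA pathway is mutated, and (iii) how transcript levels
and repressive chromatin marks (e.g. H3K9me2) respond. This package
implements that desk-side analysis for one locus at a time, at Sanger-clone
and small-RNA-library scale — the regime of classical locus studies such as
the maize *p1* gene with its transposon-fragment-laden enhancers and intronic
MITE, which the synthetic generator emulates.

## The computations

**Coordinates.** Everything is reported TSS-relative with no 0 coordinate:
the TSS is +1 and the base immediately upstream is −1.

**Bisulfite methylation.** Each clone of a bisulfite amplicon reads a
cytosine site as C (methylated) or T (unmethylated); anything else is
ambiguous and excluded. Per context,

percent = 100 · (methylated calls) / (methylated + unmethylated calls),

pooled over all clones of a plant. Plants (biological replicates) are the
statistical unit: genotypes are compared per context with a two-sided,
equal-variance Student's t-test on replicate percents, significant at
P ≤ 0.05, reported as mean ± SE. Incomplete conversion biases the estimate
upward predictably: with conversion rate c and true level p the expected
estimate is p + (1 − p)(1 − c).

**Small RNAs.** Reads are adapter-trimmed (insert = prefix before the
leftmost exact match of the adapter's first 8 nt; 18–30 nt kept), reads
matching structural RNAs (tRNA/rRNA/sn/snoRNA, either strand) are excluded,
and the rest are aligned to a single copy of the locus requiring perfect
matches, a multicopy gene being profiled as an aggregate through one
representative copy. Abundances are reads per million (RPM) over
locus-matched non-structural reads, optionally rescaled so all libraries
share a reference library's 22-nt abundance — necessary because an RdDM
mutant collapses the 24-nt class and thereby inflates every other class under
plain per-million scaling. Hits are counted once per hit in half-open 50-bp
bins on a TSS-label grid, and regions that lose 24-nt siRNAs in the mutant
are maximal runs of bins with wild-type abundance ≥ 5 and mutant/wild-type
ratio ≤ 0.2 (both configurable).

**qPCR / ChIP-qPCR.** Relative expression uses the Livak estimator
2^−ΔΔCt with technical replicates averaged on the Ct scale and an endogenous
control gene; ChIP enrichment uses percent-of-input,
100 · 2^((Ct_input − log2(1/f)) − Ct_IP) for input fraction f, with optional
no-antibody background subtraction before fold-enrichment ratios.

## Worked example

`examples/02_bisulfite_methylation.py` simulates two genotypes × two plants ×
20 clones over an intron-2 amplicon and prints:

```
region    context   wild-type %  mutant %        P  sig
Int2-1    CG               75.4      71.7   0.5603
Int2-1    CHG              52.8      50.5   0.6634
Int2-1    CHH              12.6      11.7   0.4188
Int2-2    CG               88.0      82.8   0.1503
Int2-2    CHG              78.2      49.3   0.0265  *
Int2-2    CHH              49.3      22.5   0.0011  *
```

The planted truth drops CHG/CHH methylation only in the Int2-2 sub-region of
the mutant; the t-test flags exactly those contrasts while CG and the
adjacent Int2-1 sub-region stay flat — the signature of an RdDM-maintained
sub-region abutting an RdDM-independent one.

`examples/03_srna_lost_regions.py` runs the small-RNA pipeline on a simulated
wild-type/mutant pair (100k reads each) and prints the lost-region table:

```
                feature  tss_start  tss_end  wt_abundance  mut_abundance  ratio
                Tourist      -1750    -1650       89681.0         1494.3    0.0
 proximal_enhancer,MULE       -400     -100      406531.6        12690.7    0.0
            intron2,hAT       3400     3550       30081.6            0.0    0.0
         intron2,Int2-2       4800     4900       15521.5            0.0    0.0
intron2,Int2-2,Stowaway       5000     5150      111470.0        12627.1    0.1
                  exon3       5300     5400        9933.2            0.0    0.0
```

Every flagged region coincides with a planted transposon-fragment siRNA
source whose 24-nt output is depleted or abolished in the mutant; the 21/22-nt
sources, unaffected by the mutation, are not flagged. The other two example
scripts cover locus construction and qPCR/ChIP quantification.

## Command-line pipeline

The same stages are exposed as a thin CLI for shell use:

```bash
epilocus simulate --seed 5 --out run/sim
epilocus methylation --locus run/sim/locus.fasta --features run/sim/features.bed \
    --tss 6001 --clones run/sim/clones --subset Int2-2:4778:5068 --out run/meth
epilocus srna --locus run/sim/locus.fasta --features run/sim/features.bed --tss 6001 \
    --structural run/sim/structural.fasta \
    --wt run/sim/srna/wildtype_rep1.fastq --wt run/sim/srna/wildtype_rep2.fastq \
    --mut run/sim/srna/mutant_rep1.fastq --mut run/sim/srna/mutant_rep2.fastq \
    --out run/srna
epilocus qpcr --ct-table run/sim/expression_ct.tsv --calibrator wildtype --out run/qpcr
epilocus report --methylation-dir run/meth --srna-dir run/srna --out run/report.txt
```

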