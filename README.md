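# hybridbracket

Tools for asking how far apart two species can be — genetically and
phenotypically — and still produce viable hybrids, and for testing whether a
putative hybrid specimen is the predictable intermediate of its parents.
The motivating system is the intergeneric cross between the grey seal
(*Halichoerus grypus*) and the ringed seal (*Pusa hispida*), whose uniquely
preserved hybrid cranium and dentition can be compared against both parent
species, but every analysis takes generic inputs and ships with a
synthetic-data generator so the whole stack runs without any restricted
specimen or sequencing data.

The package is aimed at population geneticists and morphologists working on
hybridization, and at palaeontologists who must judge from teeth and crania
alone whether a morphologically intermediate fossil could be a hybrid.

## What it computes

**Neutral genetic distance** (`hybridbracket.seqdist`). From per-gene codon
alignments: dicodon windows with more than one variable position are masked,
codons with missing data dropped, genes shorter than 100 clean columns
discarded, the rest concatenated, and third positions of codons that are
fourfold degenerate in every species extracted. Pairwise distances use the
Tamura (1992) correction

d = −2θ(1−θ) ln(1 − P/(2θ(1−θ)) − Q) − ½(1−2θ(1−θ)) ln(1−2Q),

with P and Q the transition and transversion proportions and θ the pairwise
GC content, plus distance ratios against a named reference pair.

**Introgression and admixture** (`hybridbracket.introgression`). Patterson's
D-statistic over four-taxon derived-allele frequencies,
D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA), with a weighted delete-one-block
jackknife (Busing-style, blocks weighted by their ABBA+BABA information)
giving SE and Z. A supervised maximum-likelihood estimator recovers the
ancestry fraction q of an individual from two parental allele-frequency
panels by maximising the binomial genotype likelihood with
m_j = q·a_j + (1−q)·b_j; an F1 hybrid estimates q ≈ 0.5.

**Dental statistics** (`hybridbracket.dental`). The top-cusp angle (at the
tallest cusp tip, between rays to the extreme flanking tips or crown-base
endpoints), cusp-number disparity Δ (mean over tooth positions P1–P5 of the
absolute between-species difference in cusp number, by mean and by mode),
and the hybrid intermediacy bracket: all cross-species pairwise averages of
specimen angles, the central 80% interval, and the hybrid's quantile within
them.

**Tooth development** (`hybridbracket.toothdev`). A reduced one-dimensional
enamel-knot patterning simulator in which inhibition strength (*Inh*),
epithelial growth rate (*Egr*) and anterior bias (*Abi*) control cusp
number, cusp pointedness and anteroposterior asymmetry; tooth rows arise
from constant per-tooth parameter changes, and hybridization is simulated by
combining parent parameters (average, 10% shift towards a parent, or direct
inheritance, independently per parameter — a grid of 27+2 combinations).

**Cranial morphometrics** (`hybridbracket.morpho`). Bilateral
symmetrization, generalized Procrustes analysis, shape PCA, permutation
tests on the Procrustes distance between group mean shapes (10,000 rounds by
default), multivariate quadratic regression of shape on centroid size, and
group geometric means.

**Synthetic data** (`hybridbracket.synthetic_data`) generates inputs for all
five stages with known ground truth, and `hybridbracket.pipeline` runs any
subset from a YAML configuration into a JSON + Markdown report.

## Worked example

Simulate a four-taxon site panel with 20% of loci introgressed, then test
for gene flow:

```sh
$ hybridbracket simulate sites --f 0.2 --eps 0.05 --beta 0.25 \
      --n-sites 100000 --seed 42 --out panel.tsv
wrote 100000 sites to panel.tsv (expected D = 0.2857)
$ hybridbracket dstat --panel panel.tsv --out d.json
D = 0.2865 +/- 0.0075 (Z = 38.38)
```

The generator's closed-form expectation is D = f(β−ε)/(2ε + f(β−ε)) =
0.2857; the estimate 0.2865 ± 0.0075 recovers it and the jackknife Z of 38
declares the gene flow highly significant (the null calibration keeps
|Z| < 3 when f = 0).

Simulate the packaged parent tooth rows:

```sh
$ hybridbracket toothdev row --out rows.tsv
```

gives per-position cusp counts and top-cusp angles — ringed-type teeth
(3,3,3,3,4) cusps at 116°→101° (subequal slender cusps), grey-type
(2,2,3,4,4) at 75°→91° (anterior teeth dominated by a central fang). The
all-average hybrid row falls between the two at every position, in both
cusp count and angle.

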