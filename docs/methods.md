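# Methods

This note records the models and procedures implemented by kinomekit, the
assumptions behind them, the defaults that matter, and what the synthetic
data generators do and do not emulate.

## Identification filter

The unit of evidence is one profile-model alignment on one protein — a row
of a HMMER3 `--domtblout` table. Two decisions are deliberate:

- The E-value cutoff (< 1.0, strict) is applied to the **per-domain
  independent E-value** (column 13), not the full-sequence E-value, because
  the coverage rule is also domain-level; mixing the two scales would let a
  strong full-sequence hit rescue a marginal domain.
- Model coverage is `(model_to − model_from + 1) / model_length` and the
  50% boundary is **inclusive** — a hit covering exactly half the model
  makes the protein a typical kinase.

Domain counting merges qualifying hits whose protein spans overlap by more
than 25% of the shorter span, keeping the higher bit score. This treats
overlapping hits from the two kinase profiles (serine/threonine- and
tyrosine-kinase models) as one catalytic domain, which is what a curator
would count. The threshold is configurable (`overlap_fraction`).

Isoform handling: only the longest peptide per gene is classified. The
gene↔isoform mapping is a regex with a named `gene` group (default:
everything before the last dot; a `VIT_*` preset ships for the grapevine
naming convention) or an explicit mapping table. Length ties break to the
lexicographically smallest protein id, so results never depend on input
order.

## Family assignment

Assignment is argmax over per-family model bit scores; ties break by lower
E-value, then family name. Bit score rather than E-value is the primary
statistic because bit scores are comparable across families with different
model lengths. A gene is `unclassified` when its best E-value is not below
the assignment threshold (default 1e−5), or — when the margin rule is
enabled — when its best-minus-second-best bit margin falls below a floor
while its best E-value exceeds a ceiling. The margin rule is the
operational stand-in for a phylogenetic cross-check: a gene with weak,
ambiguous model scores is exactly the gene that would fail to cluster with
any family in a tree, and forcing it into the argmax family would be false
precision.

Groups are aggregated from a family→group catalogue shipped as data
(`kinomekit/data/family_groups.tsv`, covering the 20 standard plant kinase
groups); families absent from the catalogue are resolved by longest-prefix
match against the group names, since families are conventionally named
`<group>_<family>`. Shares are percentages rounded to two decimals.

## Gene features

- Intron count is `len(exons) − 1` on the representative transcript. When
  a gene has several transcripts the representative is the transcript of
  the longest-isoform protein (consistency with the identification rule);
  without that information, the transcript with the greatest summed exon
  length.
- pI uses the Bjellqvist pKa set (the values behind the ExPASy Compute pI
  tool), with residue-specific N-terminal pKa values. The net charge is a
  strictly decreasing function of pH, so bisection on [0, 14] always
  converges; iteration stops when the residual charge is ≤ 1e−4, which
  puts the returned pH well within 1e−3 of the root for any realistic
  peptide. The pKa table is a plain dict and swappable.
- MW is the sum of average (not monoisotopic) residue masses plus one
  water, via Biopython's mass tables — the convention of the ExPASy tool.

## Tandem and segmental duplication

The tandem rule — two or more same-family kinase genes on one chromosome,
adjacent members separated by at most five genes (of any annotation) within
100 kb — is implemented with both thresholds inclusive and the distance
measured start-to-start between adjacent members. Because both the
intervening count and the distance are monotone in chromosomal order, the
connected components of pairwise links are exactly maximal runs of linked
consecutive same-family genes; the implementation exploits this, and the
test suite checks it against a brute-force all-pairs union-find oracle on
hundreds of random genomes. Restricting membership to same-family pairs
reflects how duplicate arrays are reported per family.

Segmental duplication detection is a self-contained collinearity chainer in
the MCScanX tradition: anchors (homologous gene pairs, supplied by the
user) are chained per chromosome pair by O(n²) dynamic programming,
requiring strictly monotone gene ordinals on both chromosomes (both
orientations tried) and per-step ordinal gaps ≤ 25; chains shorter than 5
anchors are discarded, and extraction repeats on the remaining anchors so
each anchor joins at most one block. The defaults mirror common
collinearity-scan settings and are configurable. This is deliberately a
simplified chainer: no e-value weighting of anchors and no overlapping
block resolution beyond anchor exclusivity.

## Ka/Ks and dating

Nei–Gojobori (1986) counting with equal weighting of pathways:

- Site counts: per codon position, the synonymous fraction is the number of
  single-nucleotide changes preserving the amino acid divided by the number
  of changes not creating a stop; s + n is renormalized to 3 per codon.
  Changes to stop codons are excluded from mutational opportunity — the
  standard convention, stated here because published descriptions are
  often silent about it.
- Differences: for codon pairs differing at 2–3 positions, synonymous and
  nonsynonymous step counts are averaged over all orderings of the
  differing positions whose intermediates are not stops; if every ordering
  passes through a stop (rare), the average is over all orderings so that
  sd + nd always equals the number of differing positions.
- Correction: Jukes–Cantor, K = −¾·ln(1 − 4/3·p), applied to ps = Sd/S and
  pn = Nd/N with S the mean of the two sequences' site totals. Proportions
  ≥ 3/4 are saturated: the rate is reported as undefined rather than
  extrapolated, and such pairs are flagged, not dated.
- Degenerate ratios: Ks = 0 with Ka > 0 is reported as +∞ (positive
  selection) rather than crashing on young duplicates; Ka = Ks = 0 leaves
  the ratio undefined.
- Selection modes: ratio < 1 purifying, = 1 neutral, > 1 positive, with an
  optional symmetric neutral band around 1.
- Dating: T = Ks/(2λ) in million years, λ = 6.5×10⁻⁹ per site per year by
  default (a grapevine synonymous-rate estimate); λ enters only as a scale.

Gap-containing and stop-containing codons are excluded pairwise before
counting. The estimator assumes no transition/transversion bias and uniform
rates across sites — the assumptions of the counting method itself — and
the codon-pair simulator makes the same assumptions (uniform proposals,
acceptance 1 : ω for synonymous : nonsynonymous), so parameter recovery
tests measure estimator correctness, not model misspecification.

## Expression analysis

Family profiles are arithmetic means over members present in the matrix,
computed per sample with missing values excluded cell-wise. The inclusion
rule — at least one third of family members represented — is evaluated with
exact rational arithmetic (`Fraction(present, total) >= 1/3`, boundary
inclusive), so 4 of 12 passes and 3 of 10 fails regardless of float
rounding.

Stress responses: log2 fold change of arm means on the linear scale, and a
two-sided two-sample t-test on log2 replicate values when both arms have
≥ 2 replicates. No multiple-testing correction is applied by default, in
keeping with the raw p < 0.05 convention of family-level survey analyses;
Benjamini–Hochberg is available behind a flag. Candidate genes must be
**induced** (up only) more than two-fold — both thresholds strict — in at
least three distinct conditions.

FPKM is `count / (exon_kb) / (library_size_in_millions)`. The ΔΔCt fold
change is 2^(−ΔΔCt) after reference-gene and control normalization; the
*geometric* mean fold over control samples is 1 by construction (the
arithmetic mean exceeds 1 whenever control ΔCt values vary).

## Coexpression network

One Pearson correlation per unordered pair of included family profiles;
p-values from t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom, two-sided.
Edges require p < α (strict, default 0.05, uncorrected by default); the
sign is the sign of r. When a sample→condition design is supplied, family
vectors are first averaged per condition, so correlations are taken across
treatments rather than across replicate structure; raw-sample correlation
is available by flag. Families with no significant partner are excluded
from the node count (a 56-family input can legitimately yield a 49-node
network). Constant profiles have undefined correlation and never form
edges.

## Synthetic data: what it does and does not emulate

The generators produce structurally faithful inputs — multi-isoform
proteomes with planted domains, GFF3 layouts with planted arrays (including
designed rule-violating negatives), codon pairs evolved at known ω,
expression matrices with planted family correlations and condition
effects — with a JSON truth sidecar for every dataset.

Deliberate simplifications: the planted "kinase domain" is a fixed sentinel
peptide plus a per-family signature token, so identification and
classification can be tested without a profile-HMM engine (real domtblout
input remains the supported path for real data); ancestral codon usage is
uniform and the substitution process has no transition/transversion bias
(matching the estimator's assumptions); gene layouts have no realistic
intergenic content, GC structure or nested genes; expression noise is
Gaussian on the log2 scale with a single shared family latent. Passing
tests on synthetic data therefore demonstrate the correctness of the
*computations* under their stated assumptions — not robustness to
real-data pathologies such as fragmented gene models, probe
cross-hybridization or heavy-tailed expression noise.

Default study conditions used by the test suite and the acceptance script:
200 simulated pairs of 2000 codons at 0.3 substitutions per codon for Ka/Ks
recovery (tolerances ±0.05 at ω = 0.2, ±0.10 at ω = 1.0); 200–500 random
genomes of ≤ 200 genes for tandem-oracle equivalence; 500–1000 null
replicates of 20 families × 12 samples for network calibration; planted
edges at r = 0.9 with n = 20 condition points for recall; 500–1000 random
peptides of 5–400 residues for pI convergence. These sizes give
Monte-Carlo error comfortably inside each stated tolerance.

## Known limitations

- The collinearity chainer scores blocks by anchor count only; MCScanX-like
  e-value-based block scoring is out of scope.
- NG86 saturates near Ks ≈ 3 after correction (ps → 3/4); deeply diverged
  pairs are flagged as saturated and not dated. Published tables sometimes
  report Ks values far beyond this range from other estimators; such values
  cannot be reproduced by NG86 and are intentionally not extrapolated.
- The identification contract is defined on the hit table; running the HMM
  search engine itself is external glue.
- Whole-genome self-comparison to produce homolog anchors is out of scope;
  anchors are an input.
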