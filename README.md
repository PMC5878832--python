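# kinomekit

A toolkit for genome-wide protein-kinase (kinome) analysis: identifying and
classifying kinase genes from a predicted proteome, characterizing their
gene structure and protein properties, detecting tandem and segmental
duplications, estimating selection pressure and divergence times on
duplicate pairs, aggregating expression at the family level, and building a
stress-response coexpression network. It is aimed at plant comparative
genomicists who want the standard kinome-survey pipeline as a reusable,
tested library rather than a collection of one-off scripts — and at anyone
who needs its individual pieces (NG86 Ka/Ks, tandem-array detection,
family-level coexpression) with known-answer tests behind them.

Every input format the pipeline consumes can also be *generated*, with
machine-readable ground truth, by `kinomekit.synthetic`: proteomes with
planted kinase domains, GFF3 gene layouts with planted tandem arrays and
collinear blocks, codon alignments evolved at known dN/dS, and expression
matrices with planted correlation structure and treatment effects. All
generators are deterministic given a seed.

## The methods in brief

- **Identification.** Proteins are screened with kinase-domain profile hits
  (HMMER3 `--domtblout` tables, Pkinase/Pkinase_Tyr-style models). After
  reducing each gene to its longest peptide, a gene is a *typical* kinase
  when some hit has per-domain E-value < 1.0 **and** covers ≥ 50% of the
  profile model; *atypical* when a hit passes the E-value cutoff but none
  reaches 50% coverage; *non-kinase* otherwise. Overlapping hits on one
  locus are merged, so catalytic domains — not raw hits — are counted.
- **Classification.** Each kinase takes the family with the maximal
  per-family model bit score (ties: lower E-value, then name); weak or
  ambiguous genes fall back to *unclassified*. Groups (RLK-Pelle, CMGC,
  CAMK, …) are rolled up from a family→group catalogue.
- **Gene features.** Intron count = exons − 1 on the representative
  transcript; pI by bisection on the Henderson–Hasselbalch net-charge
  function with the Bjellqvist pKa set; MW as the sum of average residue
  masses plus one water.
- **Duplications.** A tandem array is a run of ≥ 2 same-family kinase genes
  on one chromosome, adjacent members separated by ≤ 5 genes and ≤ 100 kb.
  Collinear (segmental) blocks are chained from homolog anchor pairs by
  dynamic programming with strictly monotone gene ordinals on both
  chromosomes.
- **Molecular evolution.** Nei–Gojobori (1986) counting with Jukes–Cantor
  correction: Ks = −¾·ln(1 − 4/3·ps) and likewise Ka; Ka/Ks < 1 purifying,
  = 1 neutral, > 1 positive; divergence time T = Ks/(2λ) with λ = 6.5×10⁻⁹
  synonymous substitutions per site per year by default.
- **Expression and network.** Family profiles are per-sample means over
  members present in the matrix, kept only when ≥ 1/3 of members are
  represented. Responses are log2 fold changes with two-sample t-tests;
  candidate genes are induced > 2-fold at p < 0.05 in ≥ 3 stresses. The
  coexpression network connects family pairs whose Pearson correlation is
  significant at p < 0.05, with signed edges.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Generate a synthetic proteome with 40 planted kinase genes among 100,
derive its domain-hit table, and run identification:

```python
from kinomekit import synthetic as syn

fasta, truth = syn.gen_proteome(100, 40, {1: 0.7, 2: 0.3}, seed=7)
open("proteome.fa", "w").write(fasta)
open("hits.domtblout", "w").write(syn.synthetic_hit_table(fasta))
```

```bash
kinomekit identify --hits hits.domtblout --proteins proteome.fa --out annotations.tsv
```

prints the summary

```
{"typical": 40, "atypical": 0, "non_kinase": 60, "multi_domain": {"1": 40}}
```

and writes a per-gene table:

```
gene_id  protein_id  status      n_domains  best_evalue  best_coverage
G0001    G0001.1     typical     1          1e-30        1.0
G0002    G0002.2     non_kinase  0
...
```

All 40 planted kinase genes are recovered as typical (single-domain)
kinases; the 60 background genes are non-kinase. Multi-isoform genes
(e.g. G0002) have been reduced to their longest peptide before
classification. The same flow continues through `kinomekit classify`,
`features`, `duplications`, `kaks` and `network`, or through the library
API (`kinomekit.duplication.estimate_ka_ks`, `kinomekit.network.build_network`,
…), which is what the CLI wraps.

As a library example, the divergence time of a duplicate pair with
Ks = 0.13 at the default rate is

```python
>>> from kinomekit.duplication import divergence_time
>>> divergence_time(0.13)
10.0   # million years ago
```

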