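# crisprpam

PAM discovery from CRISPR spacer content, plus Cas9-ortholog clustering and
phylogenetic grouping — a desk-scale, fully testable pipeline.

## The problem

Type II CRISPR-Cas systems cleave invading DNA only when a short
**protospacer adjacent motif (PAM)** sits immediately 3′ of the protospacer
on the non-target strand. Each Cas9 ortholog recognises its own PAM, so
anyone wanting to use an alternative Cas9 for genome editing first has to
infer that motif. The classic bioinformatic route is:

1. take the spacers of a species' CRISPR array,
2. find **protospacer candidates** — target sequences (phage, plasmid or
   genomic DNA) matching a spacer at ≥ 90 % identity on either strand,
3. extract the 10 nt immediately 3′ of each protospacer, read on the
   non-target strand,
4. stack the flanks into a position frequency matrix, score each position's
   information content IC = 2 − H (bits, H the Shannon entropy), and
5. call a degenerate IUPAC consensus (e.g. `NGG`, `NNNNACA`, `NNAGAAW`) —
   surfacing, rather than hiding, balanced positions such as an A/C split
   that reads `M`.

A companion analysis groups Cas9 orthologs: proteins shorter than 800 aa
are discarded, all pairs are aligned (BLOSUM62, affine gaps), and two
proteins are linked when the alignment covers ≥ 0.8 of both lengths **and**
its score coverage (bit score / alignment length) is ≥ 0.8; clusters are
connected components. A neighbor-joining tree on Poisson-corrected
distances over informative alignment columns, with column-bootstrap
supports, then checks whether each sequence cluster is monophyletic.

Because the original public-database searches are not reproducible at desk
scale, the package ships a first-class synthetic-corpus generator that
plants protospacers (at controlled divergence) and PAM realisations with a
ground-truth manifest, making every stage's recovery a measurable quantity.

## Worked example

```python
from crisprpam.synth import generate_corpus
from crisprpam import find_protospacers
from crisprpam.pam import extract_flank, profile_from_flanks

# a 9 kb target with 50 planted protospacers, true PAM NNNNACA, 2% noise
locus, genome, manifest = generate_corpus(
    seed=1, true_pam="NNNNACA", n_placements=50, mutation_rate=0.02)

hits = find_protospacers([locus], [genome])          # both strands, >=90% id
flanks = [f for f in (extract_flank(h, genome) for h in hits) if f]
profile = profile_from_flanks(flanks)
print(len(hits), profile.consensus, [round(float(x), 2) for x in profile.ic[:7]])
```

prints

```
50 NNNNACANNN [0.04, 0.1, 0.07, 0.03, 2.0, 1.86, 2.0]
```

All 50 planted protospacers are recovered; over the 10 nt flank the
consensus reads `NNNNACA` followed by three more uninformative positions,
with ~0 bits of information at the unconstrained positions and close to
the 2-bit maximum at the three constrained ones. The same objects are
available through the `crisprpam` CLI (`synth`, `search`, `pam`, `cluster`,
`tree`, `duplex`, `run` subcommands).

For the protein side:

```python
from crisprpam.synth import generate_protein_family
from crisprpam.pipeline import run_cluster_tree, PipelineConfig

records, labels = generate_protein_family(k_families=3, seed=5)
report = run_cluster_tree(records, config=PipelineConfig(bootstrap=30, seed=5))
print(report.clusters.n_clusters,
      [row["monophyletic"] for row in report.concordance])
```

prints `3 [True, True, True]` — the three families come back as three
clusters, each monophyletic in the bootstrapped NJ tree.

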