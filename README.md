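# t2pks

Genome mining for bacterial **type II polyketide synthase (PKS) gene
clusters** and prediction of the **aromatic polyketide chemotype** their
products belong to.

Type II PKSs are iteratively acting systems of small mono- and didomain
proteins (at most two domains per protein) that assemble aromatic
polyketides — angucyclines, anthracyclines, benzoisochromanequinones,
pentangular polyphenols, tetracenomycins, tetracyclines/aureolic acids —
from malonyl units. General-purpose domain databases often miss or
mislabel these proteins, so this package trains *per-subfamily*
classifiers from a labeled reference collection (11 classes — KS, CLF,
ACP, KR, ARO, CYC, KSIII, AL, AT, MCAT, TE — partitioned into 20
subfamilies) and uses them to mine genomes. It is aimed at natural-product
and biosynthesis researchers who have a genome (GenBank or protein FASTA)
and want to know whether it encodes a type II PKS system and what kind of
aromatic polyketide it is likely to make.

## Method

1. **Subfamily clustering.** Each PKS class of the reference set is
   partitioned by single-linkage clustering of a Smith–Waterman
   similarity graph (sequences linked when percent identity and
   alignment coverage both clear thresholds, transitively). The
   thresholds are calibrated by grid scan against the known 20-subfamily
   partition.
2. **Domain classifiers.** For every subfamily with ≥ 5 members, two
   classifiers are trained: a profile HMM (HMMER) with a gathering-style
   bit-score threshold, and an RBF-kernel SVM whose feature vector is
   the query's normalized Smith–Waterman score against the subfamily's
   member panel, with C and r grid-searched to maximize the
   cross-validated product SN × SP. Performance is measured by repeated
   cross-validation (4-fold when n ≥ 20, leave-one-out otherwise,
   10 repeats) as sensitivity, specificity, accuracy and Matthews
   correlation coefficient:
   SN = TP/(TP+FN), SP = TN/(TN+FP), AC = (TP+TN)/N,
   MCC = (TP·TN − FN·FP) / √((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
   Subfamilies with < 5 members fall back to best-homolog assignment.
3. **Cluster detection.** Genes carrying a domain call are chained along
   the genome: two hit genes join one candidate cluster when fewer than
   15,000 bp (strictly) separate their gene bodies, transitively. A
   cluster is *valid* — able in principle to produce an aromatic
   polyketide — iff it contains both a KS and a CLF call (the minimal
   condensing pair).
4. **Chemotype prediction.** The ARO/CYC subfamily combination of a
   valid cluster is looked up in an embedded table of 11 known
   combinations: a combination unique to one chemotype assigns it
   directly; a combination shared by two chemotypes (Ant ↔ Tet/Aur and
   Pen ↔ Tcm) is resolved by majority vote over the chemotype labels of
   the cluster's ARO/CYC reference homologs; anything else is
   Unclassified.

Every stage is testable offline: the `t2pks.synthetic` module generates
reference sets with the exact curated subfamily structure (308 domains
on 280 proteins) and genomes with clusters planted at known coordinates.

## Worked example

Mine a synthetic genome with a planted angucycline-type cluster:

```python
from t2pks.synthetic import make_reference_set, standard_planted_suite
from t2pks.classifiers import ModelBank
from t2pks.mining import mine_genome
from t2pks.chemotype import load_rule_table
from t2pks.taxonomy import genome_summary

refset = make_reference_set(seed=1)
bank = ModelBank.train(refset.domains, seed=1, with_svm=False)
rt = load_rule_table()
spec, genome, truth = standard_planted_suite(refset, rt, seed=7)[0]

result = mine_genome(genome, bank, rule_table=rt, reference=refset.domains)
for cluster in result.clusters:
    calls = [f"{c.subfamily_key[0]} {c.subfamily_key[1]}"
             for _, cl in cluster.genes for c in cl]
    print(f"{cluster.cluster_id}: span={cluster.span} valid={cluster.valid}")
    print(f"  domains: {calls}")
    print(f"  chemotype: {cluster.chemotype.chemotype} via {cluster.chemotype.rule_path}")
print(genome_summary([result]).to_string(index=False))
```

prints

```
SYN0001.cluster1: span=(152710, 164531) valid=True
  domains: ['KS a', 'CLF a', 'ACP a', 'ARO b', 'ARO a', 'CYC a']
  chemotype: Angucyclines via unique_match
accession          organism  size_bp  n_type2_pks  Ang  Ant  Ben  Pen  Tcm  Tet/Aur  Unc
  SYN0001 Syntheticus rule1   318240            5    1    0    0    0    0        0    0
```

One cluster was found spanning 152,710–164,531 bp. It is valid (it has
the KS+CLF pair), contains five PKS proteins carrying six domain calls
(one protein is a didomain aromatase, called as both ARO a and ARO b),
and its ARO/CYC signature {ARO a, ARO b, CYC a} matches the unique
angucycline combination, so the cluster is typed Ang. The summary row is
the per-genome report: genome size, PKS protein count in valid clusters,
and the chemotype tally.

The same pipeline runs from the shell: `t2pks fixtures`, `t2pks
load-ref`, `t2pks cluster`, `t2pks train`, `t2pks evaluate`, `t2pks
mine`, `t2pks report` (see `--help` on each).

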