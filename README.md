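# ohnolog

Inference of polyploidization history from ohnolog genealogies, synonymous
divergence, and MUL-tree reconciliation.

## The problem

Whole-genome duplication (WGD, polyploidization) leaves each gene of a
tetraploid with two copies — *ohnologs*.  Given coding sequences and gene
trees for hundreds of orthologous families across a set of closely related
polyploid species (plus diploid relatives and an outgroup), three questions
define the lineage's history:

1. **Independent or shared?**  Did each species double its genome on its own
   after speciation (independent polyploidization, IP), or did a single WGD
   in the common ancestor precede the splits (shared polyploidization, SP)?
2. **When?**  How old is each WGD?
3. **Auto- or allopolyploidy?**  Did the genome double within one lineage,
   or did two lineages hybridize and then double?

This package answers all three from the same inputs, and ships a calibrated
simulator so every stage can be validated against known ground truth.

## The method

* **Topology classification.** For two tetraploids A and B, an ohnolog
  quartet (A₁, A₂, B₁, B₂) has 15 rooted binary labelled topologies, which
  collapse to six species-labelled classes T1–T6.  Classes where a species'
  two copies group together (T1–T3) evidence IP; classes where copies pair
  across species (T4–T6) evidence SP.  Per species pair the classes are
  tallied across families and a decision is made on the IP–SP majority.
  Triplets of tetraploids are classified by the analogous 6-leaf predicates.
* **Ks dating.** Pairwise synonymous divergence between ohnologs is
  estimated with the Nei–Gojobori (1986) method (pathway-averaged counts,
  Jukes–Cantor correction).  The peak of the Gaussian-kernel Ks density per
  species converts to a divergence time via the molecular clock
  **T = Ks / 2r**, with r = 3.51 × 10⁻⁹ synonymous substitutions per site
  per year (Cyprinidae rate) by default.
* **Ordering against speciation.** The ohnolog divergence time T_Ks is
  compared with the matrilineal (mitochondrial) divergence time T_mt and its
  95% interval: T_Ks below the interval ⇒ WGD postdates speciation
  (independent); above ⇒ WGD predates speciation (shared).
* **MUL-tree reconciliation.** Each gene tree carrying both copies is
  reconciled (duplication + loss parsimony, LCA mapping) against the
  singly-labelled species tree and against every multi-labelled (MUL) tree
  formed by attaching a second copy of the polyploid subtree to an edge.
  Second copy on the polyploid's own edge ⇒ autopolyploidy; on another
  lineage ⇒ allopolyploidy with that donor.  The minimum-score hypothesis
  wins.  An ortholog-Ks asymmetry test (Wilcoxon signed-rank on the two
  copies' Ks to a diploid ortholog) provides an independent check on the
  allopolyploidy signal.
* **Synthesis.** Pairwise decisions are merged transitively: species
  connected by "shared" calls form one event; the event table reports
  sharing, mode, dates, and whether the evidence streams agree.

## Worked example

Simulate two tetraploid species "PA" and "PB" that split 9.02 Mya and then
doubled their genomes independently at 0.93 and 1.45 Mya (200 families,
5% gene-tree noise), and fit the model:

```python
import ohnolog as oh

scenario = oh.canonical_scenarios(n_families=200)["independent-auto"]
model = oh.PolyploidyHistory.from_simulation(scenario, seed=7)
results = model.fit()
print(results.summary())
```

```
==============================================================================
                      Polyploidization history inference
==============================================================================
families: 200   masked (gene conversion): 0   polyploid species: 2
------------------------------------------------------------------------------
Ohnolog genealogy tallies (per species pair)
pair               n     IP%     SP%  ambig  decision
PA-PB            166  100.00    0.00      0  independent
------------------------------------------------------------------------------
Ohnolog Ks peaks and divergence dating (T = Ks/2r)
species          n     Ks peak  T_Ks (Mya)
PA             179      0.0060        0.85
PB             187      0.0100        1.43
------------------------------------------------------------------------------
Ortholog-Ks asymmetry (larger vs smaller copy, Wilcoxon)
  PA           n=179   medians 0.0846/0.0830  p=5.87e-31
  PB           n=187   medians 0.0848/0.0821  p=4.17e-32
------------------------------------------------------------------------------
MUL-tree reconciliation (winner per unit)
  PA                 auto: H1=PA, H2=PA                       score 0 (margin 179)
  PB                 auto: H1=PB, H2=PB                       score 0 (margin 187)
------------------------------------------------------------------------------
Inferred polyploidization events: 2
  WGD[PA] independent/auto (T_Ks PA: 0.85 Mya)
  WGD[PB] independent/auto (T_Ks PB: 1.43 Mya)
==============================================================================
```

Reading the output: all 166 classifiable families show IP-type quartets, so
the two species doubled independently; the Ks peaks (0.0060, 0.0100) date
the two WGDs to 0.85 and 1.43 Mya — close to the simulated 0.93 and
1.45 Mya — and both MUL-tree searches place the second subgenome on the
species' own lineage (autopolyploidy), reconciling 0 events for the best
hypothesis.  The asymmetry line uses the deliberately liberal
larger-vs-smaller grouping (significant by construction); the informative
part is the near-identical group medians (0.0846 vs 0.0830), i.e. no
subgenome-level rate asymmetry, consistent with autopolyploidy.

The same pipeline runs from the shell:

```bash
ohnolog all --scenario independent-auto --out run/ --seed 7
# stage-by-stage: ohnolog simulate / families / ks / classify / reconcile / infer
```

Each stage writes its artifacts (tally tables, Ks densities, reconciliation
scores, the event table) plus a manifest with the seed and configuration
hash, so runs are exactly reproducible.

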