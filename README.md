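# tcmchromatin

Materia-medica-wide analysis linking traditional-medicine annotations of
medicinals (the seven-grade cold-hot *nature* and the yin/yang *flavors*)
to their predicted modulation of 18 histone/DNA modifications and of
chromatin state.

Traditional Chinese medicine annotates every medicinal with a cold-hot
nature and a set of flavors, and prescribes multi-medicinal formulas
against syndromes. This package asks, on structured synthetic data with
known ground truth, the chain of questions a chemo-epigenetic reading of
those annotations raises:

1. **Are the annotations phylogenetically coherent?** Scores are tested
   for autocorrelation on the medicinals' phylogeny with Moran's *I*,
   I = (N/Σwᵢⱼ)·Σwᵢⱼ(yᵢ−Ȳ)(yⱼ−Ȳ)/Σ(yᵢ−Ȳ)², with weights wᵢⱼ = 1/dᵢⱼ
   from cophenetic distances (analytic randomization or permutation P).
2. **Which medicinals touch the epigenome?** Each medicinal's chemicals
   are mapped through a chemical–protein interaction table onto 18
   modification attributes (DNMT, HAT, HDAC, site-specific histone
   (de)methylation, (de)phosphorylation, ATP-dependent remodeling); the
   potency for attribute X is the count of chemical–enzyme pairs, and the
   net of heterochromatic vs euchromatic marks labels the medicinal
   condensing, unpacking or poising.
3. **Do scores predict chromatin direction?** Pearson screen of all 18
   potencies against cold-hot / yin-yang scores at α = 0.05.
4. **Do formulas act coherently?** A formula profile is the sum of member
   profiles; a resampling test compares its heterochromatinization shift
   |Δ| against size- and median-matched random control formulas.

Everything runs on seeded synthetic bundles (tree, annotated catalog,
chemistry, interactions, formulas) generated by the package itself, with
plantable phylogenetic signal, score–potency associations and formula
homophily — so every stage is testable offline, including null
calibration and power. See `docs/methods.md` for models and conventions.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic bundle and write their tables under `results/`:

```sh
python analysis/01_generate_data.py
python analysis/02_score_and_phylo.py
python analysis/03_profile_medicinals.py
python analysis/04_cluster_profiles.py
python analysis/05_formula_synergy.py
```

Output of the sequence (seed 1):

```
nature_only : I=+0.1452  E[I]=-0.0054  p=7.54e-18  n=187
full        : I=+0.1230  E[I]=-0.0054  p=2.1e-13   n=187
flavor_only : I=+0.0263  E[I]=-0.0050  p=0.0571    n=200

histone-modifying: 87/200 (44%)
  condensing 71%  unpacking 17%  poising 11%
significant score-potency correlations (alpha = 0.05):
  H3K9    nature_only  r=-0.487 p=2.63e-06 n=84
  ...

histone-modifying formulas: 31/50
  all: median|D| real=0.000 control=0.167 p(two-sided)=4.62e-05 synergy=yes
```

Reading: the Brownian-evolved cold-hot trait clusters strongly on the
tree (I far above its null expectation −1/(n−1)); the planted
cold-enriched H3K9 association is recovered as a significant negative
correlation (colder medicinals carry more H3K9-methylation pairs, a
condensing mark); and real formulas shift their heterochromatinization
far less than random control formulas — members of a formula pull in the
same chromatin direction.

The same pipeline is scriptable through the CLI
(`tcmchromatin generate|score|phylo|profile|cluster|formulas|run`), e.g.

```sh
tcmchromatin generate --seed 3 --out bundle/
tcmchromatin phylo --medicinals bundle/medicinals.tsv \
    --tree bundle/tree.nwk --out moran.json
```

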