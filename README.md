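# metmap

Methylation inference from **MethylSeq** — sequencing of size-selected
HpaII restriction fragments — with explicit correction of the assay's
fragment size-selection bias.

HpaII cuts `CCGG` only when the internal CG is unmethylated, so sequencing
the ends of the resulting fragments reveals unmethylated sites. But the
read depth at a site depends as much on its *neighbors* as on the site
itself: a fragment is only sequenced if both of its bounding sites were
cut, none of its interior sites were, and its length survived the gel
size selection (50–300 bp by default). A fully unmethylated site flanked
by other unmethylated sites closer than the minimum fragment length can
therefore receive *zero* reads. `metmap` is for anyone analyzing
methylation-sensitive restriction digest sequencing who needs per-site
methylation estimates rather than raw, bias-confounded read counts.

## The model

A discrete Bayesian network is built per genomic region from the reference
sequence and the mapped read counts:

* every HpaII CG is a hidden variable over six states — methylation
  *m* ∈ {U, P, M} (unmethylated, partially/heterogeneously methylated,
  methylated) crossed with island status ∈ {I, O} (inside/outside an
  *unmethylated island*);
* every other CG is a hidden two-state island variable;
* consecutive CG variables are chained by distance-dependent transitions
  `N(d) ∝ (T·D)^(d−1)·T·E`, where `T` is a per-base two-state island chain
  (entry 3.1434·10⁻⁴, exit 2.57·10⁻², per base) and `D`, `E` condition on
  observing no CG for `d−1` bases and then a CG (CG start probability
  0.10178 inside islands, 0.01298 outside);
* methylation depends on island status: P(U,P,M | I) = (0.7231, 0.05,
  0.2269) and P(U,P,M | O) = (0.1413, 0.05, 0.8087);
* every candidate fragment (any pair of HpaII sites within the size
  window) is an **observed** variable: its read count, capped into ten
  states by a dataset-specific value `k_max`, depends on the methylation
  of its two ends and up to three interior sites through the per-allele
  production rate ρ = c(m_L)·c(m_R)·∏(1−c(m_q)) with cut probabilities
  c(U,P,M) = (1, ½, 0), binned into five equivalence classes.

Exact posteriors are computed by two-pass message passing on the clique
chain induced by eliminating variables in genomic order. Each site's
**score** is p(U) + ½·p(P) — the inferred fraction of unmethylated alleles
(the prior score outside islands is 0.1663). **SUMIs** (strongly
unmethylated islands) are annotated as the union of island-probability
runs (p(island) > 0.1) and 600 bp windows around confidently unmethylated
non-island sites, each requiring direct support from ≥ 2 sequenced
fragments, and scored by the mean site score.

The package also includes a full MethylSeq simulator (island-structured
genomes, heterogeneous epiallele methylomes, in-silico digestion, size
selection, Poisson read sampling), assay span/scope calculators (including
an RRBS-style adjacent-fragment mode), a Gardiner–Garden sequence-only
CpG-island caller, and bisulfite-validation utilities.

## Worked example

```sh
python examples/score_simulated_experiment.py
```

```
652 CCGG sites in scope at 30x (k_max = 41.0)
pos      truth_u  model_score  raw_score
5030     0.26     0.131        0.000
5131     0.00     0.153        0.000
...
Pearson(model score, true u) = 0.531
Pearson(capped raw count, true u) = 0.513
```

Each row is a CCGG site in the scope of the simulated experiment: the
planted unmethylated-allele fraction (`truth_u`), the model's posterior
score, and the naive normalized read count. The correlations summarize the
bias correction: the model's scores track the planted truth better than
capped raw counts do. `examples/annotate_unmethylated_islands.py` shows
SUMI calling on realistic island geometry (base-level Jaccard ≈ 0.75
against planted islands at 30×), and `examples/bisulfite_validation.py`
the five-point bisulfite scale and its tolerance-window adjustment.

The same functionality is available from the shell:

```sh
metmap simulate --length 2000000 --depth 30 --seed 1 --out-dir sim
metmap score --genome sim/genome.fa --alignments sim/alignments.sam \
             --k-max 41 --out-dir scored
metmap span --genome sim/genome.fa --method rrbs
```

## Layout

* `src/metmap/genome.py` — CG/CCGG scanning, fragment enumeration, scope,
  span, CpG-island calling
* `src/metmap/counts.py` — read filtering, end assignment, `k_max`, count
  capping
* `src/metmap/model.py` — the graphical model and exact inference
* `src/metmap/sumi.py` — unmethylated-region annotation and comparison
* `src/metmap/simulate.py` — the MethylSeq simulator
* `src/metmap/evaluate.py` — bisulfite scoring and correlation utilities
* `src/metmap/pipeline.py`, `src/metmap/cli.py` — orchestration and the
  `metmap` command

See `docs/methods.md` for the modeling assumptions, parameter defaults,
and known limitations.
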