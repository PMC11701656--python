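# coupnet

Bin-free naive-Bayes inference of functional association networks.

Two genes or proteins are *functionally coupled* when they act in a common
process — the same complex, pathway or regulatory program — whether or not
they touch physically. No single omics assay measures this reliably, so
`coupnet` integrates heterogeneous evidence (domain interactions, genetic
interactions, ChIP-seq regulator-target signals, mRNA and protein
co-expression, shared microRNA or transcription-factor regulators,
phylogenetic profiles, literature-supported physical interactions,
co-localization) against curated *gold standards* (complexes, metabolic and
signaling pathways, operons, physical interactions, TF→target pairs) into
one calibrated network per species, with optional cross-species evidence
and network transfer through orthologs.

## The model

For each evidence dataset and gold standard, raw scores `x` are converted
to a log-likelihood ratio without binning:

    LLR(x) = ln  P(x | coupled) / P(x | not coupled)

The two class densities are estimated by Gaussian-kernel KDE with
Silverman's bandwidth `0.9 min(sd, IQR/1.34) n^(-1/5)`, the pointwise
log-ratio is fitted with the lowest-degree polynomial (degree 2–4)
reaching R² ≥ 0.9 on a grid truncated at the 98th score percentile, and
training requires 10³–10⁶ gold-standard observations. Per gene pair, LLRs
from multiple datasets of one evidence type are ranked decreasingly and
summed with sequential redundancy weights `w₁ = 1`,
`w_k = α (1 − max(0, r_{k,k−1})) w_{k−1}` (α = 0.7, `r` the Spearman
correlation between the datasets' LLRs), and the *final Bayesian score*
is the naive-Bayes sum over evidence types and source species:

    FBS(A,B) = Σ_t LLR_t(A,B)

Confidence is calibrated by measuring the positive predictive value
PPV = TP/(TP+FP) over 1000 FBS thresholds on equal-sized positive and
resampled negative examples (30 resamples) and fitting the logistic
`PPV(x) = a / (1 + exp(−b(x − c)))` (accepted at R² ≥ 0.9). The final
network is the union over gold standards at maximum PPV; links in one /
two / three / more than three gold standards carry a floor confidence
(gsPPV) of 0.85 / 0.90 / 0.95 / 1.0 unless the evidence PPV exceeds it;
only links with PPV ≥ 0.85 are kept, and a positive directed GRG
(ChIP-seq) contribution orients a link regulator → target.

The package also provides the surrounding toolbox: gold-standard
construction rules, the ten evidence scoring metrics, orthology-based
evidence and whole-network transfer with NJ/UPGMA species trees,
group/independent/MaxLink network search, EASE pathway enrichment, and a
random-walk-with-restart benchmark with degree-preserving null networks
(performance gain). A synthetic-data module generates worlds with planted
couplings so every stage is testable against known ground truth.

## Worked example

```python
from coupnet import (FunctionalCouplingModel, TrainingConfig,
                     generate_world, generate_evidence, generate_gold_standard)

world = generate_world(100, 0.3, seed=11)          # 4950 pairs, 1485 coupled
tables = [generate_evidence(world, dataset_id="coexpr", evidence_type="MEX"),
          generate_evidence(world, dataset_id="ppi", evidence_type="PIN")]
gs = generate_gold_standard(world, recall=0.9, fpr=0.02, name="Complex", seed=12)
results = FunctionalCouplingModel(tables, [gs], TrainingConfig(min_n=500)).fit(seed=13)
print(results.summary())
```

prints

```
Functional coupling network inference
============================================================
Evidence tables: 2
Gold standards:  1
Seed:            13

LLR training (per gold standard)
------------------------------------------------------------
  Complex      accepted=2   rejected=0   pairs=4950
    MEX/coexpr         degree=2 R2=0.996 n_pos=1407
    PIN/ppi            degree=2 R2=0.996 n_pos=1407

PPV calibration
------------------------------------------------------------
  Complex      a=1.200 b=0.299 c=-1.613 R2=0.965

Assembled network: 1568 links (0 directed), 100 proteins, PPV >= 0.85
```

Both evidence tables train a quadratic LLR curve at R² ≈ 0.996 from 1407
gold-standard positives; the logistic calibration reaches R² ≈ 0.97; the
assembled network keeps the 1568 pairs whose confidence is at least 0.85,
of which 1377 are planted true couplings (88% precision against the
ground truth, versus a 30% base rate).

A CLI mirrors the library for shell use:

```bash
coupnet simulate --n-proteins 100 --coupling-fraction 0.3 --seed 11 --outdir fixtures/
coupnet build --evidence fixtures/evidence_sim0.tsv \
              --gold-standard fixtures/gold_standard.tsv \
              --seed 11 --out network.tsv
coupnet search --network network.tsv --genes P00001,P00007 --mode group --n 5
coupnet benchmark --network network.tsv --genes P00001,P00007,P00011 --seed 1
```

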