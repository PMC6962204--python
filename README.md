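# fucotype

Classification of **core vs. outer fucosylation** of N-glycopeptides from
CID tandem mass spectra.

Fucose can be attached to an N-glycan either on the innermost GlcNAc of the
trimannosyl core (alpha-1,6, "core" fucosylation, FUT8) or on the antennae
(alpha-1,3/4 Lewis-type, "outer" fucosylation). The two isoforms have
different biology — core fucosylation underlies biomarkers such as AFP-L3,
outer fucosylation marks inflammation and several cancers — but they are
isobaric, so an identified glycopeptide composition such as
`VCQDCPLLAPLNDTR_5_4_1_2` (peptide + Hex/HexNAc/Fuc/Sia counts) does not by
itself say where the fucose sits.

CID fragmentation does: a core fucose stays on the peptide and shows up in
peptide-bearing **Y ions** (Y1F...Y4F paired with Y1...Y4), while an outer
fucose travels with the glycan-only oxonium **B ions** (B2F at m/z 512.2,
B3SF at m/z 803.3, paired with B2 at 366.1 and B3S at 657.2). `fucotype`
turns each glycopeptide-spectrum match (GSM) into a 14-dimensional vector
of relative intensities of these diagnostic ions

```
B2, B2F, B3, B3F, B3S, B3SF, Y1, Y1F, Y2, Y2F, Y3, Y3F, Y4, Y4F
```

(peaks matched at ±0.02 Da with S/N ≥ 3, normalised to the spectrum base
peak) and trains two probabilistic 4-class classifiers — a fully connected
ReLU network with softmax output and a linear-kernel soft-margin model with
pairwise probability calibration — to label each GSM as **none / core /
outer / dual**.

Model selection and filtering use a target–decoy scheme. For class
probabilities `P1 ≥ P2 ≥ ...` each prediction gets a confidence score

```
Pscore = −ln(1 − (P1 − P2))
```

Decoy GSMs are made by randomly permuting the 14 intensities within each
vector (five replicates, averaged). Candidate models from the
hyperparameter grids (1,200 network candidates: nodes {8,16,32,64,128} ×
hidden layers {3,4,5} × epochs {10...20,000} × 10 replicates; 1,040 margin
candidates: 52 staged cost values × 20 seeds) are ranked by the Euclidean
length `EL = sqrt(accuracy² + AUC²)`, where the AUC is the target-vs-decoy
ROC area of the Pscore. Classified GSMs are filtered at a decoy-estimated
FDR (default < 1%), and the two families are combined by a consensus rule:
a GSM keeps its class only if both models agree and it passes the filter in
at least one of them.

A synthetic-spectrum generator (`fucotype.synthetic`) emulates the
class-dependent diagnostic-ion pairing with realistic intensity noise, so
the whole pipeline — feature extraction, training, decoy FDR, consensus —
is testable without any external data, against a rule-based oracle
classifier that encodes the pairing logic directly.

## Worked example

Simulate labelled data, train a reduced grid, classify an "unknown" set:

```sh
fucotype simulate --n-per-class 50 --seed 1 --mgf train.mgf --gsm train.tsv --source train
fucotype simulate --n-per-class 50 --seed 2 --mgf test.mgf  --gsm test.tsv  --source test
# concatenate the two TSVs into gsms.tsv, then:
cat > config.json <<'JSON'
{"network_nodes": [64], "network_layers": [4], "network_epochs": [2000],
 "network_replicates": 1, "margin_costs": [1.0, 8.7], "margin_seeds": [435],
 "seed": 1}
JSON
fucotype train --mgf train.mgf --mgf test.mgf --gsm gsms.tsv --config config.json --out models
```

which prints the per-family winners selected by Euclidean length:

```json
{
  "network": {"accuracy": 1.0, "auc": 0.996925, "euclidean_length": 1.41204,
              "pscore_cutoff": 6.5148, "n_filtered": 195,
              "spec": {"n_nodes": 64, "n_layers": 4, "epochs": 2000, ...}},
  "margin":  {"accuracy": 1.0, "auc": 0.9893, "euclidean_length": 1.40667,
              "pscore_cutoff": 1.9562, "n_filtered": 193,
              "spec": {"cost": 1.0, "seed": 435, "kernel": "linear"}}
}
```

Both models label every test GSM correctly; target Pscores separate from
shuffled decoys with AUC ≈ 0.99, and 195 of the 200 test GSMs pass the 1%
FDR Pscore cutoff for the network model. Classifying a fresh set and
scoring it against its hidden labels:

```sh
fucotype simulate --n-per-class 50 --seed 3 --mgf unknown.mgf --gsm unknown.tsv --source plasma
fucotype classify --mgf unknown.mgf --gsm unknown.tsv \
    --bundle models/model_bundle.joblib --config config.json --out cls
# classified 200 GSMs (200 consensus) -> cls/classification.tsv
fucotype evaluate --results cls/classification.tsv --labels unknown.tsv
# {"accuracy": 1.0, "sensitivity": 1.0, "n_consensus": 200, "n_total": 200, ...}
```

`cls/classification.tsv` lists, per GSM, both models' classes and Pscores,
the FDR-pass flags, the consensus class and the antennarity group of the
composition, so class-by-antennarity summaries (core enriched in mono/bi
and hybrid glycans, outer in tri/tetra-antennary) can be read directly
from the output.

The same workflow runs from Python via `fucotype.pipeline.run_train` /
`run_classify` / `run_evaluate`, or at the array level via
`train_network`, `train_margin`, `pscores`, `make_decoys`, `fdr_cutoff`
and `consensus`.

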