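# qpisa

Quantitative Protease specificity Inference from Substrate Analysis:
infer an exopeptidase's cooperative cleavage motif from quantified
peptide mixtures.

## The problem

Dipeptidyl peptidases such as human DPP4 clip two residues off the
N-terminus of peptide substrates — including the incretin GLP-1, which
makes DPP4 a central drug target in type-2 diabetes. Classical profiling
approaches enrich and detect cleavage *products*, which yields a binary
substrate/non-substrate call but little quantitative insight. qPISA
instead quantifies the *substrates*: a trypsin-digested lysate is split
into enzyme-treated and buffer-control samples, peptides are quantified
in both (e.g., by TMT multiplexing), and the depletion of each tryptic
peptide measures how efficiently the enzyme cleaves it. Because tens of
thousands of diverse peptides are quantified at once, the data support a
model that resolves not only which residues matter at each subsite but
also how *pairs* of positions cooperate.

## The model

Peptide positions follow Schechter–Berger nomenclature: the scissile
bond lies between P1 and P1', so for a dipeptidyl peptidase the
peptide's first two residues occupy P2 and P1. For each peptide the
cleavage-oriented log2 fold change

Δ = mean log2(buffer) − mean log2(enzyme)   (substrates; positive = cleaved)

is modeled by ordinary least squares as a function of the N-terminal
residue identities. Each position enters as a categorical predictor via
treatment coding (20 residues → 19 dummy variables); subsite
cooperativity enters as pairwise interaction terms (products of dummy
pairs). A suite of twelve models of increasing complexity — each single
position P2…P4', linear combinations, and the three-position model with
P2:P1', P2:P1, and/or P1:P1' interactions — is ranked by adjusted R², so
models with different parameter counts compare fairly.

The final model (P2, P1, P1' main effects + P2:P1 and P1:P1'
interactions) is rearranged into three lookup tables whose sum scores
any triplet:

score(P2, P1, P1') = term1[P1] + term2[P2, P1] + term3[P1, P1']

where term1 absorbs the intercept and all centering shifts, and term2 /
term3 are zero-mean over their first index within each P1 — the exact
numbers drawn as per-P1 sequence-logo panels. A product-based variant
fits the same machinery on accumulated semi-tryptic peptides against a
background of unchanged tryptic peptides, and a synthetic-experiment
generator with a known ground-truth motif makes the entire pipeline
testable end to end.

## Worked example

Simulate a small experiment with the built-in DPP4-like ground truth,
run the full pipeline, and score three GLP-1-derived peptides:

```sh
qpisa simulate --config gen.yaml --seed 3 --out sim
# simulated 2877 substrates and 1036 products into sim
qpisa run --config run.yaml
# pipeline complete: 12 models, 2877 substrate records; outputs in out
qpisa score --params out/rearranged_params.json --peptides peps.txt --out scores.tsv
```

`out/model_suite.tsv` holds the twelve-model comparison; on this run the
P1-only model reaches adjusted R² 0.825, the linear three-position model
0.855, and the final interaction model 0.932 — the single position P1
dominates, and cooperativity adds the rest, the signature this method
exists to expose. The scores:

```
sequence      score   zero_support
HAEGTFTSDVSR  2.33    False
DAEGTFTSDVSR  1.40    False
HAPGTFTSDVSR  -0.36   False
```

HAE… (the native GLP-1 N-terminus, Ala at P1) scores as an excellent
substrate; swapping P2 His→Asp (DAE…) markedly reduces the predicted
cleavage; placing Pro at P1' (HAP…) abolishes it — the triplet ordering
built into the generating motif and recovered by the fit. Other pipeline
outputs include the classification table, the rearranged 820-entry
parameter table (JSON + TSV), numeric logo heights (with optional SVG
rendering), a coverage audit of the 8000-triplet / 1200-residue-pair
spaces, the product-based model, and a manifest recording every filter
count and setting.

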