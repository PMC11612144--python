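# Methods

## Peptide classification

Peptides are located in the protein database by exhaustive substring
search; on multi-mapping, the first hit (database order, then position)
is used, and `ambiguous_flank` is set when the hits disagree on the
preceding residue — such peptides are excluded from modeling, since
their N-terminal context is undefined. A mapped peptide is *tryptic*
when (i) it starts downstream of K/R and ends with K/R, (ii) it starts
downstream of K/R and ends at the protein C-terminus, or (iii) it ends
with K/R and starts at the protein N-terminus; everything else is
*semi-tryptic*, the signature of an exopeptidase product. By default a
start at position 2 behind an initiator Met also counts as the protein
N-terminus (standard proteogenomics allowance; toggleable), since rule
(iii) is otherwise blind to Met-trimmed proteins. Coordinates are
1-based closed intervals throughout. Peptides containing letters outside
the 20-residue alphabet (B, J, O, U, X, Z) are excluded from modeling
with a logged count: the model's categorical space is the 20 amino
acids. I and L are distinct letters; no equivalence folding.

## Preprocessing

Raw intensities are log2-transformed and each sample column is
median-centered. Missing values are imputed MinProb-style: draws from
N(μ, σ) with μ the 0.01 quantile of all observed values and σ = 0.3 ×
the median per-peptide standard deviation, fully seeded. These two
hyperparameters are configurable; the defaults are the package's own
choice of a clearly left-censored, narrow imputation distribution.
Rows are then filtered: mean log2 intensity below the configured
threshold (default −4.7, *inclusive keep* at the boundary — the
comparison direction must be pinned for reproducibility), unmapped
peptides, and ambiguous flanks. Redundant modification forms of the same
sequence collapse to the most abundant form (ties: lexicographically
smallest form id).

Δ is computed once per peptide by averaging replicates within condition
and differencing; substrate orientation is buffer − enzyme (depletion
positive), product orientation the negation (accumulation positive), so
"positive = cleavage" holds for both model variants and their parameters
are directly comparable. Peptides shorter than 6 residues are dropped
before any model so all twelve models see the identical record set and
their adjusted R² values are comparable.

## The linear-model suite

Treatment coding uses reference residue "A" (alphabetical default;
predictions are provably invariant to this choice on full-rank designs,
and the reference is recorded in model metadata). Design columns never
realized by a record are dropped before fitting and reported; their
coefficients are 0 in all outputs. Fits are unweighted OLS via
`numpy.linalg.lstsq`; rank-deficient designs fall back to the
minimum-norm solution with a warning. Rank deficiency is not an edge
case here but a structural feature of tryptic data: internal K/R
depletion means P1 ∈ {K, R} occurs essentially only before Pro, which
makes the K/R main-effect columns collinear with their interaction
columns. Training fitted values remain unique; only extrapolation to
never-observed combinations is affected.

Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) with p the count of
retained predictor columns excluding the intercept. Reported "variance
explained" percentages are 100 × adjusted R² of the stated model;
"gains" are differences of adjusted R² in percentage points.

## Rearrangement into motif tables

With ŷ(b, a, c) the final model's prediction over all 20³ triplets
(dropped levels contributing 0):

- term1(a) = mean over b, c of ŷ
- term2(b, a) = mean over c of ŷ − term1(a)
- term3(a, c) = mean over b of ŷ − term1(a)

Averaging is uniform over the 20 residues — *unweighted* means keep the
parameters independent of the training data's residue composition
(observed-frequency weighting was considered and rejected for exactly
that reason). Because the model has no P2:P1' term, the three terms
reproduce ŷ exactly on every triplet, and term2/term3 are zero-mean over
their first index within each P1 column. Entries never observed in
training are emitted with a zero support count; logos grey them out
rather than omit them, since triplet coverage is inherently incomplete.
Model comparisons (differential logos, replicate agreement) are Pearson
correlations over the concatenated 820 entries, restricted to entries
supported in both sets.

Logo rendering is optional matplotlib output (scaled glyph outlines,
positives above the axis, magnitudes sorted toward the axis); the
normative artifact is the numeric height table.

## Product-based variant

Foreground: semi-tryptic records with accumulation Δ ≥ 1 log2 unit,
N-terminally extended by the cleavage offset (2) so their hexamers align
with substrate coordinates; records too close to the protein N-terminus
to extend are dropped and counted. Background: tryptic records with
depletion < 1 log2 unit (increases of any size are allowed in, reading
the stability criterion literally; configurable), response pinned to 0.
The background carries the proteome's residue-composition skew, the K/R
depletion of the digest, and the instrument's detection bias — without
it those biases would masquerade as specificity. No capping or weighting
of foreground versus background is applied. An extended foreground
sequence coincides with the substrate it came from; the records stay
distinct and provenance-labeled.

## Synthetic experiments

The generator emulates the study design end to end. Proteins are i.i.d.
residues from a human-like frequency table (L 9.9%, W 1.2%); in-silico
trypsin cleaves after K/R (not before Pro by default, 0 missed cleavages
by default). The ground-truth motif has the same three-table shape as
the rearranged parameters; the built-in DPP4-like default puts strong
positive weight on Pro/Ala (moderate on Ser/Thr) at P1, a P1'-Pro
penalty large enough to neutralize any favorable P1, P1-dependent
acidic-residue penalties at P2, and mild hydrophobic preferences at P1'.

Turnover modes:

- **linear** — true depletion Δ* = max(s, 0) for true score s. The
  truncation reflects that an enzyme cannot *increase* substrate: true
  scores ≤ 0 all produce zero depletion and are therefore
  unidentifiable from substrate data. Recovery comparisons consequently
  restrict to observed triplets with positive true score.
- **kinetic** — first-order turnover: cleaved fraction
  f = 1 − exp(−k0·2^s·t), Δ* = −log2(1 − f), and the product gains
  exactly the substrate's linear-scale loss (mass conservation holds to
  1e-9 in noiseless runs; f = 0.5 gives Δ* = 1 exactly). Scores map to
  rates multiplicatively (k = k0·2^s) because scores live on the log2
  scale; this yields the expected anticorrelation between scores and
  half-lives ln2/k.

Buffer channels sit at a peptide's log2 baseline (N(0, 1.5)), enzyme
channels at baseline − Δ*; three replicates per condition receive
i.i.d. Gaussian noise (default sd 0.3 log2 units). Products start from a
small pre-existing background (pseudocount 2⁻⁴) so their buffer
intensity is finite on the log scale. Left-censored dropout removes
cells below the 1% quantile of all generated values — deliberately
mild, as isobaric-label quantification within a plex has little
missingness. Defaults (~900 proteins × ~450 residues → >20,000
modelable substrates) were chosen once as a realistic mid-size
experiment and are used unchanged by the test suite and the acceptance
script.

What the generator does *not* emulate: peptide-dependent ionization
efficiency, retention time and charge effects, PTM heterogeneity,
isotopic impurity, or secondary-structure effects on cleavage. Passing
recovery tests therefore demonstrates the correctness of the inference
machinery under the stated statistical model, not robustness to every
bias of real MS data.

## Identifiability and recovery metrics

Per-sample median centering makes model scores identifiable only up to
an additive constant whenever a sizable fraction of peptides deplete
(the enzyme columns' medians shift). This affects real data exactly as
it affects the simulation; it is why motif heights are read *relative to
average cleavage*. Recovery against ground truth therefore reports the
Pearson correlation (shift-invariant) over observed positive-truth
triplets, and the RMSE after removing the single global offset,
restricted to triplets with ≥ 10 detection events.

## Known limitations

- Three-way and longer-range interactions are out of scope; the data
  volumes needed to constrain them are far beyond current coverage.
- Scores are relative (see above); absolute cleavage rates require the
  kinetic link plus a calibration the method does not provide.
- The minimum-norm fallback makes extrapolated predictions for
  structurally unidentifiable combinations (e.g., most P1 = K/R
  contexts) arbitrary within the null space; such entries carry low or
  zero support and should be read accordingly.
- The half-life validation is correlational; no kinetic model of the
  validation peptides is fit.
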