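# Methods

This note documents the models implemented in `varfit`, the defaults and
their rationale, what the synthetic-data generators do and do not
emulate, and the numerical choices a maintainer would want spelled out.

## Evolutionary features

All evolutionary features are computed from a multiple sequence alignment
whose first row is the query. The state space has 21 symbols — the 20
standard amino acids plus the gap. Nonstandard residue codes (B, Z, X, U,
O, ...) canonicalize to the gap state rather than being dropped, so the
alignment depth and the column register are preserved. A3M input has its
lowercase insertion columns removed: every feature is defined per query
position, and insertion states carry no per-position signal.

**Regularized frequencies.** With raw counts `c_i(a)` per column and
`c(a)` over the whole alignment, depth `m` and length `N`:

```
f_i(a) = c_i(a)/m · (1−θ) + θ/21
f(a)   = c(a)/(m·N) · (1−θ) + θ/21
```

The pseudocount θ defaults to 0.01. The gap is counted as the 21st state,
so every column's 21 frequencies sum to one and every frequency is at
least θ/21.

**Conservation Index.** `CI(i) = sqrt(Σ_a (f_i(a) − f(a))²)` with the sum
over the 20 standard amino acids only. Counting gaps in the frequencies
but excluding the gap term from the sum is intentional: the gap is a
legitimate state of the alignment ensemble but not a residue whose
enrichment should register as conservation.

**Log-odds ratio.** `LOR = logit f_i(mt) − logit f_i(wt)` with natural
logarithms (the base is a free convention; the fitted coefficient absorbs
it). θ > 0 is required — with θ = 0 an unobserved residue makes the logit
degenerate and the operation raises.

**PROVEAN-style score.** For every homolog row that is not gapped at the
variant column, the per-homolog delta is `s(mt, h) − s(wt, h)` under
BLOSUM62; PVS is their unweighted mean. This deliberately reuses the
MSA's pairwise alignments instead of realigning per variant, and it drops
the original PROVEAN's homolog clustering: the simplification is isolated
behind this one operation so a richer weighting can be swapped in. When
no homolog covers the column the score is 0 with a `defined=False` flag —
never a silent zero mixed in with real zeros.

## Coevolution (Potts model)

The Potts model assigns each aligned sequence the energy
`E(s) = −Σ_i h_i(s_i) − Σ_{i<j} J_ij(s_i, s_j)` over q = 21 states; gaps
are ordinary states, as is standard for alignments that contain them.

**Inference.** Sequences are reweighted by the reciprocal of the number
of rows within 80% identity (default threshold). Each column's
conditional likelihood is maximized independently (asymmetric
pseudo-likelihood) with L-BFGS from a zero initialization; the data term
is normalized by the effective depth so the regularization strength is
independent of alignment size. Defaults: λ_h = 0.01 and
λ_J = 0.01·(N−1), the plmDCA-style scaling that keeps the per-pair
penalty constant as the number of potential partners grows. The two
estimates of each coupling block are averaged, and the model is reported
in the zero-sum gauge (fields and every coupling block sum to zero over
states; sum tolerance 1e-6 in the class invariant). Zero initialization
plus a fixed gradient tolerance (1e-5) makes inference deterministic; an
optimizer failure raises with diagnostics rather than returning a
half-converged model.

**Variant score.** `PYF = E(wt) − E(mut)`, so a substitution the model
disfavors scores negative ("fitness loss" orientation). The single-site
change is evaluated incrementally in O(N). PYF is the raw energy change —
no internal mapping to fitness units is applied; the linear model's α₈
provides the scale. Gauge freedom cannot leak into PYF: energy
differences are gauge-invariant, and tests verify this to 1e-8 under
random reparameterizations. A column covered by no homolog yields
PYF = 0 with a flag.

`fit_potts_plm` accepts a reduced state count `q` so that synthetic
models over small alphabets can be re-inferred in their own state space
and compared coupling-by-coupling in a common gauge.

## Structural features

**Parsing.** PDB text only (mmCIF is a documented extension point).
Hydrogens and waters are stripped; altloc groups resolve to the highest
occupancy (ties to the record appearing first). Malformed coordinate
fields are reported with their line number.

**Accessibility.** Shrake–Rupley quadrature (probe 1.4 Å, 960 points per
atom by default, ProtOr united-atom radii) via biotite, summed per
residue. All chains present occlude each other: multimeric context is
part of the feature even though results are reported per chain. At the
default quadrature the isolated-sphere and two-sphere closed forms are
reproduced well within 0.5%; per-residue values on toy peptides are
within ~2% of a refined-quadrature answer, which is far below the
feature's biological variability.

**RSA.** `RSA(%) = 100 · ASA / maxASA(residue type)` with the bundled
extended Gly-X-Gly reference (Miller et al. 1987 values; the table is a
CSV resource and fully overridable). Values above 100% can occur and are
*not* clamped in the feature — clamping would inject a hidden
nonlinearity into a linear model; clamp only in reports.

**Chain-to-query mapping.** The chain's observed residues are globally
aligned to the query with a mismatch penalty chosen to stay cheaper than
gapping around a disagreement on both sides — otherwise true sequence
conflicts would hide as unmapped positions. Only exact matches anchor the
map; author numbering never leaks into query coordinates. Under 50%
mappable query means the wrong chain or structure and raises.

## The linear model

The eight features enter on their native scales; no standardization is
applied to the fit (standardized weights appear only in diagnostics).
OLS is the default; a rank-deficient design raises and recommends the
ridge variant (tiny L2 on the eight weights, never the intercept). Fit
diagnostics include per-coefficient standard errors and the ratio of the
blocks' standardized weights `Σ|α_j|·sd_j` (evolutionary over
structural) — on the synthetic training conditions this ratio is about 3,
which is the design regime: evolutionary terms carry most of the signal,
structural terms still improve deleterious-variant detection and remain
meaningful where the MSA is shallow.

The raw score is never clamped. Only the auxiliary single-feature PoP
model clamps: `−ReLU(−ReLU(γ₁PoP+γ₂)+1)+1`, algebraically the clamp of
the affine map to [0, 1] (equivalence is asserted to 1e-12 in tests). The
auxiliary SNP model is the plain affine rescaling β₁·SNP + β₂.

**Missing features.** Assembly never imputes; absence is recorded in a
mask. Imputation is explicit and per-protein: each feature's missing
entries take the median of its present values in the same table. A
feature absent *everywhere* cannot be median-imputed from the table; at
prediction time the fall-back is the training-set median stored inside
the coefficients file, with every such cell flagged. When a whole block
is globally imputed its scores are constant, the corresponding z-score
carries no information, and the prediction pipeline reports it as 0 with
a warning instead of failing the run (the strict `zscores` operation
itself still raises on constant input).

**Z-scores.** μ and σ are taken over the complete single-site landscape
(19 substitutions × L positions) with the *population* standard
deviation — the landscape is the whole population, not a sample. Scoring
only a subset changes the meaning of the z-scores, so subset use warns.
RSA and the intercept belong to neither block, exactly as the
decomposition is defined; the identity
`STR + EVO + α₁RSA + α₉ = score` holds to 1e-10.

## Evaluation

Kendall is the tie-corrected tau-b (deep-mutagenesis data is heavy in
ties); Spearman uses mid-ranks; RMSD is on native scales. Filter
boundaries are strict as worded: experimental fitness *above* the
hyper-complementing cutoff (default 1.36) is removed, standard error
*exceeding* 0.3 is removed, values exactly at either boundary are kept;
negative fitness floors to zero. Filters log what they removed and are
idempotent. Classification is oriented by the fitness convention — a
score *below* the threshold calls pathogenic; predictors with the
opposite polarity are ingested with a polarity flag that negates their
column. AUC-ROC uses the Mann–Whitney rank formulation (ties count one
half), which tests verify equals trapezoidal ROC integration.

## Synthetic data: what it does and does not show

Generators are deterministic functions of an integer seed; each public
function builds its own `numpy` Generator at entry, and bundle
generation derives child seeds via `SeedSequence`, so adding one
generator call never shifts another's stream.

* Profile MSAs have independent columns (Dirichlet concentration 0.5 by
  default — moderately peaked profiles; gap fraction 5%); the query row
  is drawn last and gap-free. There is **no phylogenetic correlation**
  between rows: conservation and DCA tests run under exchangeable
  sequences, so passing them does not demonstrate robustness to the
  phylogenetic redundancy of real alignments (the reweighting step
  exists for exactly that, and is tested on constructed duplicates).
* Potts MSAs are sampled by **full enumeration** of the Boltzmann
  distribution whenever q^N ≤ 10⁶ — the sampler is an oracle, not an
  approximation. The Gibbs mode (500 burn-in sweeps, thinning 10) exists
  for larger sizes and is labelled approximate; no ground-truth test
  depends on its mixing.
* Toy structures are schematic: ideal CA traces (3.8 Å spacing; helix
  rise 1.5 Å at 100°/residue) with N/C/O/CB placed by a local frame, and
  residues carry no side chain beyond CB. Accessibility tests therefore
  probe the geometry code and occlusion logic, not the absolute ASA of
  real side chains.
* Synthetic training tables draw features independently from realistic
  per-feature ranges with generating coefficients chosen so the
  standardized evolutionary block weighs ≈3× the structural one —
  the study conditions for the recovery tests (n = 2000, noise sd 0.1).
  Real feature collinearity (e.g. PoP with MAE) is not emulated except
  in dedicated rank-deficiency fixtures.

Problem sizes in the acceptance script: 200 oracle instances per
formula family, 200 recovery replicates at n = 2000, 5000 exact Potts
samples at N = 3/q = 3, and a 10-residue end-to-end landscape — sizes at
which every ground truth is exact and the whole run completes in well
under a minute of nothing but CPU arithmetic.

## Known limitations

* The in-house PROVEAN variant (no clustering, unweighted mean, BLOSUM62)
  is an explicit interpretation; original-PROVEAN scores will differ.
* RSA values depend on the radius set and the reference table; faithful
  numerical reproduction of any specific third-party RSA program is not
  claimed.
* Coefficients shipped by a run are always the product of this package's
  own training pipeline on the data given to it; no published
  coefficient set is bundled or imitated.
* The prediction CSV contract (last four columns: score, Z, Z_evo,
  Z_str) mirrors the layout common to online variant-scoring services;
  exact third-party header strings are not reproduced.
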