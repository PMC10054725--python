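# Methods

## Endpoint and scope

The modelled endpoint is the dietary biomagnification factor of organic
chemicals in fish, lipid-normalized on both sides of the trophic transfer
and expressed in log10 units:

    BMF_L = BMF · L_diet / L_fish,      endpoint = log10 BMF_L

with BMF the steady-state predator/diet concentration ratio and L_* lipid
fractions (kg lipid / kg wet weight). The alternative 5%-lipid
standardization BMF_5% = (BMF / L_fish) · 0.05 is provided for unit
conversion but is not the modelled quantity. A chemical is classed as a
biomagnifier when BMF_L > 1, i.e. Log BMF_L strictly greater than 0; the
boundary value 0 is classed as non-biomagnifier.

The package models laboratory-derived dietary BMF_L only; field-derived
BMFs (which include respiratory uptake) and octanol–water partitioning
estimates are out of scope by design.

## Data model and curation

Records carry a CAS number, a SMILES string, a data-quality category
(high/medium/low — taken as given input labels, never re-derived) and the
Log BMF_L value. Curation, applied row by row on load:

* parse SMILES with aromaticity perception; stereo descriptors are
  stripped (all descriptors are 2D and stereoisomer-specific records are
  not modelled);
* keep the largest covalently connected component (salt removal); ties are
  broken by molecular weight, then by lexicographically smallest canonical
  SMILES;
* normalize nitro groups to the single charge-separated form
  [N+](=O)[O−];
* canonicalize (RDKit canonical SMILES — deterministic and
  permutation-invariant, verified by property tests).

Unparsable rows are excluded and logged with a reason; duplicate CAS
numbers resolving to different structures are excluded as conflicts rather
than silently merged; identical structures under different CAS numbers
draw a warning (an offline surrogate for an identifier-resolution check —
no web lookup is performed). CAS checksum validation is advisory
(warning), not fatal. Replicate measurements of one structure are
averaged arithmetically on the log scale; the merged record keeps the best
contributing quality label, a choice made here because mixed-quality
replicates have no canonical label.

## Descriptors

All descriptors are computed on the hydrogen-suppressed heavy-atom graph,
with attached-hydrogen counts available to atom typing. This matches
mainstream 2D-descriptor practice; the convention, along with every choice
below, is recorded in `bmfqsar.PROVENANCE` and in the provenance attribute
of every descriptor matrix.

**Atom properties.** Atomic masses (standard atomic weights) and first
ionization potentials (eV, NIST values) ship as a versioned JSON table
covering H, B, C, N, O, F, Na, Mg, Al, Si, P, S, Cl, K, Ca, Zn, As, Se,
Br, Sn, I, Hg. Autocorrelation weights are used raw (not referenced to
carbon); a carbon-referenced variant can be obtained by rescaling the
weights, which leaves the Moran and Geary forms unchanged (affine
invariance, property-tested).

**Autocorrelations.** With d_ij the topological distance, w the property
values, w̄ their mean, n the atom count, and Δ the number of unordered
pairs at distance = lag:

* ATS  = Σ_{d=lag} w_i w_j, AATS = ATS/Δ (Broto–Moreau);
* MATS = [Σ_{d=lag}(w_i−w̄)(w_j−w̄)/Δ] / [Σ_i(w_i−w̄)²/n] (Moran);
* GATS = [Σ_{d=lag}(w_i−w_j)²/(2Δ)] / [Σ_i(w_i−w̄)²/(n−1)] (Geary).

Degenerate cases return 0 with a logged warning: Δ = 0 (no pair at the
lag) for all flavors, and zero property variance for MATS/GATS (tested
with a relative threshold, since identical weights can leave rounding dust
in the variance). This convention keeps matrix assembly total.

**BCUTw-1l.** Smallest eigenvalue of the Burden matrix: atomic masses on
the diagonal; bonded pairs 0.1·(conventional bond order) with aromatic
bonds 0.15 and bonds to terminal (degree-1) atoms incremented by 0.01; all
non-bonded pairs 0.001. These off-diagonal conventions follow the
canonical Burden formulation and are centralized so another dialect can be
swapped in.

**C3SP2.** Count of carbons that participate in a double or aromatic bond
and have exactly three carbon neighbours (ring-fusion carbons of PAHs,
branched sp² centres).

**GGI5 (Galvez topological charge index, order 5).** With A the adjacency
matrix and Q_ij = 1/d_ij² (zero diagonal), M = A·Q and
GGI_k = Σ_{i<j, d_ij=k} |M_ij − M_ji|; zero when no pair sits at distance k.

**PubChem-style keys.** Bit 38: ≥ 2 chlorine atoms. Bit 257: the SSSR
ring set contains ≥ 2 aromatic rings. Bit 503: chlorine on an aromatic
carbon whose aromatic neighbour bears a hydrogen (SMARTS
`Cl-[c]:[c;!H0]`). Bit 738: the published complex-SMARTS key
`Cc1cc(Cl)ccc1` (benzene with carbon substituent and chlorine in meta),
implemented as `[#6]c1cc(Cl)ccc1` since the reference matcher treats the
carbon atom generically.

**SubFPC295.** Count of bonds of any order joining carbon to O, N or S.

**R_TpiPCTPC.** Over all simple paths of length 0–10 on the heavy-atom
graph (a length-0 path is a single atom with empty product 1): total
conventional bond order (product of bond orders along each path, aromatic
= 1.5) divided by the total path count. Path enumeration is budget-guarded
(2·10⁶ DFS expansions by default); a molecule exceeding the budget fails
that cell explicitly instead of stalling the matrix.

**MLFER_S.** An estimate of the Abraham dipolarity/polarizability S by a
fragment-contribution scheme: intercept + Σ (unique SMARTS-fragment
matches × coefficient). The shipped table
(`data/mlfer_s_fragments_synthetic.json`) follows the group-contribution
form of the published fragment schemes for S but carries package-local
(synthetic) coefficient values over 18 fragment classes; it is versioned,
and its provenance travels with every matrix. Absolute MLFER_S values are
therefore internally consistent but not interchangeable with other
software's — the relevant limitation for reusing the frozen equations on
externally computed descriptors.

**maxHother.** Maximum hydrogen E-state over hydrogens on aromatic CH
(aaCH), =CH₂ (dCH2) and =CH– (dsCH) carbons; 0 when no such hydrogen
exists. The hydrogen E-state implemented here is a Kier–Hall-style
formulation: each heavy atom gets a hydrogen intrinsic state
I_H = (δᵛ − δ + 1)/δ, with δᵛ = valence electrons − attached hydrogens and
δ = heavy-atom degree, and the E-state of a qualifying hydrogen on atom i
is I_H(i) + Σ_j (I_H(i) − I_H(j))/(d_ij + 1)² over all other heavy atoms —
the usual inverse-square topological perturbation. The exact variant used
by legacy descriptor software is not published; this formulation is
documented, symmetric under graph automorphisms and oracle-tested.

**VE3_Dt.** From the detour matrix (longest simple-path lengths between
atom pairs; equal to the distance matrix on acyclic graphs, which is used
as a shortcut): take the unit-norm eigenvector of the largest eigenvalue,
VE1 = Σ|v_i|, and return ln(0.1·n·VE1). Cyclic graphs use exhaustive DFS
with a step budget; the exponential worst case is accepted because model
chemicals are small.

**nBondsS3.** Single non-aromatic bonds between heavy atoms.

**Pre-reduction.** Columns with one value occupying ≥ 95% of rows are
dropped as near-constant; remaining column pairs are scanned in fixed
(sorted) name order and the later-named member of any pair with
|Pearson r| > 0.98 is dropped. The name-order tie-break is this package's
rule — which member of a correlated pair survives is otherwise arbitrary —
and every drop is reported with its reason.

## Frozen models

Four MLR equations ship verbatim at printed precision (coefficients and
standard errors are never re-derived to extra digits): eq1 (split model,
115 training chemicals, high/medium-quality data) and its full-data
recalibration eq2 (152); eq3 (split model, 194, extended dataset including
screened low-quality data) and its recalibration eq4 (258). eq1/eq2 use
{AATS5i, BCUTw-1l, PubchemFP257, C3SP2, MATS1i, GATS5m, GGI5}; eq3/eq4 use
{PubchemFP503, SubFPC295, R_TpiPCTPC, MLFER_S, maxHother, GGI5, VE3_Dt}.
Prediction is exactly linear; serialization round-trips bit-exactly.

## Splitting, fitting, validation

**Split.** Records are sorted by increasing response; every record whose
1-based sorted position is a multiple of the stride goes to the prediction
set, except the global minimum and maximum, which always stay in training.
The default stride is 4: the source text describes a one-in-three rule,
but only one-in-four reproduces both published split counts (115/37 of 152
and 194/64 of 258), so the printed counts were taken as authoritative and
the stride left configurable.

**OLS.** Ordinary least squares with an intercept, returning coefficients,
standard errors, residuals, the hat diagonal and s = √(RSS/(n−p′)), where
p′ counts the variables plus one. Rank-deficient designs raise an error
naming the collinear columns (via pivoted QR). The implementation is plain
linear algebra and is cross-checked against statsmodels in the test suite.

**Statistics.** R², RMSE and MAE use their standard definitions (R²
against the mean of y). Q²(LOO) = 1 − PRESS/TSS with PRESS through the hat
identity Σ(e_i/(1−h_i))² — verified against brute-force n-refit PRESS to
10⁻¹⁰ relative. Q²(LMO) leaves 30% out over 1000 seeded iterations by
default (the named statistic has no canonical parameters; these follow
common QSAR-suite practice and are configurable), averaging
1 − PRESS_out/TSS_out with TSS_out taken against the retained-set mean.
Q²-F3 = 1 − [SSE_ext/n_ext]/[TSS_train/n_train]. Lin's CCC uses population
moments (divide by n); it never exceeds |Pearson r| in magnitude.

**k-fold cross-validation.** Folds are venetian blinds over
response-sorted records (sorted rank mod k), a deterministic assignment
chosen because no rule is prescribed; a seeded random assignment is
available. Each round re-selects a fresh descriptor subset by GA on the
retained folds, fits OLS and measures RMSE/MAE on the held-out fold;
selection frequencies across folds are reported. With k = n and a fixed
subset this reduces exactly to leave-one-out (property-tested).

## Applicability domain

Structural domain membership is by leverage: h_q = x_qᵀ(XᵀX)⁻¹x_q with the
intercept column included and X the training design of the model's
descriptors; the cutoff is h* = 3p′/n (0.209 for a 7-descriptor model with
115 training chemicals; 0.1237 at 194). Standardized residuals use the
training-fit s for query points as well, so external data plot on the same
Williams axes. Both thresholds are strict inequalities: boundary points
are in-domain / non-outliers. |standardized residual| > 2.5 flags a
response outlier; the > 3 tier is additionally reported (as
`strong_outlier`) but only 2.5 drives categorization.

The low-quality consistency screen applies a trained model to externally
measured data and categorizes each record, mutually exclusively and
exhaustively: `outside_AD_unreliable` (h > h*; no judgement on the value
is possible), else `inconsistent_in_AD` (|std residual| > 2.5), else
`consistent_in_AD`. Consistent in-domain records are the ones eligible for
pooling into an extended training set.

## Variable selection and model workflow

All-subset search evaluates every subset up to a requested size, guarded
by a subset-count budget beyond which it refers the caller to the GA. The
GA operates on fixed-size descriptor subsets with tournament selection
(size 3), uniform crossover (child genes drawn without replacement from
the union of the parents), per-gene mutation to a random unused
descriptor, and elitism (2). Defaults are population 100, generations 500,
mutation 0.2, all configurable and logged; fitness defaults to Q²(LOO) of
the OLS fit (R² and Q²(LMO) selectable). Rank-deficient subsets score −∞
and die out. Runs are fully seeded and reproducible; a preloaded optimum
is never lost under elitism (property-tested). Smaller seeded
configurations (population 60–100, generations 80–200, mutation 0.05) are
used in the test suite and acceptance script; the lower mutation rate
converges faster on the 50-descriptor pools exercised there.

Recurrent-outlier detection fits the top-k candidate subsets and flags
records that are response outliers (> 2.5 s) or high-leverage in a
majority of them, with per-model evidence — supporting the workflow of
removing recurrent outliers once and refitting. Recalibration refits a
chosen model's descriptor set on pooled training + prediction data,
keeping the subset and re-estimating coefficients and standard errors
(the split-model → full-model step).

## Synthetic fixtures

The generator emulates the composition of dietary-BMF datasets —
polychlorinated biphenyls (0–8 Cl over the ten substitutable positions),
halogenated/substituted benzenes, fused PAHs, and small heteroatom chains
(ethers, amines, thioethers, esters, chlorinated tails) — interleaved so
even small libraries mix all families. Molecules carry synthetic CAS
numbers (valid checksums) and seeded quality labels (roughly 40/30/30).
A linear response is planted on the computed descriptors:
y = intercept + Σ c_j (x_j − x̄_j) + N(0, noise_sd), with the default
planted subset (GATS5m, MATS1i, GGI5, SubFPC295, PubchemFP738, maxHother,
nBondsS3) chosen to be mutually well-conditioned on the template library
(pairwise |r| ≲ 0.7), coefficients auto-scaled so each descriptor
contributes ~0.6 response standard deviations, intercept −1.5 and noise
0.4 — placing responses and residual scatter at the magnitudes typical of
measured Log BMF_L data (roughly −4.5 to 1, residual ≈ 0.4 log units).
Gaussian decoy columns pad the descriptor pool to 50 so subset selection
faces a realistic search space.

What the fixtures do **not** emulate: real biology (no
biotransformation, no trophic structure), real descriptor–activity
relationships (the planted model is linear by construction), and real
measurement error structure (noise is homoscedastic Gaussian). Passing
tests therefore demonstrate that the statistical machinery is correct and
well-conditioned, not that the frozen equations are accurate for any
particular chemical class.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline at 200
molecules × 50 descriptors with 7 planted descriptors and 0.4 noise
(recovery checks: ≥ 6/7 descriptors, coefficients within 3 SE, Q²(LOO)
within 0.05 of R²), with smaller 60–150-record studies for unit-level
checks — sizes chosen to match the published datasets' order of magnitude
while keeping the whole suite fast. Leave-one-out identities are checked
to 10⁻¹⁰ relative; descriptor oracles to 10⁻⁹ absolute. All randomness
flows through numpy Generators seeded from a single integer.

## Known limitations

* MLFER_S uses a synthetic fragment table (above); predictions of eq3/eq4
  are internally consistent but not bit-compatible with descriptor values
  from other engines, and the same caveat applies in lesser degree to any
  convention-sensitive descriptor (autocorrelation weighting, Burden
  off-diagonals, hydrogen E-state variant).
* Detour-matrix and path descriptors are exponential in the worst case and
  budget-guarded rather than approximated; very large fused ring systems
  can fail those cells explicitly.
* The consistency screen inherits the frozen model's domain: chemicals far
  outside it (e.g. siloxanes for the high-quality-data model) are labelled
  unreliable rather than judged.
* No y-scrambling validation and no consensus averaging of the frozen
  models are provided.
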