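# Methods

## Molecular graphs and atom classes

Molecules are handled as hydrogen-suppressed 2D graphs: SMILES are parsed
with RDKit, and each heavy atom is annotated with element, aromaticity, ring
membership, hybridization, formal charge and a Gasteiger–Marsili partial
charge. Topological distances are bond counts along shortest heavy-atom
paths (RDKit's distance matrix; pairs in different fragments are infinite
and never contribute to any descriptor). All modeled descriptors are
topological, so no 3D structure generation or geometry optimization is
performed; this is an explicit design choice and the canonical-SMILES
dialect and toolkit version are recorded in the descriptor provenance for
reproducibility.

Atom classes are decidable per atom from these annotations alone:
`ringC` (ring carbon), `Cplus` (carbon with partial charge > 0, strictly),
`ringCplus`, `aroC`, `aroCplus`, `aroN` (aromatic nitrogen by perception),
`sp2C` (sp2 carbon, with aromatic atoms mapped to sp2), `sp3O`, `sp2O`,
`sp2N`, `amideN` (nitrogen single-bonded to a carbon bearing a double-bonded
oxygen), and `Cl`. Nesting follows chemistry: aroCplus ⊆ aroC ⊆ sp2C,
ringCplus ⊆ ringC; sp2O and sp3O are disjoint.

The partial-charge scheme is a configuration point. Gasteiger–Marsili is the
default because it is fast, deterministic and standard for 2D work; the
descriptor software originally used for the published model does not
document its scheme, so exact numeric parity of charge-sum descriptors with
the published descriptor values is not claimable. "Positively charged" means
charge > 0 with no tolerance band.

## Proximity descriptors

For a source class A and target class B, let d(b) be the minimum bond
distance from target atom b to any atom of A (excluding b itself when it
belongs to both classes). Three counting modes:

- `exactly_k_excl` — |{b ∈ B : d(b) = k}|. A target that also lies within
  1..k−1 bonds of *another* source atom has d(b) < k and is excluded, which
  is precisely the published "frequency at exactly k bonds with exclusion"
  semantics (e.g. `fClamdN5B`: amide N exactly five bonds from a chlorine,
  discarded if within four bonds of any other chlorine).
- `within_le_k` — |{b ∈ B : 1 ≤ d(b) ≤ k}| (the comparator descriptors such
  as `aroN_sp2C_4B`, `sp3O_sp2O_6B`).
- `pairs_le_k` — all ordered (a, b) pairs with 1 ≤ dist ≤ k, provided for
  sensitivity analysis since the original software's atom-vs-pair counting
  convention is not documented.

Counting *target atoms at the minimum distance* makes the partition identity
Σ_{k=1..K} exactly_k(k) = within_≤K(K) hold exactly, which the tests verify
on 200 synthetic molecules alongside a brute-force double-loop oracle.
Whether `aroN_sp2C_4B` should exclude sp2 carbons of the nitrogen's own ring
is ambiguous in the original description; all sp2 carbons are counted here,
which makes the descriptor effectively "number of aromatic nitrogens" in
most ring systems (an aromatic N almost always has an aromatic C within 4
bonds) — the value still varies with ring count, which is what the model
uses.

## Curation and the modeling table

Curation drops records with missing or qualified Ki (`>`, `<`, `~`, `≥`,
`≤`, empty), keeps the largest fragment of multi-fragment SMILES (salt
stripping; ties broken by first), drops molecules containing elements
outside {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}, and deduplicates by
canonical SMILES keeping the first occurrence. Charged species are not
neutralized (the original procedure is silent; not neutralizing is the
conservative choice). pKi = 9 − log₁₀(Ki[nM]).

Objective feature selection removes zero-variance columns, near-constant
columns (most frequent value occupying > 95% of rows; the 0.05 tolerance is
a package default, the original rule being numeric-free), then resolves
every pair with |Pearson R| > 0.90 greedily in descending |R| order, keeping
the column better correlated with pKi when the response is supplied (earlier
column otherwise). The greedy order makes the result deterministic; survivors
are guaranteed pairwise |R| ≤ 0.90.

The train/external split is a seeded uniform permutation with
train = round(0.8·n) (so n = 1121 gives 897/224). Only random splitting is
offered by default, matching the original protocol.

## GA-MLR subset selection and the breaking point

Chromosomes are fixed-size descriptor subsets (the original workflow selects
a best model per size and then chooses the size, so variable-length
chromosomes are unnecessary). Fitness is the leave-one-out Q² of the OLS fit
on the training rows, computed from the PRESS identity e_i/(1−h_i) via one
QR decomposition per subset — no refitting. Singular candidate designs get
fitness −∞ and are never propagated as errors. Selection is tournament
(size 3), crossover draws the child uniformly from the union of the parents'
genes (cardinality repair by construction), mutation swaps each gene with
probability 0.05 for a random outside column, and 2 elites guarantee
monotone best fitness. Defaults: population 100, generations 300 — the
original software's GA internals are unpublished, so these are package
choices validated by the recovery experiments (the analysis and acceptance
scripts use smaller budgets, population 60–100 and generations 50–120, which
the same experiments show already recover planted subsets reliably at the
problem sizes used: pools of 50–200 descriptors, n = 300–400 rows). Ties on
fitness break lexicographically on descriptor names for determinism.

The model size is chosen by the breaking point: the smallest m with
Q²_LOO(m+1) − Q²_LOO(m) < δ, default δ = 0.02 (the original work locates the
point visually on the size-vs-Q² curve; δ is a config key and is reported in
every output).

## Validation statistics

All formulas follow the standard QSAR validation literature:

- R² = 1 − SSres/SStot; adjusted R² = 1 − (1−R²)(n−1)/(n−p−1);
  F = (SSreg/p)/(SSres/(n−p−1)); s² = SSres/(n−p−1).
- CCC = 2·cov(y,ŷ) / (var(y) + var(ŷ) + (ȳ−ŷ̄)²) with population (1/n)
  moments throughout — sample-moment CCC differs in the fourth decimal, so
  the convention is fixed and documented.
- Q²_LOO from PRESS; rows with leverage numerically 1 fall back to an
  explicit refit. Q²_LOO ≤ R²_tr always (PRESS residuals dominate ordinary
  residuals).
- Q²_LMO pools squared errors over rounds:
  1 − Σ_rounds Σ_out (y−ŷ)² / Σ_rounds Σ_out (y−ȳ_full)². The pooled form
  (rather than a mean of per-round Q²) is used because it reduces *exactly*
  to Q²_LOO when the left-out groups are the n singletons, which the tests
  verify. Defaults: 30% left out, 1000 rounds, seeded.
- External set: Q²F1 uses the training mean, Q²F2 the external mean,
  Q²F3 compares per-molecule error variances
  (1 − [Σ(y−ŷ)²/n_ext]/[SStot_tr/n_tr]). r² is the squared Pearson
  correlation; k = Σyŷ/Σy² and k′ = Σyŷ/Σŷ² are the through-origin slopes
  (ŷ on y, y on ŷ); Ro² = 1 − Σ(ŷ−ky)²/Σ(ŷ−ŷ̄)² and symmetrically R′o²;
  r²m = r²(1 − √|r²−Ro²|). The published statistic printed as
  "1 − (R²/R′o²)" is only consistent with the printed component values when
  read as (R² − R′o²)/R² = 1 − R′o²/R², so that internally consistent form
  is computed and reported as `delta_r2_Ro2`/`delta_r2_Ro2_prime`.
- Y-scrambling permutes the response (identity permutations are redrawn),
  refits, and records R², Q² and Kxy per round; both the mean and the
  maximum are retained since conventions differ on which to report (the
  mean is the headline `R2_Yscr`). Kxy is Todeschini's K multivariate
  correlation index of the [X, y] block, computed from the eigenvalues of
  the correlation matrix. Default 1000 rounds.
- Williams applicability domain: leverage h_i = x_iᵀ(XᵀX)⁻¹x_i against the
  training XᵀX, threshold h* = 3(p+1)/n_train; residuals standardized by the
  model's residual SD with response outliers at |e/s| > 2.5 (the boundary is
  plotted but unnumbered in the original figure; 2.5 is the common default
  and configurable).

## Synthetic data: what it emulates and what it does not

The molecule generator assembles functional-group templates joined by
saturated linkers of ≥ 10 CH₂ units, so every requested motif distance is
exact by construction and cross-template distances (≥ 11 bonds) can neither
create nor destroy motifs at the descriptor ranges used (k ≤ 11). Templates:
chloroalkyl amides (Cl···amide-N at exact k), acetyl/ether oxygen pairs,
guanidine/ether pairs (the sp2-N source; at k = 2 the oxygen would conjugate
and perceive as sp2, so k ≥ 3), vinyl/sulfinyl pairs (a sulfinyl oxygen is
the only simple sp2-O whose nearest sp2-C can sit 8 bonds away — a carbonyl
oxygen's own carbon is sp2 at distance 1), pyridine (aromatic N), and
tetrahydrofuran or 1,3-dioxolane rings (positively charged ring carbons,
charge sums ≈ 0.09 and 0.29). Beyond the four motifs needed by the
descriptor tests, the generator adds the guanidine and sulfinyl families so
that *all six* model descriptors vary in the study library — required for
end-to-end coefficient recovery.

The study library (`gen_study_set`) draws motif combinations per molecule,
computes the six model descriptors, and assigns
pKi = published model + N(0, 0.3); Ki = 10^(9−pKi). Planted descriptor
tables (`gen_planted_table`) mimic the modeling matrix directly: a
continuous [0, 1.5] charge-sum-like column plus Poisson(1) count columns,
independent decoys of both types, and y = 6.176 + Σβx + N(0, σ) with the
published coefficients as default β and σ = 0.3. Study conditions for the
recovery experiments are n = 300 with 194 decoys (GA recovery) and n = 400
with a 50-column pool (breaking-point recovery).

What passing these tests shows: the descriptor engine, OFS, GA, breaking
point and every validation statistic are correct and jointly able to recover
a known sparse linear structure–activity relationship at realistic noise.
What it does not show: performance on real medicinal chemistry. The
synthetic library has far less scaffold diversity than a ChEMBL extraction,
its descriptor distributions are more regular, its noise is homoscedastic
Gaussian, and descriptor collinearity is milder; R²/Q² values on it are
therefore much higher than any real-data expectation and are not comparable
to the published full-data statistics, which would additionally require the
original 1121-molecule dataset and descriptor-software parity to reproduce.

## Numerical choices and degenerate inputs

OLS uses a QR decomposition with a relative rank tolerance of 1e-10;
rank-deficient designs raise an error naming the collinear columns (GA
candidates are the exception: they score −∞ and evolution continues).
Leverages are clipped away from 1 by 1e-12 inside the GA fitness only; the
user-facing Q²_LOO refits explicitly instead. Statistics that are undefined
at zero response variance (R², CCC, Q²) raise a dedicated error rather than
returning NaN, except external Q²F2, which is flagged and set to NaN so the
rest of the external block survives. Seeds are mandatory for every
stochastic operation (split, GA, LMO, Y-scrambling, generators); no
wall-clock seeding exists anywhere, and rerunning any stage or the whole
pipeline with the same config reproduces byte-identical numeric output.

## Known limitations

- Descriptor values depend on RDKit's aromaticity/hybridization perception
  and Gasteiger charges; other toolkits (or the original descriptor
  software) will differ numerically, especially for charge sums and for
  borderline sp2/sp3 oxygen assignments (e.g. ester oxygens perceive as
  sp2).
- The GA is a single-population heuristic: it is validated to recover
  planted subsets under the study conditions, not guaranteed optimal on
  arbitrary pools.
- Stereochemistry, tautomers and 3D conformation are out of scope by
  design; descriptors are purely topological.
- The published model is carried verbatim for prediction, but applicability
  on new chemistry should be checked with the Williams AD utilities rather
  than assumed.
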