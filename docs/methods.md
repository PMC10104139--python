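# Methods

This note documents the models and procedures the package implements, the
defaults that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was open.

## Reference-anchored motif scanning

Motif positions are defined on a reference protein's residue numbering
(PctD for the amine motif, PctA for the amino-acid motif; 1-based). A query
is evaluated by locating each reference position's alignment column and
reading the query residue there. Two anchoring routes exist: a supplied
multiple sequence alignment containing the reference row, or a
self-contained global pairwise alignment of query against reference.

The pairwise aligner is a Needleman–Wunsch/Gotoh affine-gap DP. Defaults
are conventional protein-alignment settings: BLOSUM62, gap open 11, gap
extend 1, with a length-L gap costing `open + (L−1)·extend`. Ties are
broken deterministically during traceback — diagonal (match/mismatch) over
gap-in-query over gap-in-reference — so reruns are byte-identical. The
unknown residue `X` scores 0 against everything and never satisfies a
motif class: an unknown residue is evidence-free.

Residue-class defaults: AROMATIC = {F,W,Y}; POSITIVE = {R,K} (histidine
excluded — it is not observed at the charged motif sites); NEGATIVE =
{D,E}; HYDROPHOBIC = {M,L,I,V,F,A}; SMALL_POLAR = {S,T}. The published
sequence logo's exact per-position degeneracy is not printed as text, so
these class memberships are reconstructed from the residues the source
structures document and every field is overridable through a motif config
file (TSV or YAML, columns reference_position / class / members / weight /
label). Position 206 is optional-weight by default because one
amine-binding receptor (McpX) carries alanine at the equivalent site yet
binds its ligand. The amino-acid motif's terminal aspartate has no printed
PctA residue number; its default position (190) is a configurable
placeholder downstream of the last documented aromatic.

Match labels: `full_match` at ≤ 0 required-position mismatches (the
extraction in the original analysis demanded the full signature),
`near_miss` at exactly 1 (the negative-control design), otherwise
`no_match`. A gap at a required position counts as a mismatch, not an
error: an indel over the binding site is informative divergence. The
R103/D133 charged-pair check is reported as supporting evidence alongside
the motif label, never as a decision on its own.

## Alignment trimming

The gap-based column-trimming rule removes every column gapped in ≥ 10 %
of rows unless that would retain fewer than 60 % of columns; in that case
the `ceil(0.60·n)` columns with the fewest gaps are kept (ties to the lower
column index), in original order. `≥` is deliberate ("10 % or more"), and
the fallback keeps the ceiling so that never fewer than 60 % of columns
survive.

## Receptor-family classification

Domain hits (HMMER3 `hmmscan --domtblout` envelope coordinates, or a plain
TSV) are filtered at independent E-value ≤ 0.01, then resolved greedily by
ascending E-value: a hit is kept iff it overlaps every already-kept hit by
at most 20 % of the shorter hit's length (HMM envelopes commonly fray; the
tolerance is configurable). The upstream domain-annotation service used for
the original census does not publish its overlap policy, so this greedy
rule is this package's own. Families follow the output-domain vocabulary
(MCPsignal, HATPase_c, GGDEF/EAL/Guanylate_cyc/HD, SpoIIE); when several
output classes co-occur the highest-priority one (chemoreceptor >
histidine kinase > cyclase/phosphodiesterase > Ser/Thr phosphatase) is
reported and the record flagged `multi_output` rather than hidden. A
protein whose resolved hits are all sensor domains is `standalone`; a
standalone sensor is labelled standalone regardless of genomic context
(operon-level analysis is out of scope). Phyletic summaries never drop
proteins: entries missing from the taxonomy are counted as `unassigned`.

## Thermal-shift analysis

Tm is the extremum of the first derivative of the fluorescence trace. The
trace is smoothed with a centred moving average (default window 5 points at
1 °C sampling — the instrument's own pre-derivative smoothing is unstated,
so the window is configurable), differentiated by central differences, and
the extremum refined by a parabola through the extremum and its neighbours
for sub-gridstep precision. The default extremum mode is the derivative
*minimum*, matching the source instrument's convention; a `max` switch
covers exports with the opposite sign, and the melt-curve generator shares
the orientation. A curve whose derivative amplitude does not exceed six
robust standard deviations (MAD-based) of the derivative noise is flagged
`flat` and yields no Tm; an extremum on the first or last grid point is
flagged `edge` rather than silently reported. Tm is invariant under adding
a constant to, or positively rescaling, the fluorescence.

The ΔTm screen calls a shift significant at ΔTm ≥ 2.0 °C (the screening
threshold used for the binding assays); flat inputs propagate a
not-evaluable status.

## One-site ITC model and fit

Units: cell volume in litres, concentrations in mol/L, K_D reported in µM,
ΔH in kcal/mol, heats in kcal per mole of injectant (raw µcal ingestion
normalizes by moles injected). Displaced-volume bookkeeping uses the
standard perfusion-cell correction on cumulative injected volume ΔV:
`Mt = Mt0·(1 − ΔV/2V0)/(1 + ΔV/2V0)`, `Xt = Xt0·(ΔV/V0)/(1 + ΔV/2V0)`;
generator and fitter share the convention. The bound fraction solves the
one-site quadratic (root in [0,1]) and the per-injection heat includes the
`(dV_i/V0)(Q_i+Q_{i−1})/2` displacement term.

A model property worth noting: per-injection heats are *not* monotone in
K_D near the stoichiometric (tight-binding) transition — weaker binding
smooths the curve and the equivalence-point injection can gain magnitude —
whereas the cumulative heat after every injection is weakly decreasing in
K_D; the property tests assert the cumulative form.

The fit is bounded weighted least squares (`scipy.optimize.least_squares`,
trf) on (n, log10 K_D, ΔH), with n ∈ [0.2, 5] and K_D ∈ [10⁻³, 10⁵] µM so
silently extrapolated parameters are refused. K_D is fitted on a log scale
because it spans five orders of magnitude. With no user initial guess the
fit multi-starts across c-value regimes (c ≈ 0.05–500) and keeps the best
solution; tolerances are tightened to 1e-15 so noiseless round trips
recover parameters to ~1e-8 even at c « 1, where the objective is nearly
flat. Standard errors come from the local curvature (Gauss–Newton J'J) at
the solution in the natural parameterization. Non-convergence is flagged
on the result, never raised. An isotherm whose corrected heats all lie
below 0.05 kcal/mol (configurable) yields a no-binding verdict instead of
a fit, mirroring how titrations without measurable heats are treated.

Fold reductions (K_D,variant / K_D,wild-type) are rounded to the nearest
integer at ≥ 10 and one decimal below, the convention of the mutant
affinity table. One printed entry of that table (14.2/2.6 → printed 5.4)
is inconsistent with its own rounded inputs — the original analysis
evidently used unrounded dissociation constants — so that entry is not a
target of the checks.

The reference titration protocol is 16 µM macromolecule in a 1.4 mL cell,
29 × 9.6 µL injections of 0.5 mM ligand. For recovery studies across the
published K_D range (2.6–970 µM) the package provides a scaled design:
cell concentration set to c ≈ 15, syringe concentration chosen to end near
molar ratio 1.6, and the injection schedule refined to 58 × 4.8 µL (same
total volume) — at high c the transition is sharp and finer injections are
needed to sample it. Under that design, with homoscedastic noise of 2 % of
the maximal heat, the median |log(K_D_fit/K_D_true)| over seeded
replicates is ≈ 0.035, against the 0.05 recovery requirement; at the
un-scaled reference protocol the wild-type K_D is recovered with a median
error of ≈ 8–9 % at the same noise (requirement: < 10 %).

## Synthetic data: what it emulates, what it does not

The sequence generator emulates reference-anchored motif presence, not
evolution: a length-260 template carries the canonical amine-motif
residues; implanted classes draw each motif residue uniformly within its
class; background substitutions hit non-motif sites at 5 % by default
(motif positions of the declared class are never touched, so truth labels
are exact); near-miss sequences substitute exactly one required position
with an out-of-class residue; random sequences are uniform over the 20
residues, which makes the false-positive null analytically exact (the
full-match probability is the product of class frequencies, ≈ 5×10⁻⁹ for
the amine motif). Implanted classes are made mutually exclusive by forcing
the *other* motif's required positions out of class. Indels, when enabled,
are drawn outside a ±3-residue guard band around motif positions so labels
stay valid — a documented limitation: real indels do not respect guard
bands, and real backgrounds are phylogenetically correlated rather than
i.i.d. uniform. Passing tests therefore demonstrate correctness of the
scanning machinery, not sensitivity/specificity on real proteomes.

Melt curves are falling logistics (half-width 2 °C) on the 23–85 °C, 1 °C
grid with optional extra transitions and seeded Gaussian noise. Isotherms
are the forward model plus a constant dilution offset and seeded Gaussian
injection noise; real baselines drift and injection noise is not i.i.d.
Domain/taxonomy tables apportion a family mix exactly (largest remainder)
with one fixed representative architecture per family.

Every generator is a pure function of its arguments and seed; reruns are
byte-identical.

## Package shape

The assay fits are exposed as model/results objects
(`OneSiteBindingModel.fit()` → `OneSiteBindingResults` with `params`,
`bse`, `summary()`, `plot()`), the natural shape for a statistical fit;
the scanning, classification and generation stages are pipeline functions
orchestrated by a thin `click` CLI. Problem sizes in the tests and the
acceptance script (500-sequence benchmark plus a 10,000-sequence null for
scanning, 100 replicates for the noisy recovery studies, 1,000 random
alignments for the trimming oracle, 500 pairs for the alignment oracle)
were chosen to make the statistical checks sharp at desk scale; the
original census-scale searches (tens of thousands of database sequences)
are consumed as pre-computed inputs, not re-run.

## Known limitations

* The motif class memberships are a reconstruction; the published logo may
  admit residues the defaults exclude. They are configurable for exactly
  this reason.
* Pairwise anchoring can mis-map motif positions when indels fall close to
  motif sites; with 2 % indel rate ≥ 95 % of implanted sequences still
  anchor correctly, but heavily gapped real alignments should be supplied
  as MSAs instead.
* The one-site model assumes a single class of independent sites;
  multi-site or sequential-binding isotherms are out of scope.
* Baseline integration of raw power traces is out of scope — integrated
  per-injection heats are the input.
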