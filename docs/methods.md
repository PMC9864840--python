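# Methods

## The model

ecmkit works on ordinary constraint-based models: steady state S·v = 0,
flux bounds, and a linear objective (usually biomass). The enzyme
constraint is a single extra row over the *split* model — every
reversible reaction divided into a forward/`_reverse` pair, every
reaction catalysed by isozymes (a top-level OR in its GPR) divided into
`_num1…_numk` copies so that each reaction maps to exactly one enzyme:

    Σ_i  v_i · MW_i / (σ_i · k_cat,i)  ≤  E = p_tot · f.

Units are part of the contract: v in mmol/gDW/h, MW in kDa (≡ g/mmol),
k_cat converted from 1/s to 1/h, so each term is g enzyme/gDW. A
reaction enters the row only when both a k_cat and an MW are known; the
rest of the network stays purely stoichiometric. The same expression
evaluated at a solution is the per-reaction enzyme cost.

This is the single-pool formulation (one budget row shared by all
enzymes), not the per-enzyme pseudo-metabolite formulation: it keeps
the model the same size as the split GEM and makes the budget row's
shadow price directly interpretable as the marginal value of proteome.

### GPR handling

`and` denotes complex subunits, `or` isozymes; `and` binds tighter than
`or`, and chains flatten into n-ary nodes. OR-of-AND rules (isozymic
complexes) are supported — each OR child becomes one split reaction. An
OR nested *below* an AND is rejected rather than distributed: expanding
`g1 and (g2 or g3)` into two complexes would silently invent enzyme
species whose molecular weights the data do not attest. Complex MW is
Σ N_j·MW_j over the distinct subunits, with N_j the homo-oligomer copy
number from the protein table.

### Enzyme mass fraction

f = Σ_model A_i·MW_i / Σ_proteome A_j·MW_j over an abundance table
(ppm). Monomer MWs are used on both sides: ppm abundances count
polypeptides, so weighting each polypeptide by its own monomer mass is
the consistent reading; complex MWs matter only inside the budget row.
Because f is a ratio, the abundance unit cancels and f is invariant to
rescaling all abundances.

### k_cat assignment

Priority per split reaction: a record keyed by the reaction id (split
suffixes stripped, so a reverse direction inherits an undirected
forward value) beats an EC-number match; EC matches take the maximum
over all matching numbers (the optimistic convention — calibration only
ever raises values, so starting high is consistent). Remaining
enzymatic reactions are optionally filled with the median of the
assigned values; gaps are data, not errors, and coverage statistics
(direct/EC/filled counts, total and non-exchange fractions) are
returned alongside.

### Solving

FBA and pFBA are assembled as sparse LPs and solved with HiGHS
(scipy.optimize.linprog), feasibility tolerances 1e-9. pFBA is the
canonical reported solution everywhere: stage 1 maximizes the
objective, stage 2 fixes it at ≥ (1 − 1e-7)·optimum (the relaxation
absorbs solver round-off) and minimizes total flux, which is meaningful
because all fluxes are non-negative after splitting; a plain model with
reversible reactions is split internally and net fluxes are mapped
back. Infeasibility is a solution status, not an exception. Bound
overrides are stated on original reaction ids in net-flux convention
(uptake = negative lower bound on an exchange) and are translated onto
split pairs automatically.

### Calibration

Database k_cats are often far too low, over-constraining the initial
model. The calibration loop: pFBA with biomass maximization → rank the
flux-carrying constrained reactions by enzyme cost (ties broken by
reaction id for determinism) → raise the most expensive reaction whose
current k_cat is below its maximal candidate to that maximum →
re-solve; stop at the target growth rate, when candidates are
exhausted, or at the iteration cap. One modification per iteration
keeps the log interpretable and the procedure deterministic; since
k_cats only increase, growth is non-decreasing and each reaction is
touched at most once. An unreachable target returns the best model
with status `"unreached"` rather than raising: partial calibration is
still useful. Note the ranking only sees reactions that carry flux —
a corrupted enzyme with a bypass is avoided, not repaired; that is a
property of cost-based calibration itself, not of this implementation.

### Biomass quality control

For a synthesis reaction producing a formula-less pseudo-species
(biomass, protein, RNA …), mass conservation implies the species weighs
(Σ reactant mass − Σ other product mass) per unit produced; growth-rate
units are only correct when that is 1 g/mmol. `biomass_molar_mass`
reports this implied mass (g/mmol) plus an element-imbalance audit.
`normalize_macromolecule` rescales so one unit weighs exactly 1 g:
precursor coefficients ÷ m in the synthesis reaction, and the species'
coefficient × m wherever it is consumed, conserving mass flow through
the network (scaling *every* coefficient of the synthesis reaction by
one factor would leave the implied mass unchanged, so it cannot be the
normalization). Atomic masses come from a fixed embedded table (4
significant digits) so results are bit-stable across environments.

## Parameters and defaults

| parameter | default | unit | why |
|---|---|---|---|
| σ (saturation) | 1.0 | — | never measured per enzyme here; calibration absorbs saturation error into effective k_cats |
| p_tot | 0.2806 | g protein/gDW | back-computed from the two published anchors E = 0.165 g/gDW and f = 0.588 for *B. subtilis*; configurable |
| f | computed from tables | — | Eq. above; 0.588 for the shipped toy tables |
| fill policy | median | — | neutral central value; overridable or disabled |
| pFBA objective fraction | 1.0 (relaxed by 1e-7) | — | avoids stage-2 infeasibility from round-off |
| LP tolerances | 1e-9 feasibility | — | HiGHS options |
| secretion/slack tolerance (staging) | 1e-6 | mmol/gDW/h, g/gDW | numerical zero at solver precision |
| sweep grid | 0–10, 101 points | mmol/gDW/h | resolves stage boundaries to 0.1 |
| PhPP grid | substrate 0–15 × O₂ 0–50, 51 steps | mmol/gDW/h | standard phase-plane window for hexose/O₂ |

## The synthetic toy

The generator emulates the *input ecosystem* of a genome-scale build —
an SBML/JSON model plus kcat, protein (monomer MW + subunit count) and
abundance tables — at a size where the enzyme-constrained optimum is
derivable by hand. The network: glucose exchange and PTS-style
transport (homodimeric, so the complex-MW path is exercised), lumped
glycolysis (glc → 2 pyruvate + 2 ATP-equivalents), two respiratory
modes burning pyruvate at identical C/H/O stoichiometry but different
ATP yields (a proton-pumping oxidase as an AND-complex, and a low-yield
bypass oxidase — *B. subtilis* really runs such a branched chain), a
fermentative branch to acetate (an OR-isozyme pair, matched through a
shared EC number), and an ATP + glucose-carbon biomass sink whose
implied mass is exactly 1 g/mmol so growth equals biomass flux. ATP is
a massless energy token; all other internal reactions balance C, H and
O exactly.

Three orderings are asserted at generation time (violations raise,
naming the inequality): ATP per glucose decreasing
(respiration > bypass > fermentation) and ATP per gram of enzyme
increasing (fermentation > bypass > respiration). Under them the
optimal μ(q) is concave piecewise-linear with analytic breakpoints —

* q\* (budget activation): pure respiration exhausts E;
* q\*\* (overflow onset): the last fully respiratory solution dies and
  acetate secretion begins;
* q\*\*\* : purely fermentative, μ saturates —

computed from per-glucose route aggregates (ỹ = y_gly + 2·y_branch,
c̃ = c_gly + 2·c_branch plus the common transport cost) by solving the
glucose/ATP/enzyme balances for each active route pair. Defaults place
q\* ≈ 2.46 and q\*\* ≈ 8.03 mmol/gDW/h, i.e. the three stages fall
inside the default 0–10 sweep with a wide switching window. A
two-route network cannot produce a finite switching stage (budget
activation and overflow onset coincide), which is why the bypass mode
exists.

Seeded randomization perturbs only the model-gene abundances
(lognormal); topology and kinetics stay fixed so the closed form
remains exact, and non-model "filler" genes are sized so the tables'
Eq.-1 f equals the target (0.588) identically, keeping E = 0.165 g/gDW
the study condition under any seed. The multisubstrate variant adds a
second hexose entering the same lower network through its own
transporter, for mixed-substrate growth tests.

What the toy does *not* emulate: genome-scale redundancy (thousands of
reactions, alternate optima), cofactor and nitrogen metabolism,
maintenance ATP, measurement noise in kinetic constants, and
multi-product overflow — a cost-optimal LP secretes only the single
cheapest overflow product by construction. Passing tests therefore
demonstrate correctness of the machinery (splitting, constraint
assembly, staging, calibration), not predictive accuracy on real
organisms.

## Numerical choices and degenerate inputs

* Budget "binding" means slack ≤ 1e-6 g/gDW; with an infinite budget
  the row is omitted entirely.
* Stage classification tolerates non-monotone stage sequences with a
  warning (they can arise from alternate optima at degenerate points)
  and still reports first-crossing boundaries.
* Ties in enzyme-cost ranking are broken lexicographically by reaction
  id, making calibration and target tables deterministic.
* Exchange reactions are recognised as single-metabolite reactions;
  secretion is the positive net exchange flux after recombining split
  pairs.
* An empty formula has molar mass 0 (with a warning); biomass detection
  requires exactly one formula-less product, otherwise the species must
  be named explicitly.
* Reactions whose genes lack protein rows, or that receive no k_cat,
  silently stay outside the budget row; an entirely empty row is an
  error, since the result would masquerade as an enzyme-constrained
  model while being plain FBA.

## Problem sizes

The shipped analyses run on the toy network (16–20 split reactions):
sweeps use 101-point grids, phase planes up to 51×51, closed-form
verification 121 points. All are exact LP solves; sizes were chosen to
resolve the analytic breakpoints to one grid step, and everything the
test suite runs completes in seconds on one CPU. The same code paths
take genome-scale models through the identical API.

## Known limitations

* One global enzyme pool: no per-enzyme abundance bounds or
  compartment-specific budgets.
* σ is a scalar policy, not fitted saturation; calibrated k_cats are
  therefore *effective* rates.
* Cost-based calibration cannot find corrupted parameters on avoidable
  reactions (see above) and stops at the first growth plateau.
* Loopless/thermodynamic constraints, flux sampling and dynamic
  simulation are out of scope; pFBA removes futile cycles only insofar
  as they cost flux.
* SBML round-trips preserve stoichiometry, bounds, GPRs and EC
  annotations, but enzyme parameters (k_cat/MW/σ) travel only in the
  native JSON dialect.
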