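# Methods

`brainflux` implements a multi-compartment, constraint-based model of human
brain energy and neurotransmitter metabolism: cell-type models for neurons,
astrocytes, microglia and oligodendrocytes are extracted from expression
evidence, merged into a four-compartment brain network with intercellular
transport, and interrogated with linear and quadratic flux programs under
resting and perturbed conditions. A reporter-metabolite module maps
gene-level differential-expression p-values onto the metabolic network.
Everything runs on a packaged synthetic toy network, so the full protocol is
reproducible without downloads.

## Constraint-based core

A model is a stoichiometric matrix S (metabolites x reactions) with flux
bounds, gene-protein-reaction (GPR) rules, and subsystem labels. All fluxes
are in umol of metabolite per gram tissue per minute. The basic problems
are:

* **FBA** — max/min `c.v` s.t. `S v = 0`, `lb <= v <= ub` (HiGHS via
  `scipy.optimize.linprog`).
* **Two-stage FBA** — FBA optima are usually degenerate, so the linear
  objective is fixed at its optimum (appended as an equality row) and
  `sum v^2` is minimized over all reactions. The result is the unique
  minimum-norm optimal flux distribution. Exchange fluxes are pinned by
  stage-1 constraints, so restricting the quadratic term to internal fluxes
  would give the same answer; the simpler all-reaction form is used.
* **FVA** — per-reaction flux min/max under fixed constraints (2 LPs per
  reaction).
* **MOMA** — after a perturbation, minimize `||v - v_ref||^2` subject to
  the perturbed constraints, i.e. the metabolic adjustment relative to a
  reference state, reported with its Euclidean distance.

Quadratic programs are solved with OSQP when importable (tight tolerances,
polishing on), with a pure-scipy augmented-Lagrangian bounded-least-squares
fallback. Either path is followed by an exact KKT polish: with the active
bound set fixed, the equality-constrained projection is re-solved in closed
form, so steady-state residuals and ratio couplings hold to ~1e-12 (well
inside the 1e-9 feasibility target). The reporting threshold for a
"nonzero" flux is 1e-6 throughout. All solver configurations are
deterministic; identical inputs give bit-identical outputs on a platform.

**Ratio couplings.** Constraints of the form `flux(A) = alpha * flux(B)`
(pentose-phosphate flux = 5%/6% of glucose uptake; intercellular GABA = 25%
of the glutamine cycle flux) are materialized as stoichiometric rows: a
pseudo-metabolite (compartment `x`, prefix `CPL_`) with coefficient +1 in A
and -alpha in B. Every downstream solve — FBA, FVA, MOMA, or an external
solver reading the same matrix — then satisfies them exactly.

## Toy brain network (synthetic data)

The generator builds one parent model per cell type (40–120 reactions) from
a shared template of lumped pathways: glycolysis, pentose-phosphate pathway,
TCA cycle, oxidative phosphorylation (P/O ratio 1.5), lactate
exchange/shuttle, ketone-body utilization, fatty-acid oxidation with the
carnitine shuttle, fatty-acid/cholesterol/sphingolipid/phospholipid
synthesis, the glutamate/glutamine/GABA system, serine/glycine and
branched-chain amino-acid shuttles, catecholamine and acetylcholine
synthesis, NAA metabolism, a lumped biomass reaction (ATP + glutamate +
lipid + nucleotide surrogate), and — in oligodendrocytes — a myelin
formation reaction consuming cholesterol, galactosylceramide,
phosphatidylcholine, phosphatidylethanolamine and sphingomyelin (equimolar
by default, overridable). Cofactor pairs (ATP/ADP, NAD(P)/NAD(P)H) are
balanced so that energy accounting is meaningful; elemental mass balance of
lumped steps is advisory only. LDH sits in "Pyruvate metabolism" (its KEGG
assignment), so glycolysis activity tracks glucose throughput rather than
NADH disposal.

Internal enzymatic reactions carry GPRs over a synthetic global gene
namespace (`G0001...`), with AND = enzyme complex = min and OR = isozymes =
max when scored against expression. A handful of transporters with
well-known genetics (GLUT, MCT, OCTN2-like carnitine transporter, amino-acid
carriers) also carry genes; other transporters and all exchanges are
GPR-free and therefore evidence-neutral.

**Expression emulation.** Each cell type gets a designated expressed gene
set (its functional reactions) and a designated silent set (e.g. glutamine
synthetase in neurons, glutamate decarboxylase in astrocytes, sphingolipid
synthesis in microglia, cholesterol synthesis in neurons). Expressed genes
receive Poisson-lognormal counts across 20 emulated cells per type; silent
genes are zero in every sample (dropout-style silence). After TPM
normalization and per-type averaging, expressed genes land far above the
cutoff of 1 TPM and silent genes below it, so the cutoff semantics of the
extraction step are exercised exactly. Counts vary with the seed; the
expressed/silent partition does not.

**Planted differential expression.** For reporter-recovery experiments,
genes adjacent to chosen "hot" metabolites draw p-values with
`-log10 p ~ Gamma(shape=16, scale=effect/16)` — mean `effect`, CV 0.25, a
coherent planted signal — while all other genes are Uniform(0,1). The
pipeline's disease contrasts plant L-carnitine in microglia and acetate in
oligodendrocytes.

**What the toy data do not emulate:** transcript-level quantification,
within-type cell heterogeneity, batch effects, realistic gene-length/GC
biases, genome-scale network redundancy, or thermodynamic constraints.
Passing tests demonstrate that the pipeline's logic is correct under the
stated conditions, not that real tissues behave this way.

## Tasks and context-specific extraction (tINIT-lite)

A metabolic task closes the system boundary, opens a stated set of inputs
(with uptake caps), and requires each stated output at a minimum flux; it is
feasible iff the resulting LP is. Essential tasks (aerobic/anaerobic ATP
regeneration, ketone utilization, biomass synthesis) apply to every cell;
cell-specific tasks encode the known division of labor (glutamine ->
glutamate in neurons and microglia, glutamate -> glutamine in astrocytes,
GABA handling, serine/glycine interconversion, BCAA transamination,
catecholamine and acetylcholine production, NAA synthesis in neurons and
degradation in oligodendrocytes, myelin formation). OPCs carry the
essential list only.

Extraction keeps every expressed reaction (GPR score >= cutoff, default 1
TPM) and removes non-expressed reactions greedily in ascending evidence
order — with the full task list re-checked after each tentative removal, so
a reaction survives iff removing it would break a task. Protected reactions
(biomass, myelin, their demands, ATP maintenance, and transport/exchange of
intercellularly traded metabolites) and evidence-neutral reactions (no GPR)
are never removed. Ties are broken lexicographically, making the result
deterministic. This greedy, task-checked procedure honours the
task-guarantee contract of expression-driven extraction at toy scale; it is
not the original MILP formulation. Its output is sound (all tasks pass) and
single-removal minimal (verified exhaustively in the tests); it does not
claim global minimality over removal sets.

## Integration

Merging suffixes reaction ids, subsystems, metabolite ids and compartments
per cell (`_N`, `_A`, `_M`, `_O`); genes stay global. A shared unsuffixed
"brain interstitial" compartment hosts pooled species. Sequential pairwise
merging equals the one-shot merge up to canonical form. Intercellular
reactions then connect extracellular interfaces: glutamate N->A and N->M,
glutamine A->N and A->M, GABA N->A, glycine/aspartate/alanine N<->A, NAA
N->O, and lactate among all four cells via a shared interstitial pool
(per-cell import/export rather than pairwise reactions — fewer reactions,
same flux semantics). Nutrient exchanges (glucose, oxygen, ketone bodies)
remain per-cell.

Single-cell resting simulations (two-stage biomass FBA, oligodendrocytes
with myelin formation active at 0.010) provide exchange constraints for the
merged model: each cell's non-nutrient exchange flux becomes a capacity
bound (between the single-cell value and zero). Capacity semantics — rather
than exact equality pins — keep the perturbation protocols well posed: an
equality pin would force, e.g., myelin-precursor uptake even when the
demyelination sweep removes its sink. Traded neurotransmitters are
included in the pinning so their circulation must run through the
intercellular reactions; NAA's blood exchange is closed outright (it does
not cross the blood-brain barrier) and neurons synthesize it
constitutively at 0.005, so the N->O transfer stays active.

## Study conditions and perturbation protocols

Resting capacities and demands (umol/g tissue/min): neurons — glucose 0.25,
O2 0.30, ATP maintenance 1.0, PPP = 5% of glucose uptake; astrocytes —
glucose 0.06, O2 0.52, maintenance 1.3, PPP = 6%; microglia and
oligodendrocytes inherit astrocyte capacities with internal lower bounds at
zero (glial convention), maintenance 0.9 and 0.6; oligodendrocytes
additionally get myelin-precursor uptakes (choline/ethanolamine/serine
0.05, palmitate 0.12). Glutamine synthetase is capacity-limited at 0.2,
which caps the glutamate/glutamine/GABA cycle. All other exchanges default
to lb -0.01 (bounded uptake), ub 1000 (free release). The caps are placed
so that the network is poised the way brain tissue is: astrocytes are
glucose-limited (their demand tops out local fuels, so glucose
supplementation is what relieves them), neurons have glucose headroom but a
snug oxygen ceiling (so an oxygen decrement forces a measurable anaerobic
shift while remaining feasible).

The integrated brain objective maximizes the glutamine A->N transfer (the
cycle scalar) with intercellular GABA tied to 25% of it, followed by the
quadratic stage. Protocols:

* **glucose** — each cell's glucose uptake flux set to 0.210;
* **ketogenic** — each cell's acetoacetate and (R)-3-hydroxybutanoate
  uptake fluxes set to 0.050. Supplementation sets the uptake *flux*, not
  merely the capacity: under the parsimonious second stage a wider bound on
  an all-oxidative fuel is never exercised, so a capacity-only reading
  would make supplementation a no-op by construction;
* **hypoxia** — each cell's O2 uptake capacity reduced by 0.100 (floored at
  zero); implemented as a capacity decrement, not a forced flux;
* **demyelination** — oligodendrocyte myelin flux fixed at 11 levels from
  0.010 to 0 in 10% steps, each solved by MOMA against the resting
  reference.

Per-condition outputs are per-cell subsystem activities (sum of |flux|,
count of reactions above 1e-6, totals; transport and exchange/demand
subsystems reported separately and excluded from mean-flux summaries) and
the intercellular flux table. On this fixture, glucose supplementation
raises glycolysis activity; ketone bodies raise TCA-cycle activity in every
cell and raise TCA/oxidative phosphorylation while lowering the glycolysis
share relative to glucose supplementation; hypoxia shifts activity from
oxidative phosphorylation and the TCA cycle toward glycolysis; and the
demyelination sweep yields 11 optimal states with zero adjustment at the
reference level and an active NAA transfer throughout. These directions are
asserted by the test suite, not assumed.

## Reporter metabolites and enrichment

Gene p-values map to Z-scores via `Z = Phi^-1(1 - p)` (p clamped to
[1e-15, 1-1e-15]). A metabolite's neighborhood is the set of *distinct*
genes in the GPRs of reactions that produce or consume it (a gene counts
once however many adjacent reactions carry it); currency metabolites
(ATP/ADP/NAD(P)(H)/CO2/O2/...) are excluded by a configurable blocklist,
and compartments are scored separately with an optional pooled mode. The
raw score is `z_raw = sum(Z_g) / sqrt(k)`; the background correction draws
10,000 random k-subsets (without replacement) of the scored genes per
occurring k, giving `z_corr = (z_raw - mu_k) / sigma_k` and upper-tail
`p = 1 - Phi(z_corr)`; a degenerate background (sigma_k = 0) defines
z_corr = 0. Sampling is seeded and vectorized. Raw p-values are reported
against the 0.05 / 0.025 thresholds without multiplicity correction;
directional (up/down) variants are not computed.

Over-representation uses the exact upper-tail hypergeometric probability of
the observed overlap between the reporter set and each pathway metabolite
set (GMT format; the pipeline derives toy pathway sets from subsystem
membership). Under null (uniform) gene p-values the reporter false-positive
rate at 0.05 is calibrated (checked against binomial 99% bounds over 50
seeds); with a planted effect of 3 the hot metabolite ranks first
essentially always.

## Numerical choices and degenerate inputs

* LP feasibility tolerance 1e-9; QP termination 1e-10 with exact polish;
  zero-flux reporting threshold 1e-6.
* Removal candidates with equal evidence are ordered lexicographically.
* Empty GPR = no evidence (None), distinct from a measured 0; missing
  genes score 0.
* All-zero count vectors are an error in TPM normalization; a task
  metabolite absent from the model makes the task infeasible-with-reason,
  not an error; solver breakdowns raise, distinct from infeasibility.
* Zero stoichiometric coefficients are dropped and ids sorted on
  canonicalization; round-trip JSON I/O is the identity on canonical form.
* Seeds propagate explicitly; no global RNG state is used.

## Known limitations

* The toy network is a caricature: lumped stoichiometry, one gene layer,
  no compartment-specific cofactor pools, no thermodynamics. Quantitative
  fluxes (e.g. biomass 0.009–0.019/min across cells) are
  order-of-magnitude plausible but not calibrated.
* The extraction procedure guarantees task feasibility and single-removal
  minimality, not global (set-wise) minimality.
* The reporter background correction is empirical; strict monotonicity of
  the corrected p in a single gene's p-value holds only for a fixed
  background (relevant at toy gene-set sizes).
* Protocol comparisons are directional, not quantitative; absolute
  activity values depend on the chosen capacities.
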