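# Methods

## Model representation

A model is an ordered collection of metabolites and bounded reactions plus a
gene inventory. Stoichiometric coefficients follow the FBA convention
(negative = consumed, positive = produced) and reversibility is encoded
purely in the bounds: a reaction is reversible iff its lower bound is
negative. This keeps one source of truth; the equation-string arrow in the
table dialect (`<=>` vs `->`) only selects the *default* bounds
([−1000, 1000] vs [0, 1000], the conventional finite caps) when explicit
bounds are absent.

An exchange reaction is structurally defined as a reaction touching exactly
one metabolite; uptake is negative exchange flux. A medium is a map from
exchange ids to maximal uptake rates (mmol/gDW/h, non-negative): applying it
sets each listed exchange's lower bound to −limit, closes uptake on every
unlisted exchange, and caps secretion at 1000. Two presets encode the study
conditions: `minimal` (glucose 10 mmol/gDW/h — the conventional default cap
for a limiting carbon source — plus inorganic N/P/S/Mg at 10 and free
O2/H2O/H+) and `fermentation` (minimal plus the 20 proteinogenic amino acids
at 0.01 mmol/gDW/h each, the uptake rate used in the original fermentation
simulations). Qualitative growth calls are threshold-based and therefore
insensitive to the exact caps.

GPR rules use a small grammar — case-insensitive `AND`/`OR`, parentheses,
`AND` binding tighter — matching common SBML-FBC text renderings. An empty
rule means "no gene association" and survives every knockout.

## Structural QC

Mass/charge balance is a reporting operation: for each reaction,
Σ coefficient×element-count and Σ coefficient×charge must vanish. Boundary
pseudo-reactions (exchanges, demands/sinks, biomass, the EPS target) are
intentionally unbalanced and reported `exempt`; reactions whose metabolites
all lack formulas are `unverifiable` rather than failed, since supplementary
reaction tables frequently omit formulas. Dead-end detection marks
metabolites that cannot be both produced and consumed given bounds and
reversibility; exchange coverage counts in both directions. Gap *filling* is
deliberately out of scope (curation is a manual, organism-specific act);
only detection is provided.

## LP and QP solving

FBA LPs are solved with HiGHS (scipy.optimize.linprog), requesting 1e-9
feasibility/optimality tolerances and verifying steady state at 1e-6 — the
gap distinguishes true zero growth (essentiality) from numerical dust.
Infeasible/unbounded statuses are propagated, never mapped to silent zeros;
an unbounded objective is treated as a model QC failure (missing caps).

FBA optima are generically non-unique, so every downstream quantity that
consumes a full flux vector uses the parsimonious reference: a second LP
minimising Σ|v| (flux splitting v = p − q) subject to retaining ≥ 99.99 % of
the objective. One-sided bounds that exclude zero (e.g. an imposed minimum
product flux) are restored as explicit inequality rows, since the plain
split relaxes them.

The MOMA projection is a strictly convex QP solved with OSQP
(eps 1e-10, polished) and verified for feasibility with an LP pre-check;
when OSQP is absent the same problem is solved with scipy's trust-constr.
The unperturbed projection returns the reference to ~1e-12, and hand-solved
KKT cases (chain and parallel-path projections) pin the solution to 1e-6.

## Essentiality

Single-gene deletion evaluates every GPR with the gene knocked out, zeroes
the bounds of inactivated reactions, and re-solves. "Zero growth" is
objective < 1e-6 (absolute, 1/h) — a numeric floor above LP tolerance for
the qualitative criterion. Product (EPS) essentiality first pins biomass to
a fraction of its wild-type optimum; the fraction defaults to 0.5 and is
exposed as a parameter because the appropriate viability level is a
modelling choice, not a derivable constant — reported essentiality counts
are conditional on it. A knockout that renders the constrained problem
infeasible counts as essential. Subsystem breakdowns assign each essential
gene to the subsystem carrying most of its reactions (ties break
lexicographically) so percentages form a partition summing to 100.

## Overexpression screen

Five steps: (i) impose a minimum product flux — a fraction φ (default 0.1,
a flag) of the maximal EPS rate under the medium, since the screen's
contract is the *ranking*, not an absolute flux level; (ii) compute the
parsimonious wild-type reference on the fermentation medium; (iii) for each
reaction with |wild-type flux| > 1e-6, force v ≥ fold × wt (direction
preserved; default fold 2.0); (iv) solve MOMA against the reference;
(v) score with f_PH = f_biomass · f_EPS and select targets with higher EPS
production and f_PH > 1. Ranking is deterministic: descending f_PH, ties by
ascending reaction id; infeasible perturbations are recorded with their
status and ranked last. Reaction targets map back to genes through the GPR,
so an isozyme (OR) reaction reports all its genes. A linear-distance MOMA
variant is a documented extension point, not implemented.

## Objective construction

The biomass pseudo-reaction converts mass fractions (g/gDW) to molar
coefficients via 1000·w/M with residue molar masses from a user registry,
plus a growth-associated maintenance ATP hydrolysis term. Coefficients
invert exactly back to the composition (mass closure to 1 g). The EPS
target drains nucleotide-sugar donors in the measured monosaccharide mole
ratios, normalised to 1 mmol total donor per unit product, releasing the
matching NDP/dNDP species. The shipped default compositions are documented
placeholders with the right qualitative shape (glucose-dominated EPS with
little fucose/rhamnose; protein/glucan-dominated biomass; GAM 40 mmol
ATP/gDW; RNA:DNA 6) — real analyses should override them from config, which
is why composition is data, not code. Polymerisation energetics (ATP per
glycosidic bond) default off because repeat-unit assembly stoichiometry is
generally unknown.

## Synthetic data: what it emulates and what it does not

The toy generator emits a compartment-free core network: carbon-source
exchanges → uptake → kinase/catabolism → a lumped energy module (rational
ATP yield per substrate, drawn from {6, 8, 10, 12} per seed) → biomass, with
inorganic N and P uptakes, optional amino-acid uptake/deamination blocks,
and the full nucleotide-sugar branch (isomerase, phosphomutases,
pyrophosphorylases, 4-epimerases, dehydrogenase/decarboxylase, and the
GDP-fucose and dTDP-rhamnose steps, the last two as two-subunit AND
complexes). Isozyme pairs (OR rules) are planted on a fixed candidate list;
a configurable chain of uniquely catalysed steps before biomass plants
known essential genes; one carbon source and one amino acid may be left
without catabolic routes to plant negative phenotype calls; and a gap can
be injected by removing all consumers of a metabolite chosen so that
exactly one new dead end appears and growth survives.

Yields are small rationals, so the maximal growth and EPS rates have closed
forms (every donor costs one glucose backbone plus two activation ATP, so
max EPS = G·(Y−1)/(Y+1) for glucose cap G and ATP yield Y); essential-gene
truths are derived structurally (single-knockout GPR falsification over the
required-reaction sets), independent of any LP. The generator re-verifies
these truths against the solver at generation time and fails loudly on
disagreement. The planted top overexpression target is the one exception:
it is computed by running the screen itself (an exhaustive screen over all
candidates) and serves as a determinism/self-consistency anchor, not an
independent oracle.

Passing on toys therefore demonstrates algorithmic correctness — solver
agreement with enumeration, exact truth recovery, projection identities —
not biological realism: toy fluxes are in arbitrary but consistent units,
there is no compartmentalisation, no cofactor bookkeeping beyond a lumped
ATP pool, and network sizes (tens of reactions) are far below genome scale.
Results on a real reconstruction depend on its curation quality and on the
conditional choices above (biomass constraint level, imposed product flux,
amplification fold).

## Problem sizes and numerical choices

Tests and the acceptance script run on toy models of 10–92 reactions:
the 10-reaction topology is used where brute-force vertex enumeration is
the oracle (20 seeds), the full topology (64 genes, 92 reactions, EPS
branch and amino acids) everywhere else. These sizes keep every truth
analytically checkable while exercising all code paths; the pipeline itself
is size-agnostic (sparse matrices, HiGHS, OSQP) and accepts genome-scale
SBML input through the same interfaces. Ties, degenerate optima and
tolerances are handled as described above; the reproducibility contract is
objective values and selected sets, not bitwise flux-vector identity.

## Known limitations

No flux variability analysis, sampling, thermodynamic or dynamic FBA; no
double deletions; no regulatory constraints (a purely stoichiometric model
cannot capture them — the urea/citrate phenotype disagreements in the
packaged validation tables are the classic symptom); automated gap filling
and charge-state prediction are out of scope; COBRA `.mat` I/O is not
provided.
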