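# Methods

This note documents the models, conventions and numerical choices behind
`oleoflux`, and what the synthetic test networks do and do not establish.

## Steady-state model and solvers

A metabolic model is held as a sparse stoichiometric matrix **S** (m
metabolites × n reactions) with per-reaction flux bounds in mmol/gDW/h,
boolean GPR rules (`and` = enzyme complex, `or` = isozymes; an empty rule is
always active) and a biomass objective whose flux is the specific growth
rate (/h).  Reversibility is encoded purely by a negative lower bound; the
arrow in tabular equation strings is display-only.  Exchange reactions are
recognised structurally — a single metabolite in the extracellular
compartment — rather than by id prefix, and negative exchange flux means
uptake.

All linear programs (FBA, FVA, robustness points, pFBA stages) are solved
with scipy's HiGHS backend.  Every vector reported as optimal passes a
post-solve audit: ‖S·v‖∞ ≤ 1e-6 and bounds respected to the same tolerance;
a solution failing the audit raises rather than propagating.  The audit
threshold is deliberately coarser than HiGHS's internal feasibility
tolerances (~1e-9) so it only fires on genuine solver misbehaviour.

**Alternate optima.**  LP optima of metabolic networks are degenerate.
Wherever a single representative flux vector matters downstream — the MOMA
reference, cofactor accounting — the parsimonious solution is used: the
objective is pinned at its optimum and total absolute flux is minimised
(implemented by variable splitting, `min Σtᵢ` s.t. `−tᵢ ≤ vᵢ ≤ tᵢ`).  This
makes every downstream quantity deterministic.

## Media

Media are exchange-bound override maps.  Applying one with
`closed_default=True` (the default) sets every unlisted exchange to
(0, 1000): a minimal medium is minimal because everything else is absent,
while secretion stays free.  The standard media are MG_glucose (glucose LB
−1.4, ammonia −10, water/oxygen/phosphate/sulfate/protons −1000, all UB
1000), MG_glycerol (glycerol −1.6 instead of glucose) and YE (MG_glucose
plus every amino-acid exchange present in the model at −0.1).  Exchanges are
located by the chemical species they carry, through an overridable alias
table, so the definitions survive naming drift between model dialects; amino
acids missing from a model are skipped rather than fatal, since
reconstructions differ in which amino acids they exchange.

## MOMA

The perturbed-state prediction is the Euclidean projection of the reference
distribution onto the perturbed flux polytope — an equality-plus-box QP with
identity Hessian.  It is solved by a primal active-set method specialised to
that structure: each iteration solves one dense KKT system (lstsq, so a
rank-deficient S is handled), takes the blocking-constraint step, and
checks multiplier signs for convergence; with a strictly convex objective
the iteration terminates finitely.  Degenerate instances that exceed the
iteration cap fall back to scipy's `trust-constr` (observed never to trigger
on the test networks); both paths face the same steady-state/bounds audit.
The optimal distance is unique even when the minimiser is not; distances
below 1e-6 are reported as exactly zero (reference feasible).  The dense KKT
solves make the implementation appropriate up to a few hundred reactions;
genome-scale use would want a sparse factorisation.

The quadratic objective is unweighted and the reference is not normalised.
Reactions absent from the reference are treated as zero.

## Essentiality

A gene deletion zeroes the bounds of every reaction whose GPR evaluates
inactive under the knockout.  Classes are growth-ratio cutoffs: essential
below 0.01, partially essential below 0.5, non-essential otherwise.  These
cutoffs are conventions, not measurements — no standard numeric definition
exists — so both are exposed as configuration, which is also the sanctioned
way to match a particular study's published counts.  Subsystem attribution
counts a gene toward every subsystem containing a reaction its deletion
disables, the least-committal reading of per-subsystem essentiality plots.
The screen aborts if the wild type fails to grow in any requested medium.

## Production objective and supplementation

"Product formation" at a growth optimum is ill-posed: a pure biomass
optimum leaves essentially zero product flux.  Production is therefore
computed lexicographically — maximise biomass, hold it at `fraction` of the
optimum as a floor, maximise the product exchange.  The fraction defaults
to 1.0; the toy networks evaluate their ground truths at 0.9 because their
small LPs have literally no slack at the full optimum (genome-scale models
show a tiny nonzero wild-type product flux only through degeneracy).

In a supplementation scan the growth floor computed for the **baseline**
medium is reused for every supplemented condition.  This makes each
supplement a pure relaxation of the production LP, so the reported percent
change is provably ≥ 0, and it compares conditions at an equal growth
demand.  Re-fixing growth at each condition's own optimum (the alternative
convention, under which monotonicity is not guaranteed) is available via
`refix_biomass=True`.  Percent changes are computed on production fluxes,
not yields.

Gap checking is a minimal-cardinality search: candidate subsets are tried
in order of increasing size (default cap 3), and the first subset whose
addition restores growth on the source is returned.  This is exact for the
small candidate pools it is meant for; no MILP machinery is used.

## Overexpression screen

Five steps: floor the DHA exchange at 0.01 mmol/gDW/h; take the parsimonious
biomass-maximal reference; for each internal biochemical reaction with
|v_ref| > 1e-6 force |v| ≥ 2·|v_ref| in the reference direction; re-solve by
MOMA; keep targets with DHA above the floor and f_PH = f_biomass · f_DHA
> 1.  The amplified bound raises the opposing bound when the target exceeds
it — overexpression is modelled as added enzyme capacity, so a pre-existing
capacity cap must yield.  An equality-pinning mode (`mode="pin"`) is
provided because "two-fold amplification" is also readable as forcing
exactly doubled flux.  Exchanges and the biomass reaction are never
amplified; transports are excluded by default (switchable).  The wild-type
DHA denominator in f_DHA is the floored reference value, since the floor is
imposed before the reference solve.  Amplifications whose forced flux cannot
be carried anywhere (MOMA infeasible) are reported as skipped — on tightly
coupled networks this is common and informative, not an error.

## Biomass assembly

`build_biomass_reaction` converts macromolecular mass fractions (g/gDCW)
and per-class monomer profiles into drain coefficients in mmol/gDCW such
that total drained monomer mass closes to 1 g within 1 %.  Nucleotide mole
fractions follow from genomic G+C content (dGTP = dCTP = gc/2, dATP = dTTP
= (1−gc)/2; RNA with UTP).  Protein and nucleic-acid monomers are accounted
as residues (one water of condensation, 18.0153 g/mol, subtracted per
monomer; toggleable).  Growth-associated maintenance ATP defaults to
30 mmol/gDCW — the order of magnitude used by reference fungal
reconstructions — and sits outside the mass closure because it is energy
spent, not matter incorporated; it should be refit whenever energetic data
exist.

## The synthetic networks

The generator emits a ~40-reaction network with the motifs the pipeline
assumes: glucose/glycerol uptake, lumped glycolysis, an oxidative PPP
(G6PD + PGD, the only route to the nucleotide precursor), a TCA backbone
with malate/citrate exchanges, the three acetyl-CoA sources (PDC as a
two-gene AND complex, ATP-citrate lyase, acetyl-CoA synthetase), malic
enzyme, a lumped PKS reaction fixed at 11 acetyl-CoA + 14 NADPH → 1 DHA
(a C22:6 acetyl-unit accounting over the iterative KS/KR/DH/ER cycles,
chosen concrete so analytic yield bounds exist), a hexokinase isozyme pair,
amino-acid synthesis/uptake pairs, and a biomass drain.  Biomass
coefficients were chosen so that growth is glucose-limited (uptake saturates
at 1.4 at the optimum) with μ ≈ 1.1 /h on MG, the PPP flux is exactly
growth-coupled, and amino-acid uptake at 0.1 rescues the synthesis
knockouts in YE.

Bottleneck modes install capacity caps: `nadph` caps the TCA leg (0.2
mmol/gDW/h) so that, with PPP growth-coupled, extra NADPH for DHA can come
only from malic enzyme's limited malate supply — opening a malate uptake
then demonstrably raises DHA; `accoa` caps pyruvate dehydrogenase at its
own parsimonious growth requirement so citrate (via ATP-citrate lyase)
becomes the relieving supplement.  Under the NADPH ceiling, doubling PKS
flux is infeasible (the network cannot regenerate 0.28 mmol/gDW/h of
NADPH), which the screen reports as a skipped lethal amplification; the
acetyl-CoA variant is the one where PKS amplification is a clean hit.

The lactose pathway (hydrolase + galactose assimilation) is emitted only in
gapped variants: removing the hydrolase gives a one-reaction gap, removing
both gives a pair in which neither singleton suffices (the hydrolase stalls
on its dead-end galactose without the kinase), making the minimal fix
exactly the pair.  A xylose exchange with no catabolic route is always
present as a structural dead end.

Every manifest claim — growth ordering, saturated glucose uptake, the
essential-in-both and essential-only-in-MG gene sets, PKS-knockout
phenotype, bottleneck relief, the analytic carbon bound on DHA yield
(6 × 1.4 / 22 mmol/gDW/h), gap fixes — is hand-derived from the construction
and re-verified at generation time with the package's own solvers;
generation fails loudly otherwise.  All randomness (gene-id naming) flows
from the single seed and emitted files are byte-identical per seed.

**What the toys do not show.**  They are two orders of magnitude smaller
than a genome-scale reconstruction, elementally unbalanced by design
(lumped reactions), and far more tightly coupled — most amplifications are
infeasible and most genes are strongly forced, where a real network's
redundancy would absorb them.  Passing tests establish correctness of the
algorithms and conventions, not quantitative agreement with any organism's
measured rates.

## Problem sizes and tolerances

Test and acceptance runs use the 40-reaction networks (LPs solve in
milliseconds; the full suite is a few hundred LP/QP solves).  Audit
tolerance 1e-6 throughout; MOMA zero-distance threshold 1e-6; active-flux
threshold for the screen 1e-6; robustness scans fix parameters by equality
(LB = UB), recording infeasible grid points in place.  Default 2D robustness
grids are 20 × 20 when not specified.
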