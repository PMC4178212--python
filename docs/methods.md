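# Methods

## Model and scope

`fluxcue` implements expression-cued flux prediction on a stoichiometric
network at steady state. The network is the usual constraint-based
object: metabolites with plain string compartment tags, reactions with
signed stoichiometries, flux bounds, boolean gene–protein–reaction (GPR)
rules, and a subsystem (pathway) label; boundary exchanges are one-sided
stoichiometries flagged explicitly. Models are read from a small JSON
dialect (schema shipped with the package) or from an SBML Level 3 / FBC
subset; SBML writing, model curation and gap-filling are out of scope.
Reactions lacking bounds in a file receive the conventional defaults
[−1000, 1000] if reversible, [0, 1000] if not. Cross-compartment
shuttles (e.g. cytosolic→ER glucose-6-phosphate transport in hepatic
glucose production) are ordinary transport reactions over two metabolite
entries; no compartment ontology is imposed.

## Expression cues

Replicates are collapsed to a per-gene, per-condition mean; no variance
model is fitted (differential-expression testing is deliberately not
part of this package). The summary is discretized to trinary states
(+1 high / 0 moderate / −1 low) in one of two modes:

* **Quantile mode** (`q_low=0.25`, `q_high=0.75` by default): states
  from the condition's own empirical quantiles, computed with linear
  interpolation between order statistics (pinned so that independent
  implementations reproduce the thresholds exactly). Quantiles may
  instead be pooled across conditions (`pooled` discretization of all
  per-condition summaries against shared cutoffs).
* **Explicit-threshold mode** (`t_low` / `t_high`): absolute cutoffs,
  for data on a known scale.

Either mode can be applied to raw summaries or to **baseline-centered**
summaries (`center="gene"`), i.e. each gene's per-condition mean minus
its mean across all conditions. Centering reads the cue as *relative
regulation* — a gene induced in one condition is a positive deviation
there and a negative one elsewhere — which is the appropriate reading
for a cross-condition flux contrast, and is how the iMAT lineage of
methods treats expression (a gene's state is judged against its own
level across contexts, not against other genes). A constant summary
vector yields no cues (logged); genes in GPRs but absent from the
profile evaluate to 0, since absence of evidence is not a cue.

Gene states propagate to reactions through the GPR with AND = min
(a complex is limited by its scarcest subunit) and OR = max (isozymes);
reactions without a GPR stay moderate. The +1 reactions form R_H, the
−1 reactions R_L.

## The cue-agreement MILP

Continuous variables v (bounded fluxes) satisfy S·v = 0. Each r ∈ R_H
contributes a binary indicator that may be 1 only if v_r ≥ ε (a second,
OR-linked indicator covers v_r ≤ −ε for reversible reactions: expression
cannot indicate direction). Each r ∈ R_L contributes an indicator that
may be 1 only if |v_r| ≤ tol. Indicators are linked by big-M constraints
with M taken from the reaction's own bounds, which is exact for bounded
fluxes. The objective maximizes the indicator sum; the optimum is the
integer count of simultaneously satisfiable cues.

Defaults: ε = 1.0 and tol = 1e−6 in toy flux units (bounds of order
10); both are configuration, reported in every manifest, and should be
scaled with the model's bound magnitudes — objectives and verdicts are
invariant under joint scaling of bounds, ε and tol. The relative MIP
gap is pinned at 1e−9 so integer objectives are certified exactly and
verdicts never hinge on solver slack. The backend is HiGHS through
`scipy.optimize.milp`; any solver meeting the same contract could stand
behind the same problem description.

## Activity classification and flux contrast

A single optimal flux vector is solver-dependent, so per-reaction
verdicts are defined by forced re-optimization: re-solve with the
reaction forced to carry flux (|v_r| ≥ ε, best over directions) and
forced silent (|v_r| ≤ tol); an infeasible forcing counts as −∞. The
verdict is **active** if the forced-active optimum strictly exceeds the
forced-inactive one, **inactive** in the mirrored case, **undetermined**
on equality — all integer comparisons, no floating tolerance. Flux
ranges are optimum-preserving variability: min/max v_r subject to
retaining the optimal cue count. Classification costs two MILPs per
reaction (four with ranges); a reaction filter restricts it to a
subsystem when models are large.

Two conditions are compared per reaction by strict interval separation:
`higher_in_a` only when min(range_a) > max(range_b), overlapping ranges
are `indistinguishable`. This is deliberately conservative — a claim of
higher flux holds across *all* optimum-preserving solutions of both
conditions, not for one arbitrary optimum.

## Enrichment

Pathway over-representation among predicted-active reactions uses the
one-sided hypergeometric tail P(X ≥ k) (computed via scipy's log-domain
survival function; the test suite certifies it against exact rational
arithmetic to 1e−12 relative error) with Benjamini–Hochberg step-up
adjustment across all tested pathways at α = 0.05 by default.
Undetermined reactions are not counted as active: "predicted active" is
read strictly. The default universe is reactions belonging to at least
one pathway — unannotated reactions (typically exchanges) cannot
contribute to any pathway count and would dilute the universe
arbitrarily; `universe="all"` is available. A contrast table flags each
pathway as significant in A only / B only / both / neither.

## Synthetic scenarios

The generator emulates the structure of a hepatic glucose-production
contrast at desk scale: `n_pathways` structurally identical linear
chains (source exchange, `pathway_length` gene-bearing conversions
including one cytosol→ER transport, sink exchange), all irreversible
with bounds [0, 10]; the first chain is labelled `gluconeogenesis` and
is the planted truth. Defaults are 5 pathways of length 6 (40 reactions,
30 genes). Expression: planted genes Normal(mu_high=10, sigma=1) in
condition `p53_active` and Normal(mu_mid=5, sigma=1) otherwise; all
other genes Normal(mu_mid, sigma) everywhere; 3 replicates per
condition on a log-expression scale, per microarray convention. The
topology is deterministic given the sizes; all randomness is seeded and
same-seed regeneration is byte-exact.

Private metabolites make chains independent, so the exhaustive oracle
stays tractable and the truth table is unambiguous; single-gene GPRs
isolate optimizer behavior from GPR logic (a paired mode with two-gene
AND/OR rules exercises the latter). The generator does **not** emulate
probe effects, batch structure, basal expression heterogeneity across
genes, branched topologies, or genome-scale stoichiometry — so passing
recovery here certifies the machinery (discretization → MILP →
classification → enrichment), not performance on real microarrays.

Each scenario records its calibrated discretization — `center="gene"`
with thresholds ±(mu_high − mu_mid)/4 — as part of the study
conditions. The calibration is principled, not fitted: on the centered
scale a planted gene deviates by ±(mu_high − mu_mid)/2 in each condition
while an unregulated gene's deviation is mean-zero replicate noise with
standard deviation σ/√(2·n_reps) ≈ 0.41 at defaults, so the midpoint of
the two magnitudes separates regulation from noise by about three
standard errors on both sides. The demo and the acceptance harness use this
scenario calibration. Two design facts drove the choice of centering
over the raw-value modes, worked out analytically before any recovery
measurement: per-condition quantile cues label a fixed quarter of genes
high even in a null condition, and a single spurious high cue activates
an entire chain, whose complete pathway overlap is then
hypergeometrically "enriched" almost regardless of α; conversely any
mode that leaves the null condition cue-free cannot pin the planted
chain's flux range there, so no strict-separation contrast can emerge.
Baseline-centered cues give both: high planted cues where the genes are
induced, low planted cues where they are not, and essentially no decoy
cues.

## Numerical choices and degenerate inputs

* Quantile definition: linear interpolation (`numpy.quantile`,
  `method="linear"`); at-or-below / at-or-above comparisons at the
  thresholds.
* Mass-balance is enforced exactly in the MILP; returned vectors are
  checked to satisfy max|S·v| ≤ tol (observed residuals are at solver
  precision, ~1e−9 or better).
* Forced subproblems with empty feasible boxes (e.g. forcing activity
  on a reaction whose bounds exclude ±ε) are treated as objective −∞
  without invoking the solver.
* The brute-force oracle enumerates indicator subsets by decreasing
  cue count with early exit and refuses instances with more than 12
  cue-bearing reactions.
* Enrichment ties (identical adjusted and raw p) are ordered
  alphabetically by pathway; an empty active set yields all p = 1 with
  a logged warning rather than an error.
* Infeasible base problems (bounds excluding any steady state) return
  an `infeasible` status, never an exception.

## Problem sizes in the shipped harness

The test and acceptance harnesses certify the solver against the
exhaustive oracle on 55 networks of ≤ 8 cue-bearing reactions, calibrate
the null false-positive rate on 1000 random active sets over the default
toy universe, and measure planted-pathway recovery on 100 seeded
scenarios at generator defaults — sizes at which the exhaustive oracle
is exact and the full suite completes in a few minutes on one CPU.
Recovery at defaults is 96–97 of 100 seeds with specificity 100/100;
the residual failures are rank ties in which replicate noise fully
activates one decoy pathway alongside the planted one.

## Known limitations

* Activity verdicts depend on ε and the discretization mode; there is
  no universal default for real data, and both are surfaced in the run
  manifest for that reason.
* Per-reaction classification is O(n) MILPs and becomes the bottleneck
  at genome scale; use the reaction filter or skip flux ranges.
* The hypergeometric universe treats reactions as exchangeable, which
  linear toy pathways satisfy but coupled genome-scale subsystems only
  approximate; enrichment p-values on real reconstructions inherit
  that caveat (as does any reaction-set over-representation analysis).
* Four-state designs (two genotypes × two treatments) are handled as
  repeated pairwise contrasts, not a joint model.
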