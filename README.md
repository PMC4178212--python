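# fluxcue

Expression-cued constraint-based flux prediction for condition
contrasts, with reaction-activity classification and pathway
over-representation under FDR control.

## The problem

Transcriptomic profiling tells you which enzyme genes move between two
cellular states — say hepatocytes with active versus depleted p53 — but
not which *metabolic fluxes* change: flux is set jointly by the whole
network's stoichiometry, not by any one transcript. `fluxcue` closes
that gap with an iMAT-style integration: treat discretized expression
levels as *cues* for whether a reaction is likely to carry flux, then
find the steady-state flux distribution most consistent with all cues at
once.

Given a stoichiometric model (S, flux bounds, gene–protein–reaction
rules, subsystem labels) and per-condition trinary gene states, the core
mixed-integer program is

```
max   Σ_{r ∈ R_H} y_r  +  Σ_{r ∈ R_L} z_r
s.t.  S v = 0,    lb ≤ v ≤ ub
      y_r = 1 ⇒ |v_r| ≥ ε        (r ∈ R_H, either direction if reversible)
      z_r = 1 ⇒ |v_r| ≤ tol      (r ∈ R_L)
      y, z ∈ {0, 1}
```

where R_H / R_L are the reaction sets cued highly / lowly expressed
through the GPR rules (AND = min, OR = max). Because the optimum is
degenerate, per-reaction verdicts come from forced re-optimization: a
reaction is **active** when forcing it silent costs cue agreement,
**inactive** when forcing it to carry flux does, **undetermined**
otherwise. Flux ranges are optimum-preserving variability (min/max v_r
subject to keeping the optimal cue count), and two conditions are
contrasted by strict interval separation of those ranges. Pathways are
scored for over-representation among the predicted-active reactions with
a one-sided hypergeometric test and Benjamini–Hochberg FDR.

The MILP backend is HiGHS (via `scipy.optimize.milp`); an exhaustive
enumeration oracle certifies the optimum on small instances.

## Worked example

```
$ fluxcue demo --seed 1 --out demo_run
top enrichment in p53_active: gluconeogenesis (k=6/6, p_adj=8.42e-06, significant=True)
```

The demo generates a hepatocyte-like toy scenario: five structurally
identical linear pathways (source exchange → six gene-bearing
conversions, one of them a cytosol→ER transport step → sink exchange),
of which one — labelled `gluconeogenesis` — has its genes shifted from a
log-expression mean of 5 to 10 in the `p53_active` condition only. The
pipeline discretizes each gene against its cross-condition baseline,
solves the MILP per condition, classifies all 40 reactions, and writes
the tables to `demo_run/`.

The printed line says the planted pathway is the top-ranked enrichment
in the active condition: all 6 of its reactions are in the 6-reaction
predicted-active set out of a 30-reaction universe, hypergeometric
p = 1/C(30,6) adjusted to 8.4e-06 across the five tested pathways —
significant at α = 0.05, while the same pathway has an empty overlap
(p = 1) in `p53_depleted`. `demo_run/flux_comparison.tsv` shows every
glucogenic reaction called `higher_in_a`: its optimum-preserving flux
range is [1, 10] under active p53 and pinned to [0, 1e-6] under
depletion — the in-silico signature of enhanced gluconeogenic flux.

The same pipeline runs on user files (`fluxcue run`) with a model in
either the package's JSON dialect (`src/fluxcue/schema/model_schema.json`)
or SBML Level 3 with FBC bounds and GPRs, an expression TSV, a
sample→condition design TSV, and a pathway-membership TSV.

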