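"""Synthetic hepatocyte-like benchmark scenarios.

The generator builds a desk-scale network emulating the structure of the
hepatic glucose-production study: one designated *glucogenic* linear
pathway — a precursor taken up by an exchange (think glycerol), converted
through a chain of internal reactions including one cytosol-to-
endoplasmic-reticulum transport step (the G6P shuttle that precedes
dephosphorylation and glucose export), and exported by a sink exchange —
plus structurally identical decoy pathways.  Every internal reaction
carries its own single-gene GPR and its pathway's subsystem label;
exchanges carry neither.

The paired expression design emulates the two-condition contrast of
p53-intact versus p53-depleted liver cells: in condition ``p53_active``
the planted pathway's genes are drawn i.i.d. Normal(mu_high, sigma) on a
log-expression scale and every other gene Normal(mu_mid, sigma); in
condition ``p53_depleted`` all genes are Normal(mu_mid, sigma).  The
scenario records the intended truth (planted reactions carry flux in
condition A only) and a calibrated discretization recommendation:
per-gene baseline centering with absolute thresholds at plus/minus a
quarter of the planted shift — on the centered scale a planted gene
deviates by half the shift in each condition (up in A, down in B) while
unregulated genes hover near zero, so the quarter-shift midpoint
separates regulation from replicate noise.

Linear pathways with private metabolites keep the exhaustive MILP oracle
tractable and make the truth table unambiguous; single-gene GPRs isolate
optimizer behavior from GPR logic (two-gene complexes/isozymes are
available via ``gpr_mode`` to exercise the latter).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionProfile
from .io import write_model
from .model import MetabolicModel, Metabolite, Reaction
from .gpr import Gpr

__all__ = [
    "SyntheticScenario",
    "generate_toy_network",
    "generate_expression",
    "generate_scenario",
    "PLANTED_PATHWAY",
    "CONDITION_A",
    "CONDITION_B",
]

PLANTED_PATHWAY = "gluconeogenesis"
CONDITION_A = "p53_active"
CONDITION_B = "p53_depleted"

#: Flux bound applied to every generated reaction (irreversible, [0, 10]).
TOY_UPPER_BOUND = 10.0


@dataclass
class SyntheticScenario:
    model: MetabolicModel
    profile: ExpressionProfile
    truth: pd.DataFrame            # reaction, condition, intended_active
    planted_pathway: str
    seed: int
    center: str                    # recommended discretization: "gene" centering ...
    t_low: float                   # ... with these absolute thresholds on centered values
    t_high: float

    @property
    def design(self) -> pd.Series:
        return self.profile.design

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the files the pipeline consumes, plus the truth table."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "model": outdir / "model.json",
            "expression": outdir / "expression.tsv",
            "design": outdir / "design.tsv",
            "pathways": outdir / "pathways.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_model(self.model, paths["model"])
        self.profile.values.to_csv(paths["expression"], sep="\t", index_label="gene")
        pd.DataFrame(
            {"sample": self.profile.design.index, "condition": self.profile.design.values}
        ).to_csv(paths["design"], sep="\t", index=False)
        with open(paths["pathways"], "w") as fh:
            for r in self.model.reactions:
                if r.pathway:
                    fh.write(f"{r.pathway}\t{r.id}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def generate_toy_network(
    n_pathways: int = 5,
    pathway_length: int = 6,
    seed: int = 0,
    *,
    gpr_mode: str = "single",
) -> MetabolicModel:
    """Build the planted-pathway toy network.

    One glucogenic chain plus ``n_pathways - 1`` decoys, each: a source
    exchange, ``pathway_length`` internal gene-bearing conversions (the
    penultimate one a cytosol -> ER transport), and a sink exchange.  All
    reactions are irreversible with bounds [0, 10].  The topology is a
    deterministic function of the sizes; ``seed`` is accepted for API
    symmetry with the expression generator and recorded downstream, but
    no randomness enters the network itself.  ``gpr_mode`` selects
    single-gene rules (default), or alternating two-gene ``and`` / ``or``
    rules (``"paired"``) to exercise complex/isozyme logic.
    """
    if n_pathways < 2:
        raise ValueError(f"need n_pathways >= 2, got {n_pathways}")
    if pathway_length < 3:
        raise ValueError(f"need pathway_length >= 3, got {pathway_length}")
    if gpr_mode not in ("single", "paired"):
        raise ValueError(f"unknown gpr_mode {gpr_mode!r}")

    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    for p in range(n_pathways):
        label = PLANTED_PATHWAY if p == 0 else f"decoy_pathway_{p}"
        tag = "glu" if p == 0 else f"d{p}"
        # metabolite chain M0..M_L; the last two live in the ER so that the
        # penultimate reaction is the cross-compartment transport step
        mets = []
        for i in range(pathway_length + 1):
            compartment = "er" if i >= pathway_length - 1 else "c"
            mets.append(Metabolite(id=f"{tag}_m{i}", compartment=compartment))
        metabolites.extend(mets)

        reactions.append(
            Reaction(
                id=f"{tag}_uptake",
                stoichiometry={mets[0].id: 1.0},
                lower_bound=0.0,
                upper_bound=TOY_UPPER_BOUND,
                is_exchange=True,
            )
        )
        for i in range(pathway_length):
            if gpr_mode == "single":
                gpr = Gpr("gene", gene=f"g_{tag}_{i + 1}")
            else:
                op = "and" if i % 2 == 0 else "or"
                gpr = Gpr(
                    op,
                    children=(
                        Gpr("gene", gene=f"g_{tag}_{i + 1}a"),
                        Gpr("gene", gene=f"g_{tag}_{i + 1}b"),
                    ),
                )
            reactions.append(
                Reaction(
                    id=f"{tag}_r{i + 1}",
                    stoichiometry={mets[i].id: -1.0, mets[i + 1].id: 1.0},
                    lower_bound=0.0,
                    upper_bound=TOY_UPPER_BOUND,
                    gpr=gpr,
                    pathway=label,
                )
            )
        reactions.append(
            Reaction(
                id=f"{tag}_export",
                stoichiometry={mets[-1].id: -1.0},
                lower_bound=0.0,
                upper_bound=TOY_UPPER_BOUND,
                is_exchange=True,
            )
        )
    return MetabolicModel(metabolites, reactions)


def generate_expression(
    model: MetabolicModel,
    mu_high: float = 10.0,
    mu_mid: float = 5.0,
    sigma: float = 1.0,
    n_reps: int = 3,
    seed: int = 0,
) -> SyntheticScenario:
    """Draw the two-condition expression design over a generated network.

    Planted-pathway genes are Normal(mu_high, sigma) in condition A and
    Normal(mu_mid, sigma) in condition B; all other genes are
    Normal(mu_mid, sigma) in both.  ``n_reps`` replicate samples per
    condition.  The same seed reproduces the scenario exactly.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")

    planted_genes: set[str] = set()
    genes: list[str] = []
    seen: set[str] = set()
    for r in model.reactions:
        if r.gpr is None:
            continue
        for g in sorted(r.gpr.genes()):
            if g not in seen:
                genes.append(g)
                seen.add(g)
            if r.pathway == PLANTED_PATHWAY:
                planted_genes.add(g)

    rng = np.random.default_rng(seed)
    samples = [f"{CONDITION_A}_rep{i + 1}" for i in range(n_reps)] + [
        f"{CONDITION_B}_rep{i + 1}" for i in range(n_reps)
    ]
    design = pd.Series(
        [CONDITION_A] * n_reps + [CONDITION_B] * n_reps, index=samples
    )
    means = np.full((len(genes), 2 * n_reps), mu_mid)
    for i, g in enumerate(genes):
        if g in planted_genes:
            means[i, :n_reps] = mu_high
    values = pd.DataFrame(
        rng.normal(means, sigma), index=pd.Index(genes, name="gene"), columns=samples
    )
    profile = ExpressionProfile(values, design)

    rows = []
    for r in model.reactions:
        planted = r.pathway == PLANTED_PATHWAY
        rows.append({"reaction": r.id, "condition": CONDITION_A, "intended_active": planted})
        rows.append({"reaction": r.id, "condition": CONDITION_B, "intended_active": False})
    truth = pd.DataFrame(rows)

    # Calibrated discretization: judged against its own cross-condition
    # baseline, a planted gene deviates by +/-(mu_high - mu_mid)/2 while an
    # unregulated gene's deviation is mean-zero noise; the midpoint of those
    # two magnitudes separates them.
    delta = (mu_high - mu_mid) / 4
    return SyntheticScenario(
        model=model,
        profile=profile,
        truth=truth,
        planted_pathway=PLANTED_PATHWAY,
        seed=seed,
        center="gene",
        t_low=-delta,
        t_high=delta,
    )


def generate_scenario(
    n_pathways: int = 5,
    pathway_length: int = 6,
    mu_high: float = 10.0,
    mu_mid: float = 5.0,
    sigma: float = 1.0,
    n_reps: int = 3,
    seed: int = 0,
    *,
    gpr_mode: str = "single",
) -> SyntheticScenario:
    """Generate network and expression in one call (the demo's entry point)."""
    model = generate_toy_network(
        n_pathways, pathway_length, seed=seed, gpr_mode=gpr_mode
    )
    return generate_expression(
        model, mu_high=mu_high, mu_mid=mu_mid, sigma=sigma, n_reps=n_reps, seed=seed
    )
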