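"""Pathway over-representation within the predicted-active reaction set.

For each pathway (subsystem) the overlap between the reactions predicted
active in a condition and the pathway's members is scored with the
one-sided hypergeometric tail P(X >= k) — the standard test for
set-vs-universe over-representation — and p-values are adjusted across
all tested pathways by the Benjamini–Hochberg step-up procedure at level
``alpha`` (the study-style FDR control).

Universe choice: by default, all model reactions that belong to at least
one pathway; reactions without a subsystem label (typically boundary
exchanges) cannot contribute to any pathway count and would dilute the
universe arbitrarily.  ``universe="all"`` switches to every reaction.
Undetermined verdicts are not counted as active: "predicted to be
active" is read strictly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .imat import ActivityCall

__all__ = [
    "EnrichmentResult",
    "hypergeometric_test",
    "bh_adjust",
    "enrich_pathways",
    "contrast_enrichment",
    "read_pathway_map",
]

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    pathway: str
    universe_size: int     # N
    pathway_size: int      # K
    active_total: int      # n
    overlap: int           # k
    p_raw: float
    p_adjusted: float
    significant: bool


def hypergeometric_test(N: int, K: int, n: int, k: int) -> float:
    """One-sided over-representation tail P(X >= k), X ~ Hypergeom(N, K, n).

    N is the universe size, K the pathway size, n the number of active
    reactions drawn, k the observed overlap.  Computed through scipy's
    log-domain survival function (numerically stable for large counts).
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, returned in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def read_pathway_map(path) -> dict[str, list[str]]:
    """Read a pathway-membership TSV: one (pathway, reaction id) pair per line."""
    df = pd.read_csv(path, sep="\t", header=None, names=["pathway", "reaction"])
    out: dict[str, list[str]] = {}
    for pathway, reaction in zip(df["pathway"].astype(str), df["reaction"].astype(str)):
        out.setdefault(pathway, []).append(reaction)
    return out


def pathway_map_from_model(model) -> dict[str, list[str]]:
    """Derive the pathway -> reactions map from a model's subsystem labels."""
    out: dict[str, list[str]] = {}
    for r in model.reactions:
        if r.pathway:
            out.setdefault(r.pathway, []).append(r.id)
    return out


def enrich_pathways(
    calls: list[ActivityCall],
    pathway_map: dict[str, list[str]],
    alpha: float = 0.05,
    *,
    universe: str = "pathway",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each pathway in the active reaction set.

    ``calls`` are one condition's activity verdicts over the whole model;
    ``universe="pathway"`` (default) restricts the universe to reactions
    belonging to at least one pathway, ``"all"`` uses every classified
    reaction.  Results are BH-adjusted across all tested pathways and
    sorted by adjusted then raw p-value.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    all_reactions = [c.reaction for c in calls]
    in_pathway = {r for members in pathway_map.values() for r in members}
    unknown = in_pathway - set(all_reactions)
    if unknown:
        raise ValueError(f"pathway map references unclassified reactions: {sorted(unknown)}")

    if universe == "pathway":
        universe_set = [r for r in all_reactions if r in in_pathway]
    elif universe == "all":
        universe_set = all_reactions
    else:
        raise ValueError(f"unknown universe mode {universe!r}")

    active = {c.reaction for c in calls if c.verdict == "active"}
    active_in_universe = [r for r in universe_set if r in active]
    N, n = len(universe_set), len(active_in_universe)
    if n == 0:
        log.warning("condition %s: empty active set, all p-values are 1",
                    calls[0].condition if calls else "?")

    pathways = sorted(pathway_map)
    raw = []
    counts = []
    universe_lookup = set(universe_set)
    for pw in pathways:
        members = [r for r in pathway_map[pw] if r in universe_lookup]
        K = len(members)
        k = sum(1 for r in members if r in active)
        counts.append((K, k))
        raw.append(hypergeometric_test(N, K, n, k) if n else 1.0)

    adjusted = bh_adjust(raw) if raw else np.array([])
    results = [
        EnrichmentResult(
            pathway=pw,
            universe_size=N,
            pathway_size=K,
            active_total=n,
            overlap=k,
            p_raw=float(p),
            p_adjusted=float(q),
            significant=bool(q <= alpha),
        )
        for pw, (K, k), p, q in zip(pathways, counts, raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.pathway))
    return results


def contrast_enrichment(
    results_a: list[EnrichmentResult], results_b: list[EnrichmentResult]
) -> pd.DataFrame:
    """Cross-condition significance contrast per pathway.

    Flags each pathway as significant in A only, in B only, in both, or
    in neither; both inputs must cover the same pathway set.
    """
    by_a = {r.pathway: r for r in results_a}
    by_b = {r.pathway: r for r in results_b}
    if set(by_a) != set(by_b):
        raise ValueError("mismatched pathway sets between conditions")
    rows = []
    for pw in sorted(by_a):
        sa, sb = by_a[pw].significant, by_b[pw].significant
        flag = {
            (True, True): "both",
            (True, False): "significant_in_a_only",
            (False, True): "significant_in_b_only",
            (False, False): "neither",
        }[(sa, sb)]
        rows.append(
            {
                "pathway": pw,
                "p_adjusted_a": by_a[pw].p_adjusted,
                "p_adjusted_b": by_b[pw].p_adjusted,
                "significant_a": sa,
                "significant_b": sb,
                "contrast": flag,
            }
        )
    return pd.DataFrame(rows)


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "N": r.universe_size,
                "K": r.pathway_size,
                "n": r.active_total,
                "k": r.overlap,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
            for r in results
        ]
    )
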