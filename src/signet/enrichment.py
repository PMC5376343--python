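"""Pathway over-representation analysis of curated target lists.

Each pathway of a database is tested with a Fisher exact test on the 2x2
table (in-pathway / out-of-pathway) x (target / non-target) over a
background set.  Under-represented pathways (target density below the
background density) are removed regardless of p-value; over-represented
ones are kept when p < alpha (default 0.1, raw p-values, no multiplicity
correction — a Benjamini-Hochberg column is reported for transparency
only).  A rescue step then adds, for every target not covered by the
selection, a pathway containing it, so the selected collection covers all
targets the database can cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Pathway",
    "EnrichmentResult",
    "fisher_enrichment",
    "enrich_all",
    "select_pathways",
    "rescue_pathways",
    "enrichment_report",
]


@dataclass
class Pathway:
    """A pathway: a member set plus its raw interaction rows.

    ``interactions`` rows are tuples ``(source, target, type, sign)`` over
    member ids or group ids; ``groups`` maps a group-node id to its member
    ids (interchangeable proteins represented as one pathway node).
    """

    id: str
    source_db: str
    members: set[str]
    interactions: list[tuple] = field(default_factory=list)
    groups: dict[str, list[str]] = field(default_factory=dict)
    name: str = ""


@dataclass
class EnrichmentResult:
    pathway_id: str
    k: int  # targets in pathway (within background)
    m: int  # pathway size (within background)
    n: int  # target-list size (within background)
    N: int  # background size
    p_value: float
    overrepresented: bool


def fisher_enrichment(targets: set[str], pathway: Pathway, background: set[str]) -> EnrichmentResult:
    """Fisher exact test of target over-representation in one pathway.

    The test is two-sided; the direction is judged separately by comparing
    the in-pathway target density k/m with the background density n/N, so
    a significant depletion is never reported as enrichment.
    """
    if not background:
        raise ValueError("empty background set")
    targets_bg = targets & background
    members_bg = pathway.members & background
    k = len(members_bg & targets_bg)
    m = len(members_bg)
    n = len(targets_bg)
    N = len(background)
    table = [[k, m - k], [n - k, N - m - (n - k)]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    over = m > 0 and (k / m) >= (n / N)
    return EnrichmentResult(pathway.id, k, m, n, N, float(p), over)


def enrich_all(
    targets: set[str],
    pathways: list[Pathway],
    background: set[str] | None = None,
    alternative: str = "two-sided",
) -> list[EnrichmentResult]:
    """Test every pathway that contains at least one target.

    ``background`` defaults to the union of all pathway members of the
    database.  ``alternative`` may be set to ``"greater"`` for a one-sided
    test; the density-based over-representation flag is applied either way.
    """
    if background is None:
        background = set().union(*(p.members for p in pathways)) if pathways else set()
    results = []
    for pw in sorted(pathways, key=lambda p: p.id):
        if not (pw.members & targets):
            continue
        res = fisher_enrichment(targets, pw, background)
        if alternative == "greater":
            targets_bg = targets & background
            members_bg = pw.members & background
            k, m, n, N = len(members_bg & targets_bg), len(members_bg), len(targets_bg), len(background)
            _, p = stats.fisher_exact(
                [[k, m - k], [n - k, N - m - (n - k)]], alternative="greater"
            )
            res.p_value = float(p)
        results.append(res)
    return results


def select_pathways(results: list[EnrichmentResult], alpha: float = 0.1) -> set[str]:
    """Keep over-represented pathways with p strictly below *alpha*."""
    return {r.pathway_id for r in results if r.overrepresented and r.p_value < alpha}


def rescue_pathways(
    all_pathways: list[Pathway],
    selected: set[str],
    targets: set[str],
    results: list[EnrichmentResult] | None = None,
    policy: str = "best-p",
) -> set[str]:
    """Add pathways covering targets the selection misses.

    For each target present in the database but in no selected pathway,
    include a containing pathway: under ``best-p`` the one with the
    smallest enrichment p-value (ties broken by smallest pathway, then
    lexicographic id); under ``all-containing`` every containing pathway.
    The returned set is disjoint from *selected*.
    """
    by_id = {p.id: p for p in all_pathways}
    p_of = {r.pathway_id: r.p_value for r in results} if results else {}
    covered = set()
    for pid in selected:
        covered |= by_id[pid].members & targets

    rescued: set[str] = set()
    for t in sorted(targets - covered):
        containing = [p for p in all_pathways if t in p.members and p.id not in selected]
        if not containing:
            continue
        if policy == "all-containing":
            rescued |= {p.id for p in containing}
        else:
            best = min(containing, key=lambda p: (p_of.get(p.id, 1.0), len(p.members), p.id))
            rescued.add(best.id)
    return rescued - selected


def enrichment_report(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results with a BH-FDR column (reported, never used to select)."""
    df = pd.DataFrame(
        [
            {
                "pathway": r.pathway_id,
                "k": r.k,
                "m": r.m,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "overrepresented": r.overrepresented,
            }
            for r in results
        ]
    )
    if len(df):
        df["fdr_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return df
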