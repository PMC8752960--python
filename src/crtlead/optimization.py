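"""Optimal lead-design selection, clustering and cross-cohort evaluation.

Patient-based optimum: the (vein, configuration) maximising the AT090
percent reduction for a subject.  Cohort-based optimum: collect every
subject's best configuration (at their best vein) and find the minimum
number of quadripolar designs that jointly contain all of them (exact set
cover over the 70 candidate designs); the primary design is the single
design containing the most subjects' optima.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .campaign import ResponseMatrix
from .leads import LeadDesign, VEIN_ORDER, enumerate_lead_designs

__all__ = [
    "OptimalSelection",
    "ClusteringResult",
    "patient_optimal",
    "cohort_optimal",
    "hac_cluster",
    "cross_cohort_evaluate",
    "minimal_design_cover",
    "greedy_design_cover",
]


@dataclass
class OptimalSelection:
    """Cohort-level design selection."""

    per_subject_best: dict  # subject -> (vein, config, reduction %)
    chosen_designs: tuple  # minimal covering set of LeadDesign
    primary_design: LeadDesign
    coverage: dict  # design name -> set of covered subjects


@dataclass
class ClusteringResult:
    """Agglomerative merge tree (scipy linkage convention) and flat labels."""

    merge_tree: np.ndarray  # (n-1, 4): idx_i, idx_j, height, size
    items: list
    labels_at_k: dict  # k -> per-item labels (1..k)


def _vein_rank(vein: str) -> int:
    return VEIN_ORDER.index(vein)


def patient_optimal(
    matrix: ResponseMatrix, subject: str, scope: str = "best_vein"
):
    """Best (vein, configuration, AT090 % reduction) for one subject.

    Ties break to the lexicographically smallest configuration name, then
    the conventional vein order (IN, IL, LA, AL, AN).  ``scope="per_vein"``
    returns a dict vein -> (config, reduction).
    """
    g = matrix.records[matrix.records["subject"] == subject]
    if g.empty:
        raise ValueError(f"no records for subject {subject!r}")
    if scope == "per_vein":
        out = {}
        for vein, gv in g.groupby("vein"):
            best = _argmax_record(gv)
            out[vein] = (best["config"], float(best["at090_red_pct"]))
        return out
    if scope != "best_vein":
        raise ValueError("scope must be per_vein or best_vein")
    best = _argmax_record(g)
    return best["vein"], best["config"], float(best["at090_red_pct"])


def _argmax_record(g: pd.DataFrame):
    red = g["at090_red_pct"].to_numpy()
    top = red.max()
    cand = g[red >= top - 1e-12].copy()
    cand["vr"] = cand["vein"].map(_vein_rank)
    cand = cand.sort_values(["config", "vr"], kind="stable")
    return cand.iloc[0]


def minimal_design_cover(
    config_names: Sequence[str], designs: Optional[Sequence[LeadDesign]] = None
) -> tuple:
    """Exact minimum set of quadripolar designs containing all configurations.

    Searches cover sizes 1, 2, 3, ... exhaustively over the candidate
    designs (those containing at least one target configuration), returning
    the lexicographically first minimal cover.  The universe is at most 36
    configurations against 70 designs, so exact search is cheap.
    """
    if designs is None:
        designs = enumerate_lead_designs()
    targets = sorted(set(config_names))
    if not targets:
        raise ValueError("no configurations to cover")
    for t in targets:
        if not any(d.contains(t) for d in designs):
            raise ValueError(f"configuration {t!r} fits no design")
    cands = [d for d in designs if any(d.contains(t) for t in targets)]
    cands.sort(key=lambda d: d.name)
    for size in range(1, len(cands) + 1):
        for combo in itertools.combinations(cands, size):
            if all(any(d.contains(t) for d in combo) for t in targets):
                return combo
    raise RuntimeError("unreachable: full candidate set always covers")


def greedy_design_cover(
    config_names: Sequence[str], designs: Optional[Sequence[LeadDesign]] = None
) -> tuple:
    """Greedy cover (cross-check only; may exceed the exact minimum)."""
    if designs is None:
        designs = enumerate_lead_designs()
    remaining = set(config_names)
    chosen = []
    while remaining:
        best = max(
            sorted(designs, key=lambda d: d.name),
            key=lambda d: len([t for t in remaining if d.contains(t)]),
        )
        covered = {t for t in remaining if best.contains(t)}
        if not covered:
            raise ValueError("some configuration fits no design")
        chosen.append(best)
        remaining -= covered
    return tuple(chosen)


def cohort_optimal(
    matrix: ResponseMatrix,
    cohort: str = "RR+HF",
    designs: Optional[Sequence[LeadDesign]] = None,
    tolerance_pct: float = 0.0,
) -> OptimalSelection:
    """Cohort-based optimal lead designs (each subject at their best vein).

    ``tolerance_pct`` > 0 treats near-optimal configurations (within the
    tolerance of the subject's maximum) as equally optimal, in which case a
    design covering any of them covers the subject.
    """
    if designs is None:
        designs = enumerate_lead_designs()
    recs = matrix.records
    if cohort != "RR+HF":
        recs = recs[recs["cohort"] == cohort]
    if recs.empty:
        raise ValueError(f"no records for cohort {cohort!r}")

    per_subject_best = {}
    accepted: dict[str, set] = {}
    for subject, g in recs.groupby("subject"):
        best = _argmax_record(g)
        per_subject_best[subject] = (
            best["vein"],
            best["config"],
            float(best["at090_red_pct"]),
        )
        top = g["at090_red_pct"].max()
        ok = g[g["at090_red_pct"] >= top - tolerance_pct]
        accepted[subject] = set(ok["config"])

    if tolerance_pct == 0.0:
        cover_targets = sorted({v[1] for v in per_subject_best.values()})
        chosen = minimal_design_cover(cover_targets, designs)
    else:
        chosen = _minimal_subject_cover(accepted, designs)

    coverage = {
        d.name: {
            s for s, cfgs in accepted.items() if any(d.contains(c) for c in cfgs)
        }
        for d in designs
    }
    primary_name = max(sorted(coverage), key=lambda nm: len(coverage[nm]))
    primary = next(d for d in designs if d.name == primary_name)
    return OptimalSelection(
        per_subject_best=per_subject_best,
        chosen_designs=tuple(chosen),
        primary_design=primary,
        coverage={d.name: coverage[d.name] for d in chosen} | {primary.name: coverage[primary.name]},
    )


def _minimal_subject_cover(accepted: dict, designs) -> tuple:
    """Exact minimal design set such that every subject has an accepted
    configuration inside some chosen design."""
    cands = sorted(designs, key=lambda d: d.name)
    subjects = sorted(accepted)
    covers = {
        d.name: {s for s in subjects if any(d.contains(c) for c in accepted[s])}
        for d in cands
    }
    cands = [d for d in cands if covers[d.name]]
    for size in range(1, len(cands) + 1):
        for combo in itertools.combinations(cands, size):
            got = set()
            for d in combo:
                got |= covers[d.name]
            if len(got) == len(subjects):
                return combo
    raise ValueError("some subject's optima fit no design")


def hac_cluster(
    matrix: ResponseMatrix,
    axis: str = "subjects",
    vein: str = "LA",
    k_values: Sequence[int] = (4,),
) -> ClusteringResult:
    """Ward2 (ward.D2) hierarchical clustering of the response sub-matrix.

    Rows are subjects (or configurations for ``axis="configurations"``),
    features the AT090 percent reductions at one vein; Euclidean distances
    with Ward's minimum-variance criterion in its distance-input
    (Murtagh-Legendre) form, as implemented by scipy's ``linkage``.
    """
    recs = matrix.records[matrix.records["vein"] == vein]
    if recs.empty:
        raise ValueError(f"no records for vein {vein!r}")
    pivot = recs.pivot_table(
        index="subject", columns="config", values="at090_red_pct", sort=True
    )
    if pivot.isna().any().any():
        raise ValueError("incomplete response sub-matrix")
    if axis == "configurations":
        pivot = pivot.T
    elif axis != "subjects":
        raise ValueError("axis must be subjects or configurations")
    X = pivot.to_numpy()
    if len(X) < 2:
        raise ValueError("need at least two items to cluster")
    Z = linkage(X, method="ward")
    labels = {int(k): fcluster(Z, t=int(k), criterion="maxclust") for k in k_values}
    return ClusteringResult(merge_tree=Z, items=list(pivot.index), labels_at_k=labels)


def cross_cohort_evaluate(
    matrix: ResponseMatrix, design: LeadDesign, cohort: str = "RR+HF"
) -> pd.Series:
    """Per-subject best AT090 % reduction achievable with a fixed design.

    Each subject is evaluated at their best vein, maximising over the
    design's 10 admissible configurations; the result feeds the
    personalised-vs-population comparisons.
    """
    if len(design.electrodes) != 4:
        raise ValueError("design must have exactly 4 electrodes")
    recs = matrix.records
    if cohort != "RR+HF":
        recs = recs[recs["cohort"] == cohort]
    if recs.empty:
        raise ValueError(f"no records for cohort {cohort!r}")
    admissible = set(design.admissible_configurations())
    out = {}
    for subject, g in recs.groupby("subject"):
        vein = _argmax_record(g)["vein"]
        gv = g[(g["vein"] == vein) & (g["config"].isin(admissible))]
        out[subject] = float(gv["at090_red_pct"].max())
    return pd.Series(out, name=f"at090_red_pct[{design.name}]").sort_index()
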