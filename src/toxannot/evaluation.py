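"""Accuracy audit of homology-tier toxin annotation against the venom proteome
and (on synthetic data) against ground truth: Venn regions, false-positive
rates, family-diversity profiles, precision/recall, and intraspecific overlap.
"""

from __future__ import annotations

import json
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .sequence import cluster_by_identity


def venn_counts(sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Exclusive region sizes for 2 or more named sets.

    Region keys are '&'-joined sorted subset names (e.g. ``"lineage&species"``
    counts ids in exactly those two sets and no other).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(sets)
    out: dict[str, int] = {}
    universe = set().union(*sets.values())
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set(universe)
            for n in combo:
                inside &= sets[n]
            for n in names:
                if n not in combo:
                    inside -= sets[n]
            out["&".join(combo)] = len(inside)
    return out


def false_positive_rate(predicted: set[str], proteome: set[str]) -> float:
    """Fraction of predicted toxins absent from the venom proteome."""
    if not predicted:
        raise ValueError("false-positive rate undefined for empty prediction")
    return len(predicted - proteome) / len(predicted)


def family_diversity_profile(
    tier_families: Mapping[str, Sequence[str]],
    proteome_families: Sequence[str],
) -> pd.DataFrame:
    """Per-family percentage of CDSs per tier, with deltas vs. the proteome.

    Deltas are reported both in percentage points and as fold ratios, since
    over/under-representation is discussed in both units. Families absent
    from a tier count as 0%.
    """
    if not proteome_families:
        raise ValueError("empty proteome profile")
    profiles = {"proteome": pd.Series(proteome_families).value_counts(normalize=True) * 100}
    for name, fams in tier_families.items():
        if len(fams) == 0:
            raise ValueError(f"empty tier {name!r}")
        profiles[name] = pd.Series(list(fams)).value_counts(normalize=True) * 100
    all_fams = sorted(set().union(*[set(p.index) for p in profiles.values()]))
    rows = []
    for name, prof in profiles.items():
        for fam in all_fams:
            pct = float(prof.get(fam, 0.0))
            ref = float(profiles["proteome"].get(fam, 0.0))
            fold = pct / ref if ref > 0 else float("inf") if pct > 0 else 1.0
            rows.append((name, fam, pct, pct - ref, fold))
    return pd.DataFrame(rows, columns=["tier", "family", "pct", "delta_pp", "fold"])


def precision_recall(predicted: set[str], truth: set[str]) -> tuple[float, float, float]:
    """Precision, recall and F1 of a predicted toxin id set vs. ground truth."""
    if not predicted:
        raise ValueError("precision undefined for empty prediction")
    tp = len(predicted & truth)
    precision = tp / len(predicted)
    recall = tp / len(truth) if truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return precision, recall, f1


def intraspecific_overlap(
    mature_a: Mapping[str, str],
    mature_b: Mapping[str, str],
    thresholds: Sequence[float] = (0.95, 0.90),
) -> dict[float, int]:
    """Shared-cluster counts between two populations' mature peptides.

    Both populations' signal-peptide-free sequences are pooled and greedily
    clustered at each identity threshold; a cluster is shared iff it contains
    at least one member from each population.
    """
    if not mature_a or not mature_b:
        raise ValueError("both populations must be non-empty")
    overlap = set(mature_a) & set(mature_b)
    if overlap:
        raise ValueError(f"populations share ids: {sorted(overlap)[:5]}")
    pooled = {**mature_a, **mature_b}
    out = {}
    for thr in thresholds:
        clusters = cluster_by_identity(pooled, thr)
        shared = 0
        for cl in clusters:
            has_a = any(m in mature_a for m in cl.member_ids)
            has_b = any(m in mature_b for m in cl.member_ids)
            if has_a and has_b:
                shared += 1
        out[thr] = shared
    return out


# ---------------------------------------------------------------------------
# report

REPORT_SCHEMA = {
    "venn": dict,
    "false_positive_rates": dict,
    "stage_counts": dict,
    "precision_recall": dict,
    "diversity_deltas": list,
    "intraspecific_shared_clusters": dict,
    "detection_expression": list,
    "filter_retention_of_proteome": float,
    "clade_filter": dict,
}


def validate_report(report: dict) -> None:
    """Structural check of a report against the shipped schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing section {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report section {key!r} must be {typ.__name__}")


def build_report(
    venn: dict[str, int],
    fp_rates: dict[str, dict[str, float]],
    stage_counts: dict[str, dict[str, int]],
    precision_recall_table: dict[str, dict[str, float]],
    diversity: pd.DataFrame,
    intraspecific: dict[float, int],
    detection_expression: pd.DataFrame,
    filter_retention: float,
    clade_filter: dict[str, dict],
) -> dict:
    """Assemble the audit report; missing sections raise by name."""
    report = {
        "venn": venn,
        "false_positive_rates": fp_rates,
        "stage_counts": stage_counts,
        "precision_recall": precision_recall_table,
        "diversity_deltas": diversity.round(6).to_dict(orient="records"),
        "intraspecific_shared_clusters": {str(k): v for k, v in intraspecific.items()},
        "detection_expression": detection_expression.round(6).to_dict(orient="records"),
        "filter_retention_of_proteome": filter_retention,
        "clade_filter": clade_filter,
    }
    validate_report(report)
    return report


def write_report(report: dict, path) -> None:
    validate_report(report)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
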