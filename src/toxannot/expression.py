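"""FPKM expression estimation, the comparative-expression filter, and
detection-expression correlation.

The study design is a single venom-gland library against a single muscle
(non-venom) library, without replicates, so the comparative filter is a
deterministic threshold rule — a venom-gland FPKM floor plus a minimum
fold-overexpression over muscle — rather than a statistical test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BACKGROUND_ID = "__background__"  # unannotated transcriptome mass in synthetic counts


@dataclass(frozen=True)
class FilterParams:
    """Comparative-expression filter: venom-gland FPKM floor and fold rule.

    ``pseudocount`` (FPKM units) is added to the muscle denominator so that
    venom-gland-unique transcripts (muscle FPKM 0) can pass the fold rule.
    """

    min_fpkm_vg: float = 100.0
    min_fold: float = 10.0
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.min_fpkm_vg < 0:
            raise ValueError("min_fpkm_vg must be >= 0")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def fpkm(count: float, length_bp: float, library_total: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM = count * 1e9 / (length_bp * library_total); an empty library
    (total 0) yields 0 by convention.
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if library_total < 0:
        raise ValueError("library_total must be >= 0")
    if library_total == 0:
        return 0.0
    return count * 1e9 / (length_bp * library_total)


def expression_table(counts: pd.DataFrame, params: FilterParams | None = None) -> pd.DataFrame:
    """Compute FPKM per tissue from a counts table.

    ``counts`` needs columns id, length_bp, count_vg, count_muscle. Library
    totals are the column sums (including any background row, which absorbs
    the unannotated transcriptome mass in synthetic data). Returns the table
    extended with fpkm_vg, fpkm_muscle, fold and pass_filter columns, with
    the background row dropped.
    """
    params = params or FilterParams()
    total_vg = float(counts["count_vg"].sum())
    total_mu = float(counts["count_muscle"].sum())
    df = counts[counts["id"] != BACKGROUND_ID].copy()
    df["fpkm_vg"] = [fpkm(c, l, total_vg) for c, l in zip(df["count_vg"], df["length_bp"])]
    df["fpkm_muscle"] = [fpkm(c, l, total_mu) for c, l in zip(df["count_muscle"], df["length_bp"])]
    df["fold"] = df["fpkm_vg"] / (df["fpkm_muscle"] + params.pseudocount)
    df["pass_filter"] = (df["fpkm_vg"] >= params.min_fpkm_vg) & (df["fold"] >= params.min_fold)
    return df.reset_index(drop=True)


def expression_filter(records: pd.DataFrame, params: FilterParams | None = None) -> set[str]:
    """Ids passing the comparative-expression filter.

    Retained iff fpkm_vg >= min_fpkm_vg and
    fpkm_vg / (fpkm_muscle + pseudocount) >= min_fold.
    """
    params = params or FilterParams()
    fv = records["fpkm_vg"].to_numpy(dtype=float)
    fm = records["fpkm_muscle"].to_numpy(dtype=float)
    keep = (fv >= params.min_fpkm_vg) & (fv / (fm + params.pseudocount) >= params.min_fold)
    return set(records["id"].to_numpy()[keep])


def spearman(x: Sequence[float], y: Sequence[float], method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with a two-tailed p-value.

    Ties receive average ranks. ``method='t'`` uses the t approximation
    t = r*sqrt((n-2)/(1-r^2)); ``method='exact'`` runs an exact/randomized
    permutation test (intended for n < 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "t":
        res = stats.spearmanr(x, y)
        return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)
    if method == "exact":
        if n > 9:
            raise ValueError("exact permutation p-value supported for n <= 9")
        from itertools import permutations
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        cx = rx - rx.mean()
        denom = np.sqrt((cx ** 2).sum())
        cy = ry - ry.mean()
        denom_y = np.sqrt((cy ** 2).sum())
        r_obs = float(np.dot(cx, cy) / (denom * denom_y))
        perms = np.array(list(permutations(cy)))
        r_all = perms @ cx / (denom * denom_y)
        p = float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))
        return CorrelationResult(r=r_obs, p=p, n=n)
    raise ValueError(f"unknown method {method!r}")


def detection_expression_table(
    annotation_sets: Mapping[str, set[str]],
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Correlation between set membership and expression, per set and tissue.

    For each named id set (venom proteome, each homology tier, ...) the
    0/1 membership indicator over *all* transcriptome ids is correlated
    (Spearman) with FPKM in venom gland and in muscle. Undefined cells
    (constant indicator) are reported with NaN statistics.
    """
    rows = []
    ids = records["id"].tolist()
    for name, members in annotation_sets.items():
        indicator = np.array([1.0 if i in members else 0.0 for i in ids])
        for tissue, col in (("venom_gland", "fpkm_vg"), ("muscle", "fpkm_muscle")):
            try:
                res = spearman(indicator, records[col].to_numpy(dtype=float))
                rows.append((name, tissue, res.r, res.p, res.n))
            except ValueError:
                rows.append((name, tissue, float("nan"), float("nan"), len(ids)))
    return pd.DataFrame(rows, columns=["set", "tissue", "r", "p", "n"])


def family_expression_summary(
    family_of: Mapping[str, str],
    records: pd.DataFrame,
) -> pd.DataFrame:
    """Five-number summary (plus 5/95 percentile whiskers) of FPKM per
    family per tissue, mirroring a per-family expression box plot."""
    df = records[records["id"].isin(family_of)].copy()
    if df.empty:
        raise ValueError("no records match the assignments")
    df["family"] = df["id"].map(family_of)
    rows = []
    for (family, tissue_col, tissue) in (
            (f, c, t) for f in sorted(df["family"].unique())
            for c, t in (("fpkm_vg", "venom_gland"), ("fpkm_muscle", "muscle"))):
        vals = np.sort(df.loc[df["family"] == family, tissue_col].to_numpy(dtype=float))
        q = np.percentile(vals, [0, 5, 25, 50, 75, 95, 100])
        rows.append((family, tissue, len(vals), *q))
    return pd.DataFrame(rows, columns=[
        "family", "tissue", "n", "min", "p5", "q1", "median", "q3", "p95", "max"])


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str})


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
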