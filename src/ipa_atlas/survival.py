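"""IpA-signature survival stratification.

RNA-seq usage proxy for 3'-seq events, signature selection by concordance,
Ward clustering of patients with a k-nearest-neighbour homogeneity filter,
and Kaplan-Meier / log-rank comparison of progression-free survival.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, pearsonr

from .annotation import GeneModel


# ---------------------------------------------------------------------------
# usage proxy from RNA-seq coverage
# ---------------------------------------------------------------------------


def rnaseq_usage_proxy(
    pos: int,
    gene: GeneModel,
    coverage: np.ndarray,
    window: int = 500,
    min_window: int = 50,
) -> float | None:
    """Usage estimate from coverage densities.

    IpA expression is the length-normalized coverage in the ``window`` nt
    upstream of the cleavage site, truncated at the nearest upstream exon and
    requiring at least ``min_window`` nt (else missing); full-length
    expression is the density over the first ``window`` nt of the last coding
    exon. Returns IpA / (IpA + FL)."""
    intron = None
    for s, e in gene.introns:
        if s <= pos < e:
            intron = (s, e)
            break
    if intron is None:
        return None
    if gene.strand == "+":
        lo = max(intron[0], pos - window)
        ipa_win = (lo, pos)
    else:
        hi = min(intron[1], pos + 1 + window)
        ipa_win = (pos + 1, hi)
    if ipa_win[1] - ipa_win[0] < min_window:
        return None
    ipa_dens = float(coverage[ipa_win[0] : ipa_win[1]].mean())
    if not gene.cds:
        return None
    last_cds = gene.cds[-1] if gene.strand == "+" else gene.cds[0]
    # clip the window to the containing exon so the density is not diluted
    # with positions the transcript never covers
    if gene.strand == "+":
        exon_end = next(e for s, e in gene.exons if s <= last_cds[0] < e)
        fl_win = (last_cds[0], min(last_cds[0] + window, exon_end, coverage.size))
    else:
        exon_start = next(s for s, e in gene.exons if s < last_cds[1] <= e)
        fl_win = (max(0, last_cds[1] - window, exon_start), last_cds[1])
    fl_dens = float(coverage[fl_win[0] : fl_win[1]].mean())
    if ipa_dens + fl_dens == 0:
        return None
    return ipa_dens / (ipa_dens + fl_dens)


def proxy_concordance(
    proxy_usage: pd.DataFrame, threeprime_usage: pd.DataFrame
) -> pd.Series:
    """Pearson r between the RNA-seq proxy and 3'-seq usage per event over
    shared calibration samples; needs >=3 samples."""
    shared = [s for s in proxy_usage.columns if s in threeprime_usage.columns]
    if len(shared) < 3:
        raise ValueError("need >=3 calibration samples for correlation")
    out = {}
    for eid in proxy_usage.index:
        if eid not in threeprime_usage.index:
            continue
        a = proxy_usage.loc[eid, shared].astype(float)
        b = threeprime_usage.loc[eid, shared].astype(float)
        mask = a.notna() & b.notna()
        if mask.sum() < 3 or a[mask].std() == 0 or b[mask].std() == 0:
            out[eid] = np.nan
            continue
        out[eid] = float(pearsonr(a[mask], b[mask])[0])
    return pd.Series(out, name="pearson_r")


def select_signature_events(
    diff_results: pd.DataFrame,
    concordance: pd.Series,
    fdr_threshold: float = 0.05,
    min_delta: float = 0.25,
    min_r: float = 0.75,
) -> list[str]:
    """Events with FDR < 0.05, |delta usage| > 0.25 and proxy concordance
    r > 0.75."""
    keep = []
    for eid, row in diff_results.iterrows():
        r = concordance.get(eid, np.nan)
        if (
            row["fdr"] < fdr_threshold
            and abs(row["delta_usage"]) > min_delta
            and not np.isnan(r)
            and r > min_r
        ):
            keep.append(eid)
    return keep


# ---------------------------------------------------------------------------
# clustering + kNN filter
# ---------------------------------------------------------------------------


def cluster_and_filter_patients(
    usage: pd.DataFrame,
    k: int = 2,
    knn: int = 5,
    agreement: float = 0.8,
) -> pd.DataFrame:
    """Ward-linkage clustering of patients on signature usage, labels ordered
    by median usage (A = lowest), then a single-pass kNN homogeneity filter:
    a patient is retained when at least ceil(agreement*knn) of its nearest
    neighbours (self excluded) share its group."""
    if usage.index.duplicated().any():
        raise ValueError("duplicate patient rows")
    if len(usage) < k + knn:
        raise ValueError("too few patients for clustering + kNN filter")
    x = usage.to_numpy(dtype=float)
    z = linkage(x, method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    med = {c: float(np.median(x[raw == c])) for c in np.unique(raw)}
    order = sorted(med, key=med.get)
    letters = [chr(ord("A") + i) for i in range(len(order))]
    relabel = {c: letters[i] for i, c in enumerate(order)}
    groups = np.array([relabel[c] for c in raw])

    d = squareform(pdist(x))
    np.fill_diagonal(d, np.inf)
    need = int(np.ceil(agreement * knn))
    retained = np.zeros(len(usage), dtype=bool)
    for i in range(len(usage)):
        nn = np.argsort(d[i], kind="stable")[:knn]
        retained[i] = int(np.sum(groups[nn] == groups[i])) >= need
    return pd.DataFrame(
        {"group": groups, "retained": retained}, index=usage.index
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier estimator; rows at each distinct event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = times.size
    out = []
    at_risk = n
    s = 1.0
    i = 0
    while i < n:
        t = times[i]
        d = removed = 0
        while i < n and times[i] == t:
            removed += 1
            d += events[i]
            i += 1
        if d > 0:
            s *= 1.0 - d / at_risk
        out.append({"time": t, "n_at_risk": at_risk, "n_events": d, "survival": s})
        at_risk -= removed
    return pd.DataFrame(out)


def logrank_test(
    times1: np.ndarray,
    events1: np.ndarray,
    times2: np.ndarray,
    events2: np.ndarray,
) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p-value)."""
    t = np.concatenate([times1, times2]).astype(float)
    e = np.concatenate([events1, events2]).astype(int)
    g = np.concatenate([np.zeros(len(times1), int), np.ones(len(times2), int)])
    if len(times1) == 0 or len(times2) == 0:
        raise ValueError("both groups must be non-empty")
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & (g == 0)).sum()
        d = ((t == et) & (e == 1)).sum()
        d1 = ((t == et) & (e == 1) & (g == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(chi2.sf(stat, df=1))


def km_logrank(
    cohort: pd.DataFrame,
    group_col: str = "group",
    time_col: str = "pfs_days",
    event_col: str = "event",
) -> dict:
    """KM curves per group plus the two-group log-rank test."""
    groups = sorted(cohort[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected 2 groups, got {groups}")
    curves = {}
    for gname in groups:
        sub = cohort[cohort[group_col] == gname]
        if len(sub) == 0 or sub[event_col].sum() == 0:
            raise ValueError(f"group {gname} has no events")
        curves[gname] = km_curve(sub[time_col].to_numpy(), sub[event_col].to_numpy())
    a = cohort[cohort[group_col] == groups[0]]
    b = cohort[cohort[group_col] == groups[1]]
    stat, p = logrank_test(
        a[time_col].to_numpy(), a[event_col].to_numpy(),
        b[time_col].to_numpy(), b[event_col].to_numpy(),
    )
    return {"curves": curves, "statistic": stat, "p": p, "groups": groups}
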