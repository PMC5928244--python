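"""Differential IpA usage between two conditions.

For each IpA event, the event's counts and the gene's pooled full-length
(3'UTR) counts are modelled across samples with a negative-binomial GLM
(log link, library-size offsets) and the isoform x condition interaction is
tested by a likelihood-ratio test — the DEXSeq-style usage test on a
two-isoform reduction. Dispersion is estimated per event by a Cox-Reid
adjusted profile likelihood with a method-of-moments fallback.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2, ks_2samp

from ._stats import bh_adjust
from .atlas import Atlas

_DISPERSION_FLOOR = 1e-4
_DISPERSION_CEIL = 5.0


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    r = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-scoring fit of a log-link NB GLM; returns (beta, mu)."""
    mu = y + 0.5
    eta = np.log(mu) - offset
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / mu
        xtw = X.T * w
        beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        eta_new = X @ beta_new
        mu_new = np.exp(np.clip(eta_new + offset, -30, 30))
        delta = np.max(np.abs(beta_new - beta)) if np.all(np.isfinite(beta_new)) else np.inf
        beta, eta, mu = beta_new, eta_new, mu_new
        if delta < tol:
            break
    if not np.all(np.isfinite(mu)):
        raise np.linalg.LinAlgError("NB IRLS diverged")
    return beta, mu


def _cr_apl(alpha: float, y, X, offset) -> float:
    """Cox-Reid adjusted profile log-likelihood at a given dispersion."""
    _, mu = _irls_nb(y, X, offset, alpha)
    w = mu / (1.0 + alpha * mu)
    xtwx = (X.T * w) @ X
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular information matrix")
    return _nb_loglik(np.asarray(y, float), mu, alpha) - 0.5 * logdet


def _moment_dispersion(y: np.ndarray, groups: np.ndarray, size: np.ndarray) -> float:
    """Method-of-moments dispersion pooled over isoform x condition cells."""
    vals = []
    norm = y / size
    for g in np.unique(groups):
        sub = norm[groups == g]
        if sub.size < 2:
            continue
        m = sub.mean()
        if m <= 0:
            continue
        vals.append((sub.var(ddof=1) - m) / (m * m))
    if not vals:
        return _DISPERSION_FLOOR
    return float(np.clip(np.mean(vals), _DISPERSION_FLOOR, _DISPERSION_CEIL))


def estimate_dispersion_cr(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, groups: np.ndarray
) -> float:
    """Maximize the CR-adjusted profile likelihood over log-dispersion,
    falling back to the moment estimate if the optimization fails."""
    size = np.exp(offset - offset.mean())
    fallback = _moment_dispersion(y, groups, size)
    try:
        res = minimize_scalar(
            lambda la: -_cr_apl(np.exp(la), y, X, offset),
            bounds=(np.log(_DISPERSION_FLOOR), np.log(_DISPERSION_CEIL)),
            method="bounded",
            options={"xatol": 1e-2},
        )
        if not res.success or not np.isfinite(res.fun):
            return fallback
        return float(np.clip(np.exp(res.x), _DISPERSION_FLOOR, _DISPERSION_CEIL))
    except np.linalg.LinAlgError:
        return fallback


def _design(ipa: np.ndarray, fl: np.ndarray, lib: np.ndarray, cond: np.ndarray):
    y = np.concatenate([fl, ipa]).astype(float)
    iso = np.concatenate([np.zeros_like(fl), np.ones_like(ipa)]).astype(float)
    cc = np.concatenate([cond, cond]).astype(float)
    offset = np.log(np.concatenate([lib, lib]).astype(float))
    X_full = np.column_stack([np.ones_like(y), iso, cc, iso * cc])
    groups = (2 * iso + cc).astype(int)
    return y, X_full, offset, groups


def event_dispersion(
    ipa: np.ndarray,
    fl: np.ndarray,
    lib: np.ndarray,
    cond: np.ndarray,
    dispersion: str = "cr",
) -> float | None:
    """Per-event dispersion estimate (CR-APL or moments); None on failure."""
    y, X_full, offset, groups = _design(ipa, fl, lib, cond)
    if y.sum() == 0:
        return None
    try:
        if dispersion == "cr":
            return estimate_dispersion_cr(y, X_full, offset, groups)
        return _moment_dispersion(y, groups, np.exp(offset - offset.mean()))
    except np.linalg.LinAlgError:
        return None


def test_interaction(
    ipa: np.ndarray,
    fl: np.ndarray,
    lib: np.ndarray,
    cond: np.ndarray,
    dispersion: str = "cr",
    alpha: float | None = None,
) -> tuple[float, float] | None:
    """LRT p-value of the isoform x condition interaction for one event.

    ``ipa``/``fl`` are count vectors over samples, ``lib`` the adjusted
    library sizes, ``cond`` a 0/1 condition indicator. ``alpha`` fixes the
    dispersion; otherwise it is estimated per event. Returns (p, alpha) or
    None when the event is untestable (all-zero or singular)."""
    y, X_full, offset, _groups = _design(ipa, fl, lib, cond)
    if y.sum() == 0:
        return None
    if alpha is None:
        alpha = event_dispersion(ipa, fl, lib, cond, dispersion)
        if alpha is None:
            return None
    X_null = X_full[:, :3]
    try:
        _, mu_full = _irls_nb(y, X_full, offset, alpha)
        _, mu_null = _irls_nb(y, X_null, offset, alpha)
    except np.linalg.LinAlgError:
        return None
    lrt = 2.0 * (_nb_loglik(y, mu_full, alpha) - _nb_loglik(y, mu_null, alpha))
    lrt = max(lrt, 0.0)
    return float(chi2.sf(lrt, df=1)), alpha


def fit_differential_usage(
    ipa_counts: pd.DataFrame,
    fl_counts: pd.DataFrame,
    conditions: Mapping[str, str],
    lib_sizes: pd.Series,
    fdr_threshold: float = 0.05,
    dispersion: str = "cr",
    share_dispersion: bool = True,
) -> pd.DataFrame:
    """Per-event interaction test plus usage and fold-change summaries.

    ``ipa_counts`` and ``fl_counts`` share an event index and sample columns;
    ``conditions`` maps samples to exactly two condition labels (sorted order
    defines the contrast direction: delta = second minus first). With
    ``share_dispersion`` each event's dispersion is floored at the median of
    the per-event estimates, damping the anti-conservativeness of noisy
    12-observation estimates."""
    samples = list(ipa_counts.columns)
    labels = sorted(set(conditions[s] for s in samples))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {labels}")
    cond = np.array([0 if conditions[s] == labels[0] else 1 for s in samples])
    if min((cond == 0).sum(), (cond == 1).sum()) < 2:
        raise ValueError("need >=2 samples per condition")
    lib = lib_sizes.reindex(samples).to_numpy(dtype=float)

    tpm_ipa = ipa_counts.to_numpy(dtype=float) / lib * 1e6
    tpm_fl = fl_counts.to_numpy(dtype=float) / lib * 1e6
    with np.errstate(invalid="ignore", divide="ignore"):
        u = tpm_ipa / (tpm_ipa + tpm_fl)

    alphas = [
        event_dispersion(
            ipa_counts.iloc[i].to_numpy(),
            fl_counts.iloc[i].to_numpy(),
            lib,
            cond,
            dispersion=dispersion,
        )
        for i in range(len(ipa_counts))
    ]
    if share_dispersion:
        known = [a for a in alphas if a is not None]
        floor = float(np.median(known)) if known else _DISPERSION_FLOOR
        alphas = [None if a is None else max(a, floor) for a in alphas]

    rows = []
    for i, eid in enumerate(ipa_counts.index):
        res = (
            None
            if alphas[i] is None
            else test_interaction(
                ipa_counts.iloc[i].to_numpy(),
                fl_counts.iloc[i].to_numpy(),
                lib,
                cond,
                alpha=alphas[i],
            )
        )
        ua = float(np.nanmean(u[i, cond == 0])) if np.any(~np.isnan(u[i, cond == 0])) else np.nan
        ub = float(np.nanmean(u[i, cond == 1])) if np.any(~np.isnan(u[i, cond == 1])) else np.nan
        pc = 0.1
        ipa_lfc = float(
            np.log2((tpm_ipa[i, cond == 1].mean() + pc) / (tpm_ipa[i, cond == 0].mean() + pc))
        )
        fl_lfc = float(
            np.log2((tpm_fl[i, cond == 1].mean() + pc) / (tpm_fl[i, cond == 0].mean() + pc))
        )
        rows.append(
            {
                "event_id": eid,
                "usage_" + labels[0]: ua,
                "usage_" + labels[1]: ub,
                "delta_usage": ub - ua,
                "p": res[0] if res else np.nan,
                "dispersion": res[1] if res else np.nan,
                "tested": res is not None,
                "ipa_lfc": ipa_lfc,
                "fl_lfc": fl_lfc,
            }
        )
    out = pd.DataFrame(rows).set_index("event_id")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    sig = out["fdr"] < fdr_threshold
    out["direction"] = np.where(
        sig & (out["delta_usage"] > 0), "UP", np.where(sig & (out["delta_usage"] < 0), "DOWN", "NS")
    )
    return out


def usage_test_inputs(atlas: Atlas) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Assemble (IpA counts, pooled full-length counts, gene map) from an
    atlas; IpA events of genes without a surviving 3'UTR event are dropped."""
    ipa = atlas.events[atlas.events["klass"] == "IPA"]
    utr = atlas.events[atlas.events["klass"] == "UTR3"]
    fl_by_gene = {
        gid: atlas.counts.loc[sub.index].sum(axis=0) for gid, sub in utr.groupby("gene_id")
    }
    keep = [eid for eid in ipa.index if ipa.loc[eid, "gene_id"] in fl_by_gene]
    ipa_counts = atlas.counts.loc[keep]
    fl_counts = pd.DataFrame(
        [fl_by_gene[ipa.loc[eid, "gene_id"]] for eid in keep], index=ipa_counts.index
    )
    genes = ipa.loc[keep, "gene_id"]
    return ipa_counts, fl_counts, genes


def full_length_shift_test(
    results: pd.DataFrame, direction: str = "UP"
) -> tuple[float, float] | None:
    """One-sided two-sample KS test: full-length fold changes of significant
    events in ``direction`` are stochastically lower than those of NS events.
    Returns (statistic, p) or None when either group has <5 events."""
    grp = results.loc[results["direction"] == direction, "fl_lfc"].dropna()
    ns = results.loc[results["direction"] == "NS", "fl_lfc"].dropna()
    if len(grp) < 5 or len(ns) < 5:
        return None
    res = ks_2samp(grp, ns, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def select_multi_event_representative(
    results: pd.DataFrame, genes: pd.Series
) -> pd.DataFrame:
    """One event per gene: smallest p, ties broken by larger |delta usage|."""
    df = results.join(genes.rename("gene_id"))
    df = df.assign(_absd=df["delta_usage"].abs())
    df = df.sort_values(["p", "_absd"], ascending=[True, False], kind="mergesort")
    out = df.groupby("gene_id", sort=True).head(1).drop(columns="_absd")
    return out
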