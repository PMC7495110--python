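"""Two-group inference on dynamics measures.

Permutation tests on the difference of group means (two-tailed, add-one p
estimator), Benjamini-Hochberg FDR within explicit measure families, Hedges'
g effect sizes (patients minus controls), and Spearman correlations between
clinical scores and dynamic measures in the patient group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import StateMetrics

logger = logging.getLogger(__name__)

_PERM_CHUNK = 20_000


@dataclass
class PermutationResult:
    p_value: float
    observed_diff: float
    n_perm: int


def _welch_t(sum_a, sumsq_a, n_a, sum_b, sumsq_b, n_b):
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    var_a = (sumsq_a - n_a * mean_a**2) / (n_a - 1)
    var_b = (sumsq_b - n_b * mean_b**2) / (n_b - 1)
    denom = np.sqrt(var_a / n_a + var_b / n_b)
    return np.divide(mean_a - mean_b, denom, out=np.zeros_like(denom), where=denom > 0)


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 100_000,
    seed: int = 0,
    statistic: str = "mean_diff",
) -> PermutationResult:
    """Two-tailed permutation test on the difference of group means.

    ``p = (1 + #{|perm stat| >= |observed|}) / (n_perm + 1)``, so p is never 0
    and never below ``1/(n_perm + 1)``.  ``statistic="t"`` permutes a Welch
    t-statistic instead of the raw mean difference; ``observed_diff`` always
    reports the plain difference of means.
    """
    if statistic not in ("mean_diff", "t"):
        raise ValueError("statistic must be 'mean_diff' or 't'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 finite values after exclusions")
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    n_b = n - n_a
    total, total_sq = pooled.sum(), (pooled**2).sum()
    if statistic == "t":
        observed_stat = float(
            _welch_t(a.sum(), (a**2).sum(), n_a, b.sum(), (b**2).sum(), n_b)
        )
    else:
        observed_stat = observed
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        chunk = min(_PERM_CHUNK, n_perm - done)
        # random subsets of size n_a via argpartition of uniforms
        u = rng.random((chunk, n))
        take = np.argpartition(u, n_a - 1, axis=1)[:, :n_a]
        sum_a = pooled[take].sum(axis=1)
        if statistic == "t":
            sumsq_a = (pooled[take] ** 2).sum(axis=1)
            stat = _welch_t(sum_a, sumsq_a, n_a, total - sum_a, total_sq - sumsq_a, n_b)
        else:
            stat = sum_a / n_a - (total - sum_a) / n_b
        exceed += int((np.abs(stat) >= abs(observed_stat) - 1e-12).sum())
        done += chunk
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(p_value=p, observed_diff=float(observed), n_perm=n_perm)


def hedges_g(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Bias-corrected standardized mean difference (a minus b).

    ``g = J * (mean_a - mean_b) / s_pooled`` with
    ``J = 1 - 3 / (4(n_a + n_b) - 9)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 finite values")
    s2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n_a + n_b - 2)
    if s2 == 0:
        raise ValueError("zero pooled standard deviation")
    d = (a.mean() - b.mean()) / np.sqrt(s2)
    j = 1.0 - 3.0 / (4.0 * (n_a + n_b) - 9.0)
    return float(j * d)


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values).

    Adjusted values are monotone in the sorted order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adjusted_sorted, 0, 1)
    reject = adjusted <= alpha
    return reject, adjusted


def spearman_corr(
    x: np.ndarray, y: np.ndarray, n_perm: int | None = None, seed: int = 0
) -> tuple[float, float]:
    """Spearman rho (mid-rank Pearson) with a large-sample p, or a seeded
    permutation p when ``n_perm`` is given (preferred at small n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    if n_perm is not None:
        rng = np.random.default_rng(seed)
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        perm_rho = np.array(
            [np.corrcoef(rx, rng.permutation(ry))[0, 1] for _ in range(n_perm)]
        )
        p = (1 + int((np.abs(perm_rho) >= abs(rho) - 1e-12).sum())) / (n_perm + 1)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# full analysis plan

def _measure_frame(metrics: list[StateMetrics], k: int) -> pd.DataFrame:
    """Per-subject measure table with FDR family labels."""
    rows = []
    for m in metrics:
        row = {"subject_id": m.subject_id}
        for s in range(k):
            row[f"ft_state_{s + 1}"] = m.ft[s]
            row[f"mdt_state_{s + 1}"] = m.mdt[s]
            row[f"visits_state_{s + 1}"] = float(m.visits[s])
        row["n_transitions"] = float(m.n_transitions)
        for a in range(k):
            for b in range(k):
                if a != b:
                    row[f"trans_{a + 1}_to_{b + 1}"] = float(m.specific[a, b])
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def run_group_analysis(
    patient_metrics: list[StateMetrics],
    control_metrics: list[StateMetrics],
    k: int,
    clinical: pd.DataFrame | None = None,
    n_perm: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
    mdt_absent_as_zero: bool = False,
) -> pd.DataFrame:
    """Compare every dynamics measure between groups.

    FT and MDT are each FDR-corrected as a family of size k; total
    transitions, visits, and the k(k-1) specific transitions are reported
    uncorrected.  Differences and g are patients minus controls.  Subjects
    with an undefined MDT (state never visited) are excluded pairwise and the
    exclusion counts are recorded (``mdt_absent_as_zero=True`` scores absences
    as dwell 0 instead).  Returns one row per measure; clinical Spearman
    correlations (patients only) are appended when ``clinical`` has any of the
    columns cgi/bdi/bai.
    """
    if not patient_metrics or not control_metrics:
        raise ValueError("metrics for both groups are required")
    pat = _measure_frame(patient_metrics, k)
    con = _measure_frame(control_metrics, k)
    if mdt_absent_as_zero:
        mdt_cols = [c for c in pat.columns if c.startswith("mdt_state_")]
        pat[mdt_cols] = pat[mdt_cols].fillna(0.0)
        con[mdt_cols] = con[mdt_cols].fillna(0.0)
    families = {f"ft_state_{s + 1}": "ft" for s in range(k)}
    families.update({f"mdt_state_{s + 1}": "mdt" for s in range(k)})
    rows = []
    rng = np.random.default_rng(seed)
    for col in pat.columns:
        a = pat[col].to_numpy()
        b = con[col].to_numpy()
        fin_a, fin_b = np.isfinite(a), np.isfinite(b)
        row = {
            "measure": col,
            "family": families.get(col, "uncorrected"),
            "n_patient": int(fin_a.sum()),
            "n_control": int(fin_b.sum()),
            "excluded": int((~fin_a).sum() + (~fin_b).sum()),
            "mean_patient": float(np.nanmean(a)) if fin_a.any() else np.nan,
            "mean_control": float(np.nanmean(b)) if fin_b.any() else np.nan,
            "sd_patient": float(np.nanstd(a, ddof=1)) if fin_a.sum() > 1 else np.nan,
            "sd_control": float(np.nanstd(b, ddof=1)) if fin_b.sum() > 1 else np.nan,
            "n_perm": n_perm,
        }
        test_seed = int(rng.integers(2**31))
        try:
            res = permutation_test(a, b, n_perm=n_perm, seed=test_seed)
            row["diff"] = res.observed_diff
            row["p"] = res.p_value
            row["note"] = ""
        except ValueError as exc:
            row.update({"diff": np.nan, "p": np.nan, "note": f"not computable: {exc}"})
        try:
            row["g"] = hedges_g(a, b)
        except ValueError:
            row["g"] = np.nan
        rows.append(row)
    report = pd.DataFrame(rows)
    report["q"] = np.nan
    for fam in ("ft", "mdt"):
        mask = (report["family"] == fam) & report["p"].notna()
        if mask.any():
            _, adj = fdr_bh(report.loc[mask, "p"].to_numpy(), alpha=alpha)
            report.loc[mask, "q"] = adj
    report["significant"] = np.where(
        report["family"].isin(["ft", "mdt"]), report["q"] <= alpha, report["p"] <= alpha
    )
    if clinical is not None:
        corr = clinical_correlations(pat, clinical, alpha=alpha)
        report = pd.concat([report, corr], ignore_index=True)
    return report


def clinical_correlations(
    patient_measures: pd.DataFrame, clinical: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman correlation of each clinical score with each dynamic measure
    in the patient group, FDR-corrected per score across measures."""
    scores = [c for c in ("cgi", "bdi", "bai") if c in clinical.columns]
    rows = []
    for score in scores:
        joined = patient_measures.join(clinical[score], how="inner")
        for col in patient_measures.columns:
            row = {
                "measure": f"spearman[{score} ~ {col}]",
                "family": f"clinical_{score}",
                "note": "",
            }
            try:
                rho, p = spearman_corr(joined[score].to_numpy(), joined[col].to_numpy())
                row.update({"rho": rho, "p": p})
            except ValueError as exc:
                row.update({"rho": np.nan, "p": np.nan, "note": f"not computable: {exc}"})
            rows.append(row)
    corr = pd.DataFrame(rows)
    if corr.empty:
        return corr
    corr["q"] = np.nan
    for fam in corr["family"].unique():
        mask = (corr["family"] == fam) & corr["p"].notna()
        if mask.any():
            _, adj = fdr_bh(corr.loc[mask, "p"].to_numpy(), alpha=alpha)
            corr.loc[mask, "q"] = adj
    corr["significant"] = corr["q"] <= alpha
    return corr
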