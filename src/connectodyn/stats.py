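"""Group statistics linking connectome topology, dynamics and cognition.

Covariate-adjusted general-linear-model group comparisons with
Benjamini-Hochberg FDR, Mann-Whitney/Wilcoxon rank tests with a
tie-corrected normal approximation, two-tailed Pearson correlation
inference, Fisher r-to-z comparison of two independent correlations, a
two-variable PCA coupling structural and functional clustering, and a
log-transformed Mahalanobis composite of cognitive deviance from the
control group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "CorrelationDifference",
    "PcaResult",
    "CognitiveComposite",
    "DEFAULT_COMPOSITE_SCORES",
    "glm_group_comparison",
    "fdr_adjust",
    "wilcoxon_rank",
    "pearson_correlation",
    "correlation_pvalue",
    "normal_p_two_tailed",
    "compare_correlations",
    "pca_structure_function",
    "mahalanobis_composite",
    "run_statistical_battery",
]

#: the four cognitive tests that survive FDR in the study conditions
DEFAULT_COMPOSITE_SCORES = ["ravlt_total", "ravlt_interference", "ctmt1", "cowa"]

_MHD_FLOOR = 1e-12


@dataclass
class GroupComparisonResult:
    outcome: str
    f_statistic: float
    p: float
    p_fdr: float | None = None
    covariate_p: dict[str, float] = field(default_factory=dict)
    group_means: dict[str, float] = field(default_factory=dict)


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_two_tailed: float


@dataclass
class CorrelationDifference:
    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p_two_tailed: float


@dataclass
class PcaResult:
    loadings: dict[str, float]
    scores: np.ndarray
    variance_explained: float


@dataclass
class CognitiveComposite:
    subject_ids: list[str]
    distance: np.ndarray
    log_mhd: np.ndarray
    score_names: list[str]


def glm_group_comparison(
    table: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    group_col: str = "group",
) -> GroupComparisonResult:
    """OLS fit ``outcome ~ group + covariates`` with a model-comparison F.

    The group F is the full-versus-reduced (group dropped) comparison, which
    reproduces the type-III GLM F for a single two-level factor regardless of
    coding.  A constant outcome yields F = 0, p = 1 rather than an error.
    """
    covariates = list(covariates or [])
    cols = [outcome, group_col, *covariates]
    data = table.dropna(subset=cols)
    y = data[outcome].to_numpy(dtype=float)
    levels = sorted(data[group_col].unique())
    if len(levels) != 2:
        raise ValueError("group column must have exactly 2 levels")
    g = (data[group_col] == levels[1]).to_numpy(dtype=float)
    x_cov = sm.add_constant(
        data[covariates].to_numpy(dtype=float)
        if covariates
        else np.empty((len(data), 0)),
        has_constant="add",
    )
    x_full = np.column_stack([x_cov, g])
    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        raise ValueError(
            f"rank-deficient design for outcome {outcome!r}: collinear columns "
            f"among {['const', *covariates, group_col]}"
        )
    if np.ptp(y) == 0:
        return GroupComparisonResult(outcome=outcome, f_statistic=0.0, p=1.0)
    full = sm.OLS(y, x_full).fit()
    reduced = sm.OLS(y, x_cov).fit()
    f_stat, p_val, _ = full.compare_f_test(reduced)
    cov_p = {c: float(full.pvalues[i + 1]) for i, c in enumerate(covariates)}
    means = {lev: float(y[(data[group_col] == lev).to_numpy()].mean()) for lev in levels}
    return GroupComparisonResult(
        outcome=outcome,
        f_statistic=float(f_stat),
        p=float(p_val),
        covariate_p=cov_p,
        group_means=means,
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank(x, y) -> tuple[float, float]:
    """Mann-Whitney U with a tie-corrected normal approximation, two-tailed.

    U counts (x, y) pairs with x < y plus half-ties; the z statistic is
    ``(U - n1 n2 / 2) / sd`` with the tie-corrected variance and no
    continuity correction.  All-tied samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u_greater = r1 - n1 * (n1 + 1) / 2.0  # pairs with x > y (+ half ties)
    u = n1 * n2 - u_greater  # pairs with x < y (+ half ties)
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return float(u), 1.0
    z = (u - n1 * n2 / 2.0) / np.sqrt(var)
    return float(u), float(2.0 * sps.norm.sf(abs(z)))


def normal_p_two_tailed(z: float) -> float:
    """Two-tailed standard-normal p for an observed z."""
    return float(2.0 * sps.norm.sf(abs(z)))


def rank_test_pvalue(u: float, n1: int, n2: int) -> float:
    """Two-tailed normal-approximation p for a stated U (no tie correction)."""
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return normal_p_two_tailed((u - n1 * n2 / 2.0) / sd)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r via t = r sqrt(n-2) / sqrt(1-r^2)."""
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def pearson_correlation(x, y) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length samples with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r=r, n=x.size, p_two_tailed=correlation_pvalue(r, x.size))


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> CorrelationDifference:
    """Fisher r-to-z test for the difference of two independent correlations."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both groups")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return CorrelationDifference(
        r1=r1, n1=n1, r2=r2, n2=n2, z=float(z), p_two_tailed=normal_p_two_tailed(z)
    )


def pca_structure_function(
    table: pd.DataFrame,
    structural_col: str = "sc_global_clust",
    functional_col: str = "fc_global_clust",
) -> PcaResult:
    """First principal component of the standardized (structural, functional)
    clustering columns across all participants.

    For two standardized variables with cross-correlation r the leading
    eigenvalue of the correlation matrix is 1 + |r|, so the first component
    explains (1 + |r|)/2 of the variance.  Loadings are oriented so the
    structural loading is positive.
    """
    cols = [structural_col, functional_col]
    data = table.dropna(subset=cols)
    x = data[cols].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column in PCA input")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z.T)
    eigvals, eigvecs = np.linalg.eigh(corr)
    lead = eigvecs[:, -1]
    if lead[0] < 0:
        lead = -lead
    return PcaResult(
        loadings={structural_col: float(lead[0]), functional_col: float(lead[1])},
        scores=z @ lead,
        variance_explained=float(eigvals[-1] / eigvals.sum()),
    )


def mahalanobis_composite(
    patients: pd.DataFrame,
    controls: pd.DataFrame,
    score_names: list[str] | None = None,
) -> CognitiveComposite:
    """Per-patient Mahalanobis distance from the control score distribution.

    Uses the control-group mean and unbiased covariance, so the distance
    measures cognitive deviance from controls; the natural-log transform is
    floored at d = 1e-12 for the degenerate patient-at-control-mean case.
    """
    names = list(score_names or DEFAULT_COMPOSITE_SCORES)
    if len(controls) < len(names) + 2:
        raise ValueError(f"need at least {len(names) + 2} control rows")
    xc = controls[names].to_numpy(dtype=float)
    xp = patients[names].to_numpy(dtype=float)
    mu = xc.mean(axis=0)
    cov = np.cov(xc, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular control covariance; reduce the score set"
        ) from exc
    w = np.linalg.solve(chol, (xp - mu).T)
    d = np.sqrt((w**2).sum(axis=0))
    ids = (
        patients["subject_id"].tolist()
        if "subject_id" in patients.columns
        else [str(i) for i in range(len(patients))]
    )
    return CognitiveComposite(
        subject_ids=ids,
        distance=d,
        log_mhd=np.log(np.maximum(d, _MHD_FLOOR)),
        score_names=names,
    )


def _comparison_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "outcome": [r.outcome for r in results],
            "f_statistic": [r.f_statistic for r in results],
            "p": [r.p for r in results],
            "p_fdr": [r.p_fdr for r in results],
            "mean_patient": [r.group_means.get("patient") for r in results],
            "mean_control": [r.group_means.get("control") for r in results],
        }
    )


def _correlation_rows(table, group, pairs):
    rows = []
    for a, b in pairs:
        sub = table[table["group"] == group].dropna(subset=[a, b])
        res = pearson_correlation(sub[a], sub[b])
        rho, rho_p = sps.spearmanr(sub[a], sub[b])
        rows.append(
            {
                "group": group,
                "x": a,
                "y": b,
                "r": res.r,
                "n": res.n,
                "p": res.p_two_tailed,
                "spearman_rho": float(rho),
                "spearman_p": float(rho_p),
            }
        )
    return rows


def run_statistical_battery(
    table: pd.DataFrame,
    nodal_tables: dict[str, pd.DataFrame] | None = None,
    performance_measures: list[str] | None = None,
    self_report_measures: list[str] | None = None,
    composite_scores: list[str] | None = None,
) -> dict:
    """The full statistical layer over an assembled cohort table.

    Emits (a) cognitive group comparisons with FDR over the performance
    measures (self-report measures analyzed with the CAD covariate but kept
    out of the FDR family), (b) global network-metric comparisons (GLM for
    clustering, rank test for global H), (c) per-region local comparisons
    with FDR per family, (d) within-group correlations among the three global
    metrics with between-group Fisher comparisons, (e) the structure-function
    PCA and its correlation with the log-Mahalanobis cognitive composite in
    patients, and (f) exploratory demographic correlations (uncorrected).

    ``nodal_tables`` maps family name ("fc_local", "sc_local", "hurst_local")
    to a subjects-by-region DataFrame carrying subject_id and group columns.
    """
    from .simulate import PERFORMANCE_MEASURES, SELF_REPORT_MEASURES

    performance = list(performance_measures or PERFORMANCE_MEASURES)
    self_report = list(self_report_measures or SELF_REPORT_MEASURES)
    results: dict = {}

    # (a) cognitive comparisons
    cog = [
        glm_group_comparison(table, m, ["minority", "cad_score"]) for m in performance
    ]
    adj = fdr_adjust([r.p for r in cog])
    for r, q in zip(cog, adj):
        r.p_fdr = float(q)
    cog += [
        glm_group_comparison(table, m, ["minority", "cad_score"]) for m in self_report
    ]
    results["cognitive"] = _comparison_frame(cog)

    # (b) global network metrics
    global_rows = []
    for outcome, covs in [
        ("fc_global_clust", ["minority", "cad_score"]),
        ("sc_global_clust", ["minority", "cad_score", "sc_n_nodes"]),
        ("sc_n_nodes", ["minority", "cad_score"]),
    ]:
        if outcome in table.columns:
            r = glm_group_comparison(table, outcome, covs)
            global_rows.append(
                {
                    "outcome": outcome,
                    "test": "glm_f",
                    "statistic": r.f_statistic,
                    "p": r.p,
                    "mean_patient": r.group_means.get("patient"),
                    "mean_control": r.group_means.get("control"),
                }
            )
    if "global_h" in table.columns:
        pat = table.loc[table["group"] == "patient", "global_h"].dropna()
        ctl = table.loc[table["group"] == "control", "global_h"].dropna()
        u, p = wilcoxon_rank(pat, ctl)
        global_rows.append(
            {
                "outcome": "global_h",
                "test": "wilcoxon_u",
                "statistic": u,
                "p": p,
                "mean_patient": float(pat.mean()),
                "mean_control": float(ctl.mean()),
            }
        )
    results["global_metrics"] = pd.DataFrame(global_rows)

    # (c) per-region local comparisons
    local_frames = {}
    for family, sub in (nodal_tables or {}).items():
        regions = [c for c in sub.columns if c not in ("subject_id", "group")]
        rows = []
        for reg in regions:
            pat = sub.loc[sub["group"] == "patient", reg].dropna()
            ctl = sub.loc[sub["group"] == "control", reg].dropna()
            if len(pat) < 2 or len(ctl) < 2:
                # e.g. a parcel with no cubes in any subject: missing, not zero
                rows.append({"region": reg, "statistic": np.nan, "p": np.nan})
                continue
            if family == "hurst_local":
                stat, p = wilcoxon_rank(pat, ctl)
            else:
                covs = (
                    ["minority", "cad_score"]
                    if {"minority", "cad_score"}.issubset(sub.columns)
                    else []
                )
                res = glm_group_comparison(sub, reg, covs)
                stat, p = res.f_statistic, res.p
            rows.append({"region": reg, "statistic": stat, "p": p})
        frame = pd.DataFrame(rows)
        frame["p_fdr"] = np.nan
        ok = frame["p"].notna()
        if ok.any():
            frame.loc[ok, "p_fdr"] = fdr_adjust(frame.loc[ok, "p"])
        local_frames[family] = frame
    results["local_metrics"] = local_frames

    # (d) within-group correlations + Fisher comparisons
    metric_pairs = [
        ("sc_global_clust", "fc_global_clust"),
        ("sc_global_clust", "global_h"),
        ("fc_global_clust", "global_h"),
    ]
    have = [p_ for p_ in metric_pairs if set(p_).issubset(table.columns)]
    corr_rows = _correlation_rows(table, "patient", have) + _correlation_rows(
        table, "control", have
    )
    results["within_group_correlations"] = pd.DataFrame(corr_rows)
    fisher_rows = []
    for a, b in have:
        rp = next(r for r in corr_rows if r["group"] == "patient" and r["x"] == a and r["y"] == b)
        rc = next(r for r in corr_rows if r["group"] == "control" and r["x"] == a and r["y"] == b)
        diff = compare_correlations(rp["r"], rp["n"], rc["r"], rc["n"])
        fisher_rows.append(
            {
                "x": a,
                "y": b,
                "r_patient": diff.r1,
                "r_control": diff.r2,
                "z": diff.z,
                "p": diff.p_two_tailed,
            }
        )
    results["correlation_differences"] = pd.DataFrame(fisher_rows)

    # (e) PCA + cognitive composite
    if {"sc_global_clust", "fc_global_clust"}.issubset(table.columns):
        pca = pca_structure_function(table)
        results["pca"] = pca
        patients = table[table["group"] == "patient"]
        controls = table[table["group"] == "control"]
        names = list(composite_scores or DEFAULT_COMPOSITE_SCORES)
        if set(names).issubset(table.columns):
            comp = mahalanobis_composite(patients, controls, names)
            results["composite"] = comp
            sub = table.dropna(subset=["sc_global_clust", "fc_global_clust"])
            scores = pd.Series(pca.scores, index=sub["subject_id"].to_numpy())
            pat_scores = scores.reindex(comp.subject_ids)
            ok = pat_scores.notna().to_numpy()
            if ok.sum() >= 4:
                res = pearson_correlation(
                    pat_scores.to_numpy()[ok], comp.log_mhd[ok]
                )
                results["pca_vs_composite"] = res

    # (f) exploratory demographic correlations (uncorrected)
    expl_rows = []
    metrics = [
        c
        for c in ("fc_global_clust", "sc_global_clust", "global_h")
        if c in table.columns
    ]
    pat = table[table["group"] == "patient"]
    for demo in ("cad_score", "minority"):
        for m in metrics:
            sub = pat.dropna(subset=[demo, m])
            if sub[demo].std() == 0 or sub[m].std() == 0 or len(sub) < 4:
                continue
            res = pearson_correlation(sub[demo], sub[m])
            expl_rows.append(
                {
                    "exploratory": True,
                    "x": demo,
                    "y": m,
                    "r": res.r,
                    "n": res.n,
                    "p_uncorrected": res.p_two_tailed,
                }
            )
    results["exploratory"] = pd.DataFrame(expl_rows)
    return results
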