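"""Screening-model evaluation: group tests, ROC, cutoffs, IDI/NRI.

This module reproduces the full evaluation surface of a screening-model
comparison study:

* Mann-Whitney U comparison of marker distributions between groups,
* ROC curves with rank-statistic AUC and stratified-bootstrap CIs,
* Youden-optimal cutoffs,
* the standard 2x2 diagnostic table (DR, PPV, NPV, FPR, FNR, +LR, -LR),
* integrated discrimination improvement (IDI) and continuous net
  reclassification improvement (NRI) between nested models.

AUC uses the midrank (Mann-Whitney) statistic, so tied scores receive
half credit; this equals the trapezoidal area under the empirical ROC
curve.  The AUC confidence interval is a stratified percentile
bootstrap (cases and controls resampled separately, B = 2000 by
default, seeded), with the asymptotic Hanley-McNeil variance available
as an option; the p-value tests H0: AUC = 0.5 with a normal
approximation on the bootstrap standard error.

NRI is category-free (continuous) by default: no risk categories are
published for this model family, and the reported NRI magnitudes are
inconsistent with a coarse two-category scheme.  Categorical NRI with
user-supplied thresholds is provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .markers import AFFECTED_LABEL, AFP_L2, PANEL, mom_column
from .risk import model_id

logger = logging.getLogger(__name__)


def _split(values, labels, positive=AFFECTED_LABEL):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    if not pos.any() or pos.all():
        raise ValueError("labels must contain both classes")
    return values[pos], values[~pos]


def significance_marker(p: float) -> str:
    """Footnote marker: '**' for p<0.05, '*' for p<0.001, '' otherwise."""
    if p < 0.001:
        return "*"
    if p < 0.05:
        return "**"
    return ""


# ---------------------------------------------------------------------
# Mann-Whitney U


def mann_whitney(group_a, group_b, method: str = "asymptotic") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (Z, p).

    The asymptotic path uses the normal approximation with midrank tie
    correction and a 0.5 continuity correction.  ``method="exact"``
    enumerates the permutation null (no ties; small samples), and
    ``"auto"`` picks exact for n_a + n_b <= 12 without ties.  Z is
    signed by the direction of group_a relative to group_b.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    if np.all(tie_counts == tie_counts[0]) and tie_counts[0] == len(pooled):
        warnings.warn("all values tied across both groups", stacklevel=2)
        return 0.0, 1.0

    if method == "auto":
        method = "exact" if (n1 + n2 <= 12 and np.all(tie_counts == 1)) else "asymptotic"

    if method == "exact":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        # report the tie-corrected Z alongside the exact p
        z = _mw_z(u_a, n1, n2, tie_counts)
        return z, p
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    z = _mw_z(u_a, n1, n2, tie_counts)
    return z, float(2.0 * stats.norm.sf(abs(z)))


def _mw_z(u_a: float, n1: int, n2: int, tie_counts: np.ndarray) -> float:
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return 0.0
    # continuity correction toward the mean
    cc = 0.5 * np.sign(u_a - mean_u) if u_a != mean_u else 0.0
    return float((u_a - mean_u - cc) / np.sqrt(var_u))


# ---------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with rank-statistic AUC and bootstrap CI."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    p_value: float


def auc_rank(scores, labels, positive=AFFECTED_LABEL) -> float:
    """AUC as the normalized midrank statistic (ties get half credit)."""
    cases, controls = _split(scores, labels, positive)
    n1, n0 = len(cases), len(controls)
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc(
    scores,
    labels,
    positive=AFFECTED_LABEL,
    n_bootstrap: int = 2000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> ROCResult:
    """ROC curve, AUC, 95% CI and a test of AUC = 0.5.

    The curve enumerates every distinct score as a ">= threshold"
    classification rule, in descending order.  The CI is a stratified
    percentile bootstrap (``ci_method="bootstrap"``) or the
    Hanley-McNeil normal interval (``"asymptotic"``); either interval
    is widened, if necessary, to contain the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases, controls = _split(scores, labels, positive)
    n1, n0 = len(cases), len(controls)

    thresholds = np.unique(scores)[::-1]
    sens = np.array([(cases >= t).mean() for t in thresholds])
    spec = np.array([(controls < t).mean() for t in thresholds])

    point = auc_rank(scores, labels, positive)
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            ca = rng.choice(cases, size=n1, replace=True)
            co = rng.choice(controls, size=n0, replace=True)
            r = stats.rankdata(np.concatenate([ca, co]))
            boots[i] = (r[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        se = float(boots.std(ddof=1))
    elif ci_method == "asymptotic":
        se = _hanley_mcneil_se(point, n1, n0)
        lo, hi = point - 1.959964 * se, point + 1.959964 * se
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(point - 0.5) / se))
    else:
        p = 1.0 if point == 0.5 else 0.0
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=point,
        auc_ci_low=float(min(lo, point)),
        auc_ci_high=float(min(max(hi, point), 1.0)),
        p_value=p,
    )


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------
# Youden cutoff and the 2x2 diagnostic table


@dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float


def youden_optimal(roc_result: ROCResult) -> YoudenResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties in J are broken toward the higher-specificity (more
    conservative) threshold.
    """
    j = roc_result.sensitivity + roc_result.specificity - 1.0
    best = np.lexsort((roc_result.specificity, j))[-1]
    return YoudenResult(
        cutoff=float(roc_result.thresholds[best]),
        youden_j=float(j[best]),
        sensitivity=float(roc_result.sensitivity[best]),
        specificity=float(roc_result.specificity[best]),
    )


@dataclass(frozen=True)
class DiagnosticTable:
    """Screening diagnostics of a ">= cutoff" rule on a 2x2 table."""

    dr: float
    ppv: float
    npv: float
    fpr: float
    fnr: float
    plr: float
    nlr: float
    tp: int
    fn: int
    fp: int
    tn: int


def diagnostic_table(
    scores, labels, cutoff: float, positive=AFFECTED_LABEL
) -> DiagnosticTable:
    """All seven screening metrics at a fixed cutoff (ties positive).

    A positive call is ``score >= cutoff``.  Ratios with an empty
    denominator (e.g. +LR at zero FPR) are reported as NaN with a
    warning, mirroring the "-" convention of printed screening tables.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    cases, controls = _split(scores, labels, positive)
    tp = int((cases >= cutoff).sum())
    fn = len(cases) - tp
    fp = int((controls >= cutoff).sum())
    tn = len(controls) - fp

    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    fpr, fnr = 1.0 - spec, 1.0 - sens

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    return DiagnosticTable(
        dr=sens,
        ppv=_ratio(tp, tp + fp, "PPV"),
        npv=_ratio(tn, tn + fn, "NPV"),
        fpr=fpr,
        fnr=fnr,
        plr=_ratio(sens, fpr, "+LR"),
        nlr=_ratio(fnr, spec, "-LR"),
        tp=tp, fn=fn, fp=fp, tn=tn,
    )


# ---------------------------------------------------------------------
# IDI / NRI


def _as_probabilities(base, ext):
    base = np.asarray(base, dtype=float)
    ext = np.asarray(ext, dtype=float)
    if base.shape != ext.shape:
        raise ValueError("base and extended score vectors differ in length")
    both = np.concatenate([base, ext])
    if both.min() < 0.0 or both.max() > 1.0:
        warnings.warn(
            "scores outside (0,1); min-max rescaling the model pair jointly",
            stacklevel=3,
        )
        lo, hi = both.min(), both.max()
        span = hi - lo if hi > lo else 1.0
        base = (base - lo) / span
        ext = (ext - lo) / span
    return base, ext


def idi(base_scores, ext_scores, labels, positive=AFFECTED_LABEL) -> tuple[float, float]:
    """Integrated discrimination improvement and its p-value.

    IDI is the gain in mean predicted-risk separation between cases and
    controls when moving from the base to the extended model; the test
    is the standard paired-difference normal approximation.
    """
    base, ext = _as_probabilities(base_scores, ext_scores)
    d = ext - base
    d_case, d_ctrl = _split(d, labels, positive)
    value = float(d_case.mean() - d_ctrl.mean())
    se = np.sqrt(
        (d_case.var(ddof=1) / len(d_case) if len(d_case) > 1 else 0.0)
        + (d_ctrl.var(ddof=1) / len(d_ctrl) if len(d_ctrl) > 1 else 0.0)
    )
    if se == 0:
        return value, 1.0 if value == 0 else 0.0
    return value, float(2.0 * stats.norm.sf(abs(value) / se))


def nri(
    base_scores,
    ext_scores,
    labels,
    categories: list[float] | None = None,
    positive=AFFECTED_LABEL,
) -> tuple[float, float]:
    """Net reclassification improvement and its p-value.

    Continuous (category-free) NRI by default: any upward score
    movement in a case and downward movement in a control counts as
    correct reclassification.  With ``categories`` (sorted thresholds)
    the movement is between risk categories instead.  The p-value is
    the usual asymptotic z-test on the two group-wise net proportions.
    """
    base, ext = _as_probabilities(base_scores, ext_scores)
    if categories is not None:
        edges = np.asarray(sorted(categories), dtype=float)
        base = np.digitize(base, edges).astype(float)
        ext = np.digitize(ext, edges).astype(float)
    up = (ext > base).astype(float)
    down = (ext < base).astype(float)
    up_case, up_ctrl = _split(up, labels, positive)
    down_case, down_ctrl = _split(down, labels, positive)

    pu1, pd1 = up_case.mean(), down_case.mean()
    pu0, pd0 = up_ctrl.mean(), down_ctrl.mean()
    value = float((pu1 - pd1) + (pd0 - pu0))
    n1, n0 = len(up_case), len(up_ctrl)
    var = (pu1 + pd1 - (pu1 - pd1) ** 2) / n1 + (pu0 + pd0 - (pd0 - pu0) ** 2) / n0
    if var <= 0:
        return value, 1.0 if value == 0 else 0.0
    return value, float(2.0 * stats.norm.sf(abs(value) / np.sqrt(var)))


# ---------------------------------------------------------------------
# Full report


@dataclass
class EvaluationReport:
    """Tabular evaluation of all marker-subset models.

    ``discrimination``: per model, Youden index, sensitivity,
    specificity, cutoff (risk score and "1 in N" notation), AUC with CI
    and p-value.  ``diagnostics``: per model, the seven screening
    metrics at the Youden cutoff.  ``improvement``: per nested model
    pair, IDI and NRI (percent) with p-values.
    """

    discrimination: pd.DataFrame
    diagnostics: pd.DataFrame
    improvement: pd.DataFrame
    group_comparison: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        from pathlib import Path
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.discrimination.to_csv(outdir / "discrimination.tsv", sep="\t", index=False)
        self.diagnostics.to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)
        self.improvement.to_csv(outdir / "improvement.tsv", sep="\t", index=False)
        if self.group_comparison is not None:
            self.group_comparison.to_csv(
                outdir / "group_comparison.tsv", sep="\t", index=False
            )
        summary = {
            "config": self.config,
            "discrimination": self.discrimination.to_dict(orient="records"),
            "diagnostics": self.diagnostics.to_dict(orient="records"),
            "improvement": self.improvement.to_dict(orient="records"),
        }
        if self.group_comparison is not None:
            summary["group_comparison"] = self.group_comparison.to_dict(
                orient="records"
            )
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)


def group_comparison(cohort: pd.DataFrame, positive=AFFECTED_LABEL) -> pd.DataFrame:
    """Per-marker group summaries and Mann-Whitney tests.

    One row per marker: median (P2.5-P97.5) in each group, the
    tie-corrected Z and the two-sided p.
    """
    rows = []
    labels = cohort["group"].to_numpy()
    for marker in PANEL:
        col = mom_column(marker)
        if col not in cohort.columns:
            continue
        values = cohort[col].to_numpy(dtype=float)
        cases, controls = _split(values, labels, positive)
        z, p = mann_whitney(cases, controls)
        row = {"marker": marker}
        for name, grp in (("case", cases), ("control", controls)):
            q = np.percentile(grp, [2.5, 50, 97.5])
            row[f"{name}_median"] = q[1]
            row[f"{name}_p2_5"] = q[0]
            row[f"{name}_p97_5"] = q[2]
        row.update({"z": z, "p_value": p, "signif": significance_marker(p)})
        rows.append(row)
    return pd.DataFrame(rows)


def improvement_pairs(
    model_ids: list[str], added_marker: str = AFP_L2
) -> list[tuple[str, str]]:
    """Nested pairs (M, M + added_marker) present in ``model_ids``.

    For the 4-marker panel with AFP-L2 as the added marker this yields
    the 7 comparisons of every AFP-L2-free model against its AFP-L2
    extension.
    """
    pairs = []
    for mid in model_ids:
        markers = tuple(mid.split("+"))
        if added_marker in markers:
            continue
        ext = model_id(
            tuple(m for m in PANEL if m in markers or m == added_marker)
        )
        if ext in model_ids:
            pairs.append((mid, ext))
    return pairs


def evaluate_all(
    score_table: pd.DataFrame,
    labels: pd.Series | np.ndarray | dict,
    positive=AFFECTED_LABEL,
    n_bootstrap: int = 2000,
    seed: int = 0,
    nri_categories: list[float] | None = None,
    added_marker: str = AFP_L2,
) -> EvaluationReport:
    """Evaluate every model in a long score table.

    ``score_table`` is the output of :func:`triscreen.risk.score_cohort`
    (columns ``subject_id, model_id, risk_probability``); ``labels``
    maps subject_id to outcome group (dict / Series) or is a vector
    aligned with the unique subjects in first-appearance order.
    """
    wide = score_table.pivot(
        index="subject_id", columns="model_id", values="risk_probability"
    )
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"score table has missing scores for models {missing}")
    # restore first-appearance subject order
    order = score_table["subject_id"].drop_duplicates().to_numpy()
    wide = wide.loc[order]

    if isinstance(labels, dict):
        y = np.array([labels[s] for s in wide.index])
    elif isinstance(labels, pd.Series):
        y = labels.reindex(wide.index).to_numpy()
    else:
        y = np.asarray(labels)
        if len(y) != len(wide):
            raise ValueError("labels length does not match number of subjects")

    model_order = score_table["model_id"].drop_duplicates().tolist()

    disc_rows, diag_rows = [], []
    for mid in model_order:
        scores = wide[mid].to_numpy()
        r = roc(scores, y, positive, n_bootstrap=n_bootstrap, seed=seed)
        yj = youden_optimal(r)
        dt = diagnostic_table(scores, y, yj.cutoff, positive)
        disc_rows.append(
            {
                "model_id": mid,
                "youden_index": yj.youden_j,
                "sensitivity": yj.sensitivity,
                "specificity": yj.specificity,
                "cutoff": yj.cutoff,
                "cutoff_one_in_n": 1.0 / yj.cutoff if yj.cutoff > 0 else np.inf,
                "auc": r.auc,
                "auc_ci_low": r.auc_ci_low,
                "auc_ci_high": r.auc_ci_high,
                "p_value": r.p_value,
                "signif": significance_marker(r.p_value),
            }
        )
        diag_rows.append(
            {
                "model_id": mid,
                "dr": dt.dr, "ppv": dt.ppv, "npv": dt.npv,
                "fpr": dt.fpr, "fnr": dt.fnr, "plr": dt.plr, "nlr": dt.nlr,
            }
        )

    imp_rows = []
    for base_id, ext_id in improvement_pairs(model_order, added_marker):
        b = wide[base_id].to_numpy()
        e = wide[ext_id].to_numpy()
        idi_v, idi_p = idi(b, e, y, positive)
        nri_v, nri_p = nri(b, e, y, nri_categories, positive)
        imp_rows.append(
            {
                "baseline_model_id": base_id,
                "extended_model_id": ext_id,
                "idi_percent": 100.0 * idi_v,
                "idi_p": idi_p,
                "idi_signif": significance_marker(idi_p),
                "nri_percent": 100.0 * nri_v,
                "nri_p": nri_p,
                "nri_signif": significance_marker(nri_p),
            }
        )

    return EvaluationReport(
        discrimination=pd.DataFrame(disc_rows),
        diagnostics=pd.DataFrame(diag_rows),
        improvement=pd.DataFrame(imp_rows),
        config={
            "n_bootstrap": n_bootstrap,
            "seed": seed,
            "nri_categories": nri_categories,
            "positive_label": str(positive),
        },
    )
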