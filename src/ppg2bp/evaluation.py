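"""Cross-validated evaluation, agreement analysis and BP grading.

Metrics
-------
MSE, RMSE, MAE and MAPE follow their standard definitions; R² is the
coefficient of determination 1 − SSE/SST with SST taken about the mean of
the observed targets. Headline numbers are computed on the pooled
out-of-fold predictions of a shuffled k-fold split; per-fold values are
retained so dispersion across folds can be inspected.

Agreement
---------
Bland–Altman statistics use the predicted-minus-actual sign convention and
±1.96·SD limits of agreement (sample SD, n−1 denominator). Correlation is
the Pearson product-moment coefficient.

Grading
-------
:func:`classify_bp_grade` maps an (SBP, DBP) pair to the British
Hypertension Society category. Hypertension grades take precedence over the
normotensive bands, the higher of the SBP- and DBP-implied grades wins, and
isolated systolic hypertension (SBP ≥ 140 with DBP < 90) is labelled
separately.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .regression import BPRegression, ModelSpec, _as_spec

__all__ = [
    "metrics",
    "cross_validate",
    "EvaluationReport",
    "BlandAltman",
    "bland_altman",
    "correlation",
    "classify_bp_grade",
    "export_report",
    "evaluate_models",
]


def metrics(y, yhat) -> dict[str, float]:
    """MSE, RMSE, MAE, MAPE (%) and R² of predictions against references.

    MAPE is NaN (undefined) when any reference value is zero; the other
    metrics are still returned.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if len(y) != len(yhat):
        raise ValueError(f"length mismatch: {len(y)} references, {len(yhat)} predictions")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    err = y - yhat
    mse = float(np.mean(err**2))
    out = {
        "MSE": mse,
        "RMSE": float(np.sqrt(mse)),
        "MAE": float(np.mean(np.abs(err))),
    }
    if np.any(y == 0):
        out["MAPE"] = float("nan")  # undefined: zero reference value
    else:
        out["MAPE"] = float(np.mean(np.abs(err / y)) * 100.0)
    sst = float(np.sum((y - y.mean()) ** 2))
    out["R2"] = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else float("nan")
    return out


@dataclass
class BlandAltman:
    """Agreement statistics between predicted and reference pressures."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(y, yhat) -> BlandAltman:
    """Bland–Altman analysis; differences are predicted − actual."""
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if len(y) != len(yhat) or len(y) < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    diffs = yhat - y
    means = (yhat + y) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltman(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        means=means,
        diffs=diffs,
    )


def correlation(y, yhat) -> float:
    """Pearson product-moment correlation; NaN if either input is constant."""
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if len(y) != len(yhat) or len(y) < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if y.std() == 0 or yhat.std() == 0:
        return float("nan")  # undefined for zero-variance input
    return float(np.corrcoef(y, yhat)[0, 1])


@dataclass
class EvaluationReport:
    """Cross-validated results for one model and one target."""

    model_name: str
    target: str
    n_folds: int
    seed: int
    pooled_metrics: dict[str, float]
    fold_metrics: list[dict[str, float]]
    y: np.ndarray
    yhat_oof: np.ndarray
    agreement: BlandAltman = field(init=False)
    pearson_r: float = field(init=False)

    def __post_init__(self) -> None:
        self.agreement = bland_altman(self.y, self.yhat_oof)
        self.pearson_r = correlation(self.y, self.yhat_oof)


def cross_validate(
    table,
    spec: str | ModelSpec,
    target: str = "SBP",
    k: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Shuffled k-fold cross-validation of one model on a feature table.

    Every row is predicted exactly once out-of-fold; pooled metrics are
    computed on the assembled out-of-fold prediction vector, per-fold
    metrics on each held-out fold.
    """
    spec = _as_spec(spec)
    X = table.X
    y = table.y(target)
    n = len(y)
    if k < 2:
        raise ValueError(f"need at least 2 folds, got {k}")
    if n < k:
        raise ValueError(f"{n} rows cannot be split into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    yhat = np.full(n, np.nan)
    fold_metrics = []
    for train_idx, test_idx in kf.split(X):
        res = BPRegression(y[train_idx], X[train_idx], spec).fit()
        pred = res.predict(X[test_idx])
        yhat[test_idx] = pred
        if len(test_idx) >= 2:
            fold_metrics.append(metrics(y[test_idx], pred))
    assert not np.any(np.isnan(yhat)), "incomplete out-of-fold cover"
    return EvaluationReport(
        model_name=spec.name,
        target=target.upper(),
        n_folds=k,
        seed=seed,
        pooled_metrics=metrics(y, yhat),
        fold_metrics=fold_metrics,
        y=y,
        yhat_oof=yhat,
    )


def evaluate_models(
    table,
    models=None,
    targets=("SBP", "DBP"),
    k: int = 10,
    seed: int = 0,
) -> list[EvaluationReport]:
    """Cross-validate a set of models for each target."""
    from .regression import MODEL_NAMES

    models = list(models) if models is not None else list(MODEL_NAMES)
    return [
        cross_validate(table, m, target=t, k=k, seed=seed)
        for t in targets
        for m in models
    ]


# ---------------------------------------------------------------------------
# British Hypertension Society grading
# ---------------------------------------------------------------------------

def classify_bp_grade(sbp: float, dbp: float) -> str:
    """BHS blood-pressure category for one (SBP, DBP) pair in mmHg.

    Bands (inclusive printed ranges): Optimal <120/<80; Normal <130/<85;
    High normal 130–139 or 85–89; Grade 1 140–159 or 90–99; Grade 2
    160–179 or 100–109; Grade 3 ≥180 or ≥110. Isolated systolic
    hypertension: SBP ≥ 140 with DBP < 90 (Grade 2 when SBP ≥ 160). The
    higher-severity category wins when SBP and DBP disagree.
    """
    if not (sbp > dbp > 0):
        raise ValueError(f"need SBP > DBP > 0, got ({sbp}, {dbp})")

    if sbp >= 140 and dbp < 90:
        return ("Isolated systolic hypertension Grade 2" if sbp >= 160
                else "Isolated systolic hypertension Grade 1")

    def sys_grade(s):
        if s >= 180:
            return 3
        if s >= 160:
            return 2
        if s >= 140:
            return 1
        return 0

    def dia_grade(d):
        if d >= 110:
            return 3
        if d >= 100:
            return 2
        if d >= 90:
            return 1
        return 0

    grade = max(sys_grade(sbp), dia_grade(dbp))
    if grade == 3:
        return "Grade 3 (Severe)"
    if grade == 2:
        return "Grade 2 (Moderate)"
    if grade == 1:
        return "Grade 1 (Mild)"
    if sbp >= 130 or dbp >= 85:
        return "High normal"
    if sbp < 120 and dbp < 80:
        return "Optimal"
    return "Normal"


# ---------------------------------------------------------------------------
# report export
# ---------------------------------------------------------------------------

METRIC_TABLE_COLUMNS = ["Regression Methods", "Target", "RMSE", "R2", "MSE", "MAE"]


def export_report(reports: list[EvaluationReport], out_dir) -> dict[str, str]:
    """Write the evaluation artifacts as CSV files.

    * ``metrics.csv`` — one row per model × target (RMSE, R², MSE, MAE).
    * ``agreement_<target>_<model>.csv`` — Bland–Altman (mean, diff) pairs
      with the limits of agreement repeated per row, plus Pearson r.
    * ``overlay_<target>_<model>.csv`` — reference vs out-of-fold predicted
      series, one row per segment, for time-series overlay plots.

    Returns a mapping of artifact name → written path.
    """
    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, str] = {}
    rows = []
    for r in reports:
        rows.append({
            "Regression Methods": r.model_name,
            "Target": r.target,
            "RMSE": r.pooled_metrics["RMSE"],
            "R2": r.pooled_metrics["R2"],
            "MSE": r.pooled_metrics["MSE"],
            "MAE": r.pooled_metrics["MAE"],
        })
    metrics_path = os.path.join(out_dir, "metrics.csv")
    pd.DataFrame(rows, columns=METRIC_TABLE_COLUMNS).to_csv(
        metrics_path, index=False, float_format="%.6g"
    )
    written["metrics"] = metrics_path
    for r in reports:
        tag = f"{r.target.lower()}_{r.model_name}"
        ba = r.agreement
        agree = pd.DataFrame({
            "mean": ba.means,
            "diff": ba.diffs,
            "mean_diff": ba.mean_diff,
            "loa_low": ba.loa_low,
            "loa_high": ba.loa_high,
            "pearson_r": r.pearson_r,
        })
        p = os.path.join(out_dir, f"agreement_{tag}.csv")
        agree.to_csv(p, index=False, float_format="%.10g")
        written[f"agreement_{tag}"] = p
        overlay = pd.DataFrame({
            "segment": np.arange(len(r.y)),
            "actual": r.y,
            "predicted": r.yhat_oof,
        })
        p = os.path.join(out_dir, f"overlay_{tag}.csv")
        overlay.to_csv(p, index=False, float_format="%.10g")
        written[f"overlay_{tag}"] = p
    return written


def plot_agreement(report: EvaluationReport, path=None):
    """Correlation + Bland–Altman panel for one report (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.scatter(report.y, report.yhat_oof, s=8, alpha=0.6)
    lims = [min(report.y.min(), report.yhat_oof.min()),
            max(report.y.max(), report.yhat_oof.max())]
    ax1.plot(lims, lims, "k--", lw=1)
    ax1.set_xlabel(f"actual {report.target} (mmHg)")
    ax1.set_ylabel(f"predicted {report.target} (mmHg)")
    ax1.set_title(f"r = {report.pearson_r:.3f}")
    ba = report.agreement
    ax2.scatter(ba.means, ba.diffs, s=8, alpha=0.6)
    for v, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax2.axhline(v, color="r", ls=style, lw=1)
    ax2.set_xlabel("mean of predicted and actual (mmHg)")
    ax2.set_ylabel("predicted − actual (mmHg)")
    ax2.set_title(f"{report.model_name} / {report.target}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
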