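"""Downstream inference on prediction tables.

The scientific payload of the pipeline: given per-subject network
predictions aligned with truth, compute confusion matrices, the
prediction-residual adiposity index ΔBMI = predicted − measured BMI,
linear regression of visceral adipose tissue (VAT) volume on ΔBMI
controlling for measured BMI, per-SD odds ratios of comorbidities
adjusted for age and measured BMI, χ² comparisons of comorbidity
frequencies between misclassification groups (TP vs FN, TN vs FP) with
Benjamini-Hochberg correction, rank-statistic ROC/AUC after binarizing
continuous estimates, and RMSE.

All fits are intended to be run per sex; the functions operate on the
table they are given and do not stratify internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "confusion_matrix",
    "confusion_groups",
    "delta_bmi",
    "vat_regression",
    "comorbidity_or",
    "misclassification_chi2",
    "binarized_roc",
    "rmse",
    "COMORBIDITIES",
]

COMORBIDITIES = ["htn", "chd", "dm", "dyslip"]

BMI_OVERWEIGHT = 25.0  # kg/m^2, overweight/obese threshold
BMI_OBESE = 30.0  # kg/m^2


@dataclass
class StatResult:
    """One estimate with its uncertainty and correction metadata."""

    name: str
    estimate: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    scale: str = "per_unit"  # "per_unit" | "per_sd" | "statistic"
    n: int = 0
    r_squared: float | None = None
    correction: str = "none"  # "none" | "BH"
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "scale": self.scale,
            "n": self.n,
            "r_squared": self.r_squared,
            "correction": self.correction,
        }
        d.update(self.extras)
        return d


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def _truth_classes(truth_bmi: np.ndarray, n_classes: int) -> np.ndarray:
    if n_classes == 2:
        return (truth_bmi >= BMI_OVERWEIGHT).astype(int)
    return np.where(truth_bmi >= BMI_OBESE, 2, np.where(truth_bmi >= BMI_OVERWEIGHT, 1, 0))


def confusion_matrix(table: pd.DataFrame, n_classes: int = 2) -> tuple[np.ndarray, float]:
    """Confusion matrix (rows truth, columns prediction) and accuracy.

    Truth classes are derived from `truth_bmi` at 25 (binary) or 25/30
    kg/m² (3-class); predictions come from `pred_class`.
    """
    if len(table) == 0:
        raise ValueError("empty prediction table")
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    truth = _truth_classes(table["truth_bmi"].to_numpy(), n_classes)
    pred = table["pred_class"].to_numpy().astype(int)
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (truth, pred), 1)
    return mat, float(np.trace(mat) / mat.sum())


def confusion_groups(table: pd.DataFrame) -> pd.Series:
    """Label each binary-classified subject TP, FP, TN or FN.

    Positive = measured BMI >= 25 kg/m²; so FP subjects have BMI < 25 but
    were called overweight/obese by the network.
    """
    truth = (table["truth_bmi"].to_numpy() >= BMI_OVERWEIGHT).astype(int)
    pred = table["pred_class"].to_numpy().astype(int)
    labels = np.select(
        [(truth == 1) & (pred == 1), (truth == 0) & (pred == 1), (truth == 0) & (pred == 0)],
        ["TP", "FP", "TN"],
        default="FN",
    )
    return pd.Series(labels, index=table.index, name="group")


def delta_bmi(table: pd.DataFrame) -> pd.Series:
    """ΔBMI = network-predicted BMI − measured BMI, kg/m².

    Rows with a missing prediction are excluded (count available from the
    returned series' length versus the table's).
    """
    if "pred_bmi" not in table:
        raise ValueError("table has no continuous BMI predictions")
    d = table["pred_bmi"] - table["truth_bmi"]
    return d.dropna().rename("delta_bmi")


def vat_regression(table: pd.DataFrame, min_n: int = 30) -> dict:
    """OLS of VAT volume (L) on ΔBMI, controlling for measured BMI.

    Returns a dict with `beta_per_unit` and `beta_per_sd` StatResults
    (95% Wald CIs, p for the ΔBMI coefficient), the full-model R², the
    partial R² of ΔBMI alone and the sample SD of ΔBMI. Per-SD effects
    multiply the per-unit coefficient by the sample SD of ΔBMI.
    """
    sub = table.dropna(subset=["truth_vat", "pred_bmi", "truth_bmi"])
    if len(sub) < min_n:
        raise ValueError(f"VAT regression needs >= {min_n} subjects with VAT, got {len(sub)}")
    d = (sub["pred_bmi"] - sub["truth_bmi"]).to_numpy()
    sd_d = float(np.std(d, ddof=1))
    if sd_d <= 1e-9 * max(1.0, float(np.abs(d).max())):
        raise ValueError("ΔBMI has zero variance; coefficient unidentifiable")
    X = sm.add_constant(pd.DataFrame({"delta_bmi": d, "truth_bmi": sub["truth_bmi"].to_numpy()}))
    fit = sm.OLS(sub["truth_vat"].to_numpy(), X).fit()
    beta = float(fit.params["delta_bmi"])
    lo, hi = (float(v) for v in fit.conf_int().loc["delta_bmi"])
    p = float(fit.pvalues["delta_bmi"])
    # R² of the ΔBMI term alone, on top of the BMI-only model
    base = sm.OLS(
        sub["truth_vat"].to_numpy(),
        sm.add_constant(sub["truth_bmi"].to_numpy()),
    ).fit()
    partial_r2 = float(fit.rsquared - base.rsquared)
    n = len(sub)
    return {
        "beta_per_unit": StatResult(
            "vat_on_delta_bmi", beta, lo, hi, p, "per_unit", n, r_squared=float(fit.rsquared)
        ),
        "beta_per_sd": StatResult(
            "vat_on_delta_bmi",
            beta * sd_d,
            lo * sd_d,
            hi * sd_d,
            p,
            "per_sd",
            n,
            r_squared=float(fit.rsquared),
            extras={"sd_delta_bmi": sd_d},
        ),
        "r_squared": float(fit.rsquared),
        "partial_r_squared_delta": partial_r2,
        "sd_delta_bmi": sd_d,
        "n": n,
    }


def comorbidity_or(table: pd.DataFrame, index: str, condition: str, min_cases: int = 5) -> StatResult:
    """Per-SD odds ratio of a comorbidity for one adiposity index.

    Fits logistic(condition) ~ z(index) + age + measured BMI, where z is
    the index standardized by the analysis-sample mean and SD, and reports
    exp(coefficient on z) with a 95% Wald CI. `index` is one of pred_vat,
    pred_bmi, delta_bmi, truth_vat, truth_bmi (delta_bmi is derived from
    pred_bmi − truth_bmi if not already a column). Perfect separation is
    flagged and refitted with an L2 penalty (no CI in that case).
    """
    work = table.copy()
    if index == "delta_bmi" and "delta_bmi" not in work:
        work["delta_bmi"] = work["pred_bmi"] - work["truth_bmi"]
    sub = work.dropna(subset=[index, "age", "truth_bmi", condition])
    y = sub[condition].to_numpy().astype(int)
    n_cases = int(y.sum())
    if n_cases == 0 or n_cases == len(y):
        raise ValueError(f"condition {condition!r} is degenerate (all {y[0]})")
    if n_cases < min_cases:
        raise ValueError(f"condition {condition!r} has only {n_cases} cases (< {min_cases})")
    raw = sub[index].to_numpy().astype(float)
    z = (raw - raw.mean()) / raw.std(ddof=1)
    covars = {"z_index": z, "age": sub["age"].to_numpy()}
    adjusted_for = ["age"]
    if index != "truth_bmi":  # measured BMI cannot be adjusted for itself
        covars["truth_bmi"] = sub["truth_bmi"].to_numpy()
        adjusted_for.append("truth_bmi")
    X = sm.add_constant(pd.DataFrame(covars))
    try:
        with warnings.catch_warnings():
            # intermediate optimizer iterates can overflow the logistic link
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)):
            raise np.linalg.LinAlgError("non-finite standard errors")
        coef = float(fit.params["z_index"])
        lo, hi = (float(v) for v in fit.conf_int().loc["z_index"])
        return StatResult(
            f"or_{condition}_{index}",
            float(np.exp(coef)),
            float(np.exp(lo)),
            float(np.exp(hi)),
            float(fit.pvalues["z_index"]),
            "per_sd",
            len(y),
            extras={"condition": condition, "index": index, "adjusted_for": adjusted_for},
        )
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        # separation: maximum likelihood unbounded, fall back to a ridge fit
        fit = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        return StatResult(
            f"or_{condition}_{index}",
            float(np.exp(fit.params["z_index"])),
            scale="per_sd",
            n=len(y),
            extras={
                "condition": condition,
                "index": index,
                "adjusted_for": adjusted_for,
                "separation": True,
            },
        )


def misclassification_chi2(
    table: pd.DataFrame,
    groups: pd.Series | None = None,
    alpha: float = 0.05,
) -> list[StatResult]:
    """χ² comparisons of comorbidity frequencies across error groups.

    For each of the four conditions and both contrasts (TP vs FN, TN vs
    FP): a 2x2 χ² test without continuity correction. Benjamini-Hochberg
    correction is applied across the family of all computed tests in this
    call (8 when none are skipped); significance at corrected p < alpha.
    Tests with any expected cell < 1 are skipped and reported as such.
    """
    if groups is None:
        groups = confusion_groups(table)
    results: list[StatResult] = []
    testable: list[int] = []
    pvals: list[float] = []
    for condition in COMORBIDITIES:
        for g1, g2 in (("TP", "FN"), ("TN", "FP")):
            in1, in2 = groups == g1, groups == g2
            if not (in1.any() and in2.any()):
                raise ValueError(f"group {g1} or {g2} is empty")
            y1 = table.loc[in1, condition].to_numpy().astype(int)
            y2 = table.loc[in2, condition].to_numpy().astype(int)
            obs = np.array(
                [[y1.sum(), len(y1) - y1.sum()], [y2.sum(), len(y2) - y2.sum()]], dtype=float
            )
            expected = spstats.contingency.expected_freq(obs)
            extras = {
                "condition": condition,
                "contrast": f"{g1}_vs_{g2}",
                "prevalence_1": float(y1.mean()),
                "prevalence_2": float(y2.mean()),
                "n_1": len(y1),
                "n_2": len(y2),
            }
            if expected.min() < 1.0:
                results.append(
                    StatResult(
                        f"chi2_{condition}_{g1}v{g2}",
                        np.nan,
                        scale="statistic",
                        n=len(y1) + len(y2),
                        correction="BH",
                        extras={**extras, "skipped": True},
                    )
                )
                continue
            chi2, p, _, _ = spstats.chi2_contingency(obs, correction=False)
            results.append(
                StatResult(
                    f"chi2_{condition}_{g1}v{g2}",
                    float(chi2),
                    p_value=float(p),
                    scale="statistic",
                    n=len(y1) + len(y2),
                    correction="BH",
                    extras=extras,
                )
            )
            testable.append(len(results) - 1)
            pvals.append(float(p))
    if pvals:
        p_adj = bh_adjust(pvals)
        for i, idx in enumerate(testable):
            results[idx].extras["p_adjusted"] = float(p_adj[i])
            results[idx].extras["significant"] = bool(p_adj[i] < alpha)
    return results


def binarized_roc(table: pd.DataFrame, task: str) -> float:
    """AUC of a continuous estimate against a binarized truth.

    task "bmi": labels are measured BMI >= 25 kg/m², scores are the
    continuous BMI estimates. task "vat": labels are measured VAT above
    the sample median (no conventional VAT obesity cutoff exists), scores
    are the continuous VAT estimates. The AUC is the Mann-Whitney rank
    statistic with tied scores averaged.
    """
    if task == "bmi":
        sub = table.dropna(subset=["pred_bmi", "truth_bmi"])
        labels = (sub["truth_bmi"].to_numpy() >= BMI_OVERWEIGHT).astype(int)
        scores = sub["pred_bmi"].to_numpy()
    elif task == "vat":
        sub = table.dropna(subset=["pred_vat", "truth_vat"])
        truth = sub["truth_vat"].to_numpy()
        labels = (truth > np.median(truth)).astype(int)
        scores = sub["pred_vat"].to_numpy()
    else:
        raise ValueError("task must be 'bmi' or 'vat'")
    if labels.min() == labels.max():
        raise ValueError("one label class is empty; AUC undefined")
    return float(roc_auc_score(labels, scores))


def rmse(table: pd.DataFrame, task: str) -> StatResult:
    """Root-mean-square error of a continuous estimate, in its units."""
    pred_col, truth_col = ("pred_bmi", "truth_bmi") if task == "bmi" else ("pred_vat", "truth_vat")
    sub = table.dropna(subset=[pred_col, truth_col])
    if len(sub) == 0:
        raise ValueError("empty prediction table")
    err = sub[pred_col].to_numpy() - sub[truth_col].to_numpy()
    return StatResult(f"rmse_{task}", float(np.sqrt(np.mean(err**2))), scale="statistic", n=len(sub))
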