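"""Screening-test evaluation: discrimination, calibration, operating points,
per-lesion and per-site-combination sensitivity tables, and paired rater
statistics (McNemar, Cohen's and Fleiss' kappa).

Conventions
-----------
* AUROC uses the Mann-Whitney tie convention (ties get half credit).
* A score is called positive ("refer") when it is >= the threshold.
* Expected calibration error uses equal-width probability bins (default 10).
* Confidence intervals are percentile bootstrap over patients.
* McNemar is the exact two-sided binomial test on discordant pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import EchoReport, Lesion, LesionKind, SeverityGrade, significant_lesions

__all__ = [
    "OperatingPoint",
    "EvalReport",
    "UndefinedMetricError",
    "auroc",
    "sens_spec",
    "threshold_for_specificity",
    "ece",
    "bootstrap_ci",
    "mcnemar",
    "cohens_kappa",
    "fleiss_kappa",
    "majority_vote",
    "youden",
    "sensitivity_by_lesion",
    "site_combination_table",
    "evaluate_predictions",
    "plot_reliability",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. single-class labels)."""


@dataclass(frozen=True)
class OperatingPoint:
    """Decision threshold: score >= threshold means 'refer'."""

    threshold: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0 + 1e-12:
            raise ValueError("threshold must be in [0, 1]")

    def decide(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores) >= self.threshold


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-D arrays")
    return scores, labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve: P(score_pos > score_neg) + 0.5 P(tie)."""
    from sklearn.metrics import roc_auc_score

    scores, labels = _check_scores_labels(scores, labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def sens_spec(scores, labels, op: OperatingPoint) -> tuple[float, float, dict[str, int]]:
    """Sensitivity, specificity and confusion counts at an operating point."""
    scores, labels = _check_scores_labels(scores, labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError("sensitivity/specificity need both classes present")
    pred = op.decide(scores)
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    return tp / (tp + fn), tn / (tn + fp), {"tp": tp, "fp": fp, "tn": tn, "fn": fn}


def threshold_for_specificity(scores, labels, target: float) -> OperatingPoint:
    """Smallest threshold whose specificity is >= target (maximising sensitivity
    subject to the specificity constraint).

    Candidate thresholds are the observed score cut-points.  If the target is
    unattainable a threshold above the maximum score is returned with a warning.
    """
    scores, labels = _check_scores_labels(scores, labels)
    neg = scores[labels == 0]
    if neg.size == 0:
        raise UndefinedMetricError("no negatives: specificity undefined")
    for thr in np.unique(scores):
        spec = float(np.mean(neg < thr))
        if spec >= target:
            return OperatingPoint(threshold=min(float(thr), 1.0))
    warnings.warn(f"target specificity {target} not achievable; refusing all")
    return OperatingPoint(threshold=1.0)


def ece(probs, labels, n_bins: int = 10) -> tuple[float, pd.DataFrame]:
    """Expected calibration error with equal-width bins on [0, 1].

    ECE = sum_b (n_b / n) * |mean confidence_b - empirical accuracy_b| over
    non-empty bins, where accuracy is the observed positive fraction.
    Also returns the reliability bins (confidence, accuracy, count).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if probs.size == 0:
        raise ValueError("empty input")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must be in [0, 1]")
    idx = np.minimum((probs * n_bins).astype(int), n_bins - 1)
    rows = []
    total = 0.0
    for b in range(n_bins):
        mask = idx == b
        n_b = int(mask.sum())
        if n_b == 0:
            rows.append({"bin": b, "lo": b / n_bins, "hi": (b + 1) / n_bins,
                         "confidence": np.nan, "accuracy": np.nan, "count": 0})
            continue
        conf = float(probs[mask].mean())
        acc = float(labels[mask].mean())
        total += n_b / probs.size * abs(conf - acc)
        rows.append({"bin": b, "lo": b / n_bins, "hi": (b + 1) / n_bins,
                     "confidence": conf, "accuracy": acc, "count": n_b})
    return total, pd.DataFrame(rows)


def bootstrap_ci(statistic, data, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float, int]:
    """Percentile bootstrap interval for ``statistic(*resampled columns)``.

    ``data`` is a tuple of aligned arrays resampled jointly (the resampling
    unit is the patient).  Resamples on which the statistic is undefined
    (e.g. single-class) are skipped; their count is returned third.
    """
    arrays = [np.asarray(a) for a in (data if isinstance(data, (tuple, list)) else (data,))]
    n = arrays[0].shape[0]
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            vals.append(float(statistic(*(a[idx] for a in arrays))))
        except UndefinedMetricError:
            skipped += 1
    if not vals:
        raise UndefinedMetricError("statistic undefined on every bootstrap resample")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi), skipped


def mcnemar(correct_a, correct_b) -> tuple[int, int, float]:
    """Exact McNemar test on paired correctness flags.

    Returns (b01, b10, p) where b01 counts patients A got right and B wrong,
    b10 the reverse, and p is the exact two-sided binomial probability on the
    discordant pairs.  With no discordant pairs p = 1.
    """
    from scipy.stats import binomtest

    a = np.asarray(correct_a).astype(bool)
    b = np.asarray(correct_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("paired flags must be aligned")
    b01 = int(np.sum(a & ~b))
    b10 = int(np.sum(~a & b))
    n_disc = b01 + b10
    if n_disc == 0:
        return b01, b10, 1.0
    p = binomtest(min(b01, b10), n=n_disc, p=0.5, alternative="two-sided").pvalue
    return b01, b10, float(min(p, 1.0))


def cohens_kappa(r1, r2) -> float:
    """Cohen's kappa for two raters with marginal-product chance agreement."""
    from sklearn.metrics import cohen_kappa_score

    r1 = np.asarray(r1).astype(int)
    r2 = np.asarray(r2).astype(int)
    if r1.shape != r2.shape or r1.size == 0:
        raise ValueError("ratings must be aligned and non-empty")
    cats = np.union1d(r1, r2)
    p_e = sum(np.mean(r1 == c) * np.mean(r2 == c) for c in cats)
    if p_e >= 1.0 - 1e-12:
        raise UndefinedMetricError("chance agreement is 1; kappa undefined")
    return float(cohen_kappa_score(r1, r2))


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss' kappa for an (n_subjects x n_raters) matrix of categorical ratings."""
    from statsmodels.stats.inter_rater import aggregate_raters
    from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

    ratings = np.asarray(ratings)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be (subjects x raters) with >= 2 raters")
    table, _cats = aggregate_raters(ratings)
    p_cat = table.sum(axis=0) / table.sum()
    if np.max(p_cat) >= 1.0 - 1e-12:
        raise UndefinedMetricError("all ratings in one category; kappa undefined")
    return float(sm_fleiss(table, method="fleiss"))


def majority_vote(votes) -> bool:
    """Majority referral decision with a bias to refer on ties."""
    votes = list(votes)
    if not votes:
        raise ValueError("empty vote list")
    n_refer = sum(bool(v) for v in votes)
    return n_refer >= len(votes) - n_refer


def youden(sens: float, spec: float) -> float:
    """Youden index J = sensitivity + specificity - 1."""
    return sens + spec - 1.0


# ---------------------------------------------------------------------------
# table builders

_GRADES_BY_KIND = {
    LesionKind.STENOSIS: (SeverityGrade.SEVERE, SeverityGrade.MODERATE, SeverityGrade.MILD),
    LesionKind.REGURGITATION: (SeverityGrade.SEVERE, SeverityGrade.MODERATE),
}


def sensitivity_by_lesion(preds: pd.DataFrame, echos: dict[str, EchoReport],
                          op: OperatingPoint, isolated_only: bool = False,
                          n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
    """Sensitivity per (lesion, grade) cell at a fixed operating point.

    Cells contain patients whose echo shows that lesion at that grade and for
    whom the grade individually meets the significance rule (so every cell
    member carries the positive label).  ``isolated_only`` restricts a cell
    to patients whose *only* significant lesion is that one.  Empty cells get
    n = 0 and NaN sensitivity.
    """
    rows = []
    by_id = dict(zip(preds["id"], preds["prob_fused"]))
    for lesion in Lesion:
        for grade in _GRADES_BY_KIND[lesion.kind]:
            members = []
            for pid, echo in echos.items():
                if pid not in by_id or echo.grades[lesion] != grade:
                    continue
                if isolated_only and significant_lesions(echo) != [lesion]:
                    continue
                members.append(pid)
            if not members:
                rows.append({"lesion": lesion.value, "grade": grade.name.lower(),
                             "sensitivity": np.nan, "n": 0,
                             "ci_lo": np.nan, "ci_hi": np.nan})
                continue
            scores = np.array([by_id[pid] for pid in members])
            hits = op.decide(scores)
            sens = float(hits.mean())
            lo, hi, _ = bootstrap_ci(lambda h: float(np.mean(h)), (hits.astype(float),),
                                     n_boot=n_boot, seed=seed)
            rows.append({"lesion": lesion.value, "grade": grade.name.lower(),
                         "sensitivity": sens, "n": len(members),
                         "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows).set_index(["lesion", "grade"])


def site_combination_table(preds: pd.DataFrame, echos: dict[str, EchoReport],
                           combos: list[tuple[str, ...]],
                           target_spec: float = 0.82) -> pd.DataFrame:
    """Sensitivity per site combination at a per-combination fixed specificity.

    ``preds`` must carry per-site probability columns (``prob_A`` ...) and a
    ``label`` column.  For each combination the fused score is the maximum
    over that combination's sites; patients missing any site of the
    combination are dropped (count in column ``n_dropped``); the threshold is
    set per combination so specificity equals ``target_spec``.  Sensitivity
    is reported overall and within each significant-lesion group.
    """
    rows = []
    for combo in combos:
        cols = [f"prob_{s}" for s in combo]
        sub = preds.dropna(subset=cols)
        n_dropped = len(preds) - len(sub)
        fused = sub[cols].max(axis=1).to_numpy()
        labels = sub["label"].to_numpy().astype(int)
        if labels.min() == labels.max():
            raise UndefinedMetricError("combination subset lost a class")
        op = threshold_for_specificity(fused, labels, target_spec)
        sens, spec, _ = sens_spec(fused, labels, op)
        row = {"combo": "".join(combo), "threshold": op.threshold,
               "specificity": spec, "sensitivity": sens,
               "n": len(sub), "n_dropped": n_dropped}
        by_id = dict(zip(sub["id"], fused))
        for lesion in Lesion:
            members = [pid for pid, echo in echos.items()
                       if pid in by_id and lesion in significant_lesions(echo)]
            if members:
                scores = np.array([by_id[m] for m in members])
                row[f"sens_{lesion.value}"] = float(np.mean(op.decide(scores)))
            else:
                row[f"sens_{lesion.value}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("combo")


# ---------------------------------------------------------------------------
# report object

@dataclass
class EvalReport:
    """Bundle of screening metrics for one prediction set."""

    n: int
    auroc: float
    auroc_ci: tuple[float, float]
    operating_point: OperatingPoint
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    youden: float
    ece: float
    ece_ci: tuple[float, float]
    reliability_bins: pd.DataFrame
    confusion: dict[str, int]
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci),
            "threshold": self.operating_point.threshold,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "youden": self.youden,
            "ece": self.ece,
            "ece_ci": list(self.ece_ci),
            "reliability_bins": self.reliability_bins.to_dict(orient="records"),
            "confusion": self.confusion,
            **self.extras,
        }

    def summary(self) -> str:
        lines = [
            "Screening evaluation",
            "=" * 48,
            f"n patients               {self.n}",
            f"AUROC                    {self.auroc:.3f} ({self.auroc_ci[0]:.3f}-{self.auroc_ci[1]:.3f})",
            f"operating threshold      {self.operating_point.threshold:.3f}",
            f"sensitivity              {self.sensitivity:.1%} ({self.sensitivity_ci[0]:.1%}-{self.sensitivity_ci[1]:.1%})",
            f"specificity              {self.specificity:.1%} ({self.specificity_ci[0]:.1%}-{self.specificity_ci[1]:.1%})",
            f"Youden index             {self.youden:.3f}",
            f"expected calibration err {self.ece:.3f} ({self.ece_ci[0]:.3f}-{self.ece_ci[1]:.3f})",
        ]
        return "\n".join(lines)


def evaluate_predictions(scores, labels, spec_target: float = 0.82,
                         operating_point: OperatingPoint | None = None,
                         n_boot: int = 1000, seed: int = 0,
                         n_bins: int = 10) -> EvalReport:
    """Full screening evaluation of patient-level probabilities.

    The operating point defaults to the smallest threshold achieving the
    target specificity on this cohort; pass ``operating_point`` to use a
    pre-specified threshold instead.
    """
    scores, labels = _check_scores_labels(scores, labels)
    a = auroc(scores, labels)
    a_lo, a_hi, _ = bootstrap_ci(auroc, (scores, labels), n_boot=n_boot, seed=seed)
    op = operating_point or threshold_for_specificity(scores, labels, spec_target)
    sens, spec, conf = sens_spec(scores, labels, op)

    def _sens(s, l):
        return sens_spec(s, l, op)[0]

    def _spec(s, l):
        return sens_spec(s, l, op)[1]

    s_lo, s_hi, _ = bootstrap_ci(_sens, (scores, labels), n_boot=n_boot, seed=seed + 1)
    p_lo, p_hi, _ = bootstrap_ci(_spec, (scores, labels), n_boot=n_boot, seed=seed + 2)
    e, bins = ece(scores, labels, n_bins=n_bins)
    e_lo, e_hi, _ = bootstrap_ci(lambda s, l: ece(s, l, n_bins)[0], (scores, labels),
                                 n_boot=n_boot, seed=seed + 3)
    return EvalReport(
        n=len(scores), auroc=a, auroc_ci=(a_lo, a_hi), operating_point=op,
        sensitivity=sens, sensitivity_ci=(s_lo, s_hi),
        specificity=spec, specificity_ci=(p_lo, p_hi),
        youden=youden(sens, spec), ece=e, ece_ci=(e_lo, e_hi),
        reliability_bins=bins, confusion=conf,
    )


def plot_reliability(bins: pd.DataFrame, path: str) -> None:
    """Reliability diagram (predicted probability vs observed frequency)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect calibration")
    ok = bins["count"] > 0
    ax.bar(bins.loc[ok, "lo"], bins.loc[ok, "accuracy"], width=1.0 / len(bins),
           align="edge", edgecolor="k", alpha=0.6, label="observed")
    ax.plot(bins.loc[ok, "confidence"], bins.loc[ok, "accuracy"], "o-", color="C1")
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed frequency")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
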