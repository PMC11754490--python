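"""Agreement and diagnostic statistics for risk-category evaluation.

Implements the evaluation suite for comparing predicted against reference
Agatston results: Dice overlap for masks, the 5x5 risk-grade confusion
matrix, unweighted Cohen's kappa with an asymptotic 95% CI (Fleiss-Cohen-
Everitt standard error; a seeded bootstrap is available as a cross-check),
one-vs-rest per-grade sensitivity / specificity / PPV / NPV / F1, agreement
summaries (exact, within-one-category, over/under-estimation), and
presence/absence diagnostics at the total-score > 0 cutoff.

Undefined ratios (zero denominators) are reported as NaN ("not available"),
never coerced to 0 — sparse grades must not silently inflate performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_io import BinaryMask

__all__ = [
    "N_GRADES",
    "ConfusionMatrix5",
    "KappaResult",
    "EvalReport",
    "dice",
    "confusion",
    "cohen_kappa",
    "bootstrap_kappa",
    "per_category_metrics",
    "agreement_summary",
    "presence_metrics",
    "build_eval_report",
]

N_GRADES = 5
METRIC_COLUMNS = ("sensitivity", "specificity", "ppv", "npv", "f1")


def dice(mask_a: BinaryMask | np.ndarray, mask_b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = mask_a.bits if isinstance(mask_a, BinaryMask) else np.asarray(mask_a, bool)
    b = mask_b.bits if isinstance(mask_b, BinaryMask) else np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


@dataclass
class ConfusionMatrix5:
    """5x5 counts; rows = reference grade, columns = predicted grade."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_GRADES, N_GRADES):
            raise ValueError(f"expected a {N_GRADES}x{N_GRADES} matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        labels = ["0", "I", "II", "III", "IV"]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def _as_grade_array(grades) -> np.ndarray:
    arr = np.asarray([int(g) for g in grades], dtype=np.int64)
    if arr.size and ((arr < 0) | (arr >= N_GRADES)).any():
        bad = arr[(arr < 0) | (arr >= N_GRADES)]
        raise ValueError(f"grades outside 0..{N_GRADES - 1}: {sorted(set(bad.tolist()))}")
    return arr


def confusion(reference_grades, predicted_grades) -> ConfusionMatrix5:
    """Tally (reference, predicted) grade pairs into a 5x5 matrix."""
    ref = _as_grade_array(reference_grades)
    pred = _as_grade_array(predicted_grades)
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted grade sequences differ in length")
    counts = np.zeros((N_GRADES, N_GRADES), dtype=np.int64)
    np.add.at(counts, (ref, pred), 1)
    return ConfusionMatrix5(counts)


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    se: float


def cohen_kappa(cm: ConfusionMatrix5, z: float = 1.959963984540054) -> KappaResult:
    """Unweighted Cohen's kappa with the asymptotic (Fleiss-Cohen-Everitt) CI.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the diagonal fraction and p_e
    the chance agreement from the marginals. Degenerate marginals (p_e = 1)
    leave kappa undefined and raise. CI bounds are clipped to [-1, 1].
    """
    n = cm.n
    if n < 2:
        raise ValueError(f"kappa needs at least 2 subjects, got n={n}")
    p = cm.counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    if math.isclose(p_e, 1.0):
        raise ValueError("kappa undefined: single-category marginals (p_e = 1)")
    kappa = (p_o - p_e) / (1.0 - p_e)

    # large-sample variance (Fleiss, Cohen & Everitt 1969)
    a = 0.0
    b = 0.0
    for i in range(N_GRADES):
        a += p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2
        for j in range(N_GRADES):
            if i != j:
                b += p[i, j] * (col[i] + row[j]) ** 2
    b *= (1.0 - kappa) ** 2
    c = (kappa - p_e * (1.0 - kappa)) ** 2
    var = (a + b - c) / (n * (1.0 - p_e) ** 2)
    se = math.sqrt(max(var, 0.0))
    return KappaResult(kappa, max(kappa - z * se, -1.0), min(kappa + z * se, 1.0), se)


def bootstrap_kappa(reference_grades, predicted_grades, n_boot: int = 2000,
                    seed: int = 0, alpha: float = 0.05) -> KappaResult:
    """Percentile-bootstrap kappa CI — a cross-check on the asymptotic CI."""
    ref = _as_grade_array(reference_grades)
    pred = _as_grade_array(predicted_grades)
    if ref.shape != pred.shape or ref.size < 2:
        raise ValueError("need equal-length sequences with at least 2 subjects")
    point = cohen_kappa(confusion(ref, pred)).kappa
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, ref.size, size=ref.size)
        try:
            stats.append(cohen_kappa(confusion(ref[idx], pred[idx])).kappa)
        except ValueError:  # degenerate resample
            continue
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return KappaResult(point, float(lo), float(hi), float(np.std(stats)))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def per_category_metrics(cm: ConfusionMatrix5) -> pd.DataFrame:
    """One-vs-rest sensitivity/specificity/PPV/NPV/F1 per grade (NaN = n/a)."""
    if cm.n < 1:
        raise ValueError("empty confusion matrix")
    rows = {}
    total = cm.n
    for g in range(N_GRADES):
        tp = int(cm.counts[g, g])
        fn = int(cm.counts[g].sum()) - tp
        fp = int(cm.counts[:, g].sum()) - tp
        tn = total - tp - fn - fp
        sens = _ratio(tp, tp + fn)
        spec = _ratio(tn, tn + fp)
        ppv = _ratio(tp, tp + fp)
        npv = _ratio(tn, tn + fn)
        f1 = _ratio(2 * ppv * sens, ppv + sens) if not (math.isnan(ppv) or math.isnan(sens)) \
            else float("nan")
        rows[("0", "I", "II", "III", "IV")[g]] = [sens, spec, ppv, npv, f1]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_COLUMNS))


def agreement_summary(cm: ConfusionMatrix5) -> dict[str, float]:
    """Exact / off-by-one / off-by-more fractions plus over/under-estimation."""
    n = cm.n
    if n < 1:
        raise ValueError("empty confusion matrix")
    r, p = np.meshgrid(np.arange(N_GRADES), np.arange(N_GRADES), indexing="ij")
    d = p - r
    c = cm.counts
    return {
        "exact": float(c[d == 0].sum()) / n,
        "within_one": float(c[np.abs(d) == 1].sum()) / n,
        "beyond_one": float(c[np.abs(d) > 1].sum()) / n,
        "over_estimated": float(c[d > 0].sum()) / n,
        "under_estimated": float(c[d < 0].sum()) / n,
    }


def presence_metrics(reference_totals, predicted_totals) -> tuple[float, float]:
    """Sensitivity and specificity for presence of any calcium (total > 0)."""
    ref = np.asarray(list(reference_totals), dtype=float)
    pred = np.asarray(list(predicted_totals), dtype=float)
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted score sequences differ in length")
    rp = ref > 0
    pp = pred > 0
    sens = _ratio(int((rp & pp).sum()), int(rp.sum()))
    spec = _ratio(int((~rp & ~pp).sum()), int((~rp).sum()))
    return sens, spec


@dataclass
class EvalReport:
    """Bundle of every evaluation statistic for a cohort of paired results."""

    confusion_matrix: ConfusionMatrix5
    kappa: KappaResult | None
    agreement: dict[str, float]
    per_category: pd.DataFrame
    presence_sensitivity: float
    presence_specificity: float
    mean_dice: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _clean(x):
            return None if (isinstance(x, float) and math.isnan(x)) else x
        return {
            "n": self.confusion_matrix.n,
            "confusion_matrix": self.confusion_matrix.counts.tolist(),
            "kappa": None if self.kappa is None else {
                "kappa": self.kappa.kappa,
                "ci95": [self.kappa.ci_low, self.kappa.ci_high],
                "se": self.kappa.se,
            },
            "agreement": self.agreement,
            "per_category": {
                g: {m: _clean(v) for m, v in row.items()}
                for g, row in self.per_category.to_dict(orient="index").items()
            },
            "presence": {
                "sensitivity": _clean(self.presence_sensitivity),
                "specificity": _clean(self.presence_specificity),
            },
            "mean_dice": self.mean_dice,
            "notes": list(self.notes),
        }


def build_eval_report(reference_totals, predicted_totals,
                      reference_grades=None, predicted_grades=None,
                      mean_dice: float | None = None) -> EvalReport:
    """Assemble the full report from paired per-subject scores.

    Grades are derived from the raw totals via CAC-DRS categorization when
    not supplied explicitly.
    """
    from .scoring import categorize  # local import: scoring does not need metrics

    ref_t = list(reference_totals)
    pred_t = list(predicted_totals)
    if reference_grades is None:
        reference_grades = [int(categorize(t)) for t in ref_t]
    if predicted_grades is None:
        predicted_grades = [int(categorize(t)) for t in pred_t]

    cm = confusion(reference_grades, predicted_grades)
    notes: list[str] = []
    try:
        kap = cohen_kappa(cm)
    except ValueError as exc:
        kap = None
        notes.append(f"kappa not computed: {exc}")
    sens, spec = presence_metrics(ref_t, pred_t)
    return EvalReport(cm, kap, agreement_summary(cm), per_category_metrics(cm),
                      sens, spec, mean_dice, notes)
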