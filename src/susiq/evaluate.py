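"""Diagnostic-performance statistics for semi-quantitative measures.

ROC analysis with the Mann-Whitney AUC, DeLong variance/covariance for
confidence intervals and paired AUC comparisons, Youden-criterion cutoffs,
stratified bootstrap of AUC differences, the random-pair sign test used to
compare AUC-difference distributions between settings, Welch t tests, and
a 2x2 two-way ANOVA with interaction.

Orientation convention: reduced uptake is test-positive. For a measure
where low values indicate disease ("lower" orientation), a subject is
classified positive when the score is strictly *below* the cutoff;
at-cutoff values are classified negative. No multiple-testing adjustment
is applied anywhere; all p-values are reported unadjusted.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocResult",
    "BootDist",
    "roc_auc",
    "delong_ci",
    "delong_paired_test",
    "youden_cutoff",
    "bootstrap_auc_diff",
    "sign_test_double_diff",
    "welch_t_test",
    "two_way_anova",
    "classification_report",
    "roc_analysis",
]


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D arrays of equal length")
    pos = labels.astype(bool)
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    return scores, pos


def _oriented(scores: np.ndarray, orientation: str) -> np.ndarray:
    if orientation == "lower":
        return -scores
    if orientation == "higher":
        return scores.copy()
    raise ValueError("orientation must be 'lower' or 'higher'")


def roc_auc(scores, labels, orientation: str = "lower") -> float:
    """Mann-Whitney AUC with ties counted 1/2.

    ``labels`` truthy = disease (test-positive class); ``orientation``
    'lower' means lower scores indicate disease.
    """
    scores, pos = _check_scores_labels(scores, labels)
    s = _oriented(scores, orientation)
    ranks = stats.rankdata(s)  # average ranks handle ties
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_components(scores_2d: np.ndarray, pos: np.ndarray):
    """DeLong structural components V10/V01 for each score row."""
    aucs, v10s, v01s = [], [], []
    for s in scores_2d:
        x = s[pos]            # diseased
        y = s[~pos]           # non-diseased
        # psi(x_i, y_j) = 1 if x>y, 0.5 if tie, 0 otherwise, via midranks
        all_ranks = stats.rankdata(np.concatenate([x, y]))
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        m, n = x.size, y.size
        v10 = (all_ranks[:m] - rx) / n
        v01 = 1.0 - (all_ranks[m:] - ry) / m
        auc = v10.mean()
        aucs.append(auc)
        v10s.append(v10)
        v01s.append(v01)
    return np.asarray(aucs), np.asarray(v10s), np.asarray(v01s)


def _delong_cov(scores_2d: np.ndarray, pos: np.ndarray):
    aucs, v10, v01 = _delong_components(scores_2d, pos)
    m = v10.shape[1]
    n = v01.shape[1]
    s10 = np.cov(v10) if v10.shape[0] > 1 else np.atleast_2d(np.var(v10, ddof=1))
    s01 = np.cov(v01) if v01.shape[0] > 1 else np.atleast_2d(np.var(v01, ddof=1))
    return aucs, np.atleast_2d(s10) / m + np.atleast_2d(s01) / n


def delong_ci(scores, labels, orientation: str = "lower",
              alpha: float = 0.05) -> tuple[float, float, bool]:
    """DeLong normal-approximation CI for one AUC, truncated to [0, 1].

    Returns ``(lo, hi, degenerate)``; ``degenerate`` flags zero variance
    (e.g. perfect separation), in which case the CI collapses to the AUC.
    """
    scores, pos = _check_scores_labels(scores, labels)
    s = _oriented(scores, orientation)
    aucs, cov = _delong_cov(s[None, :], pos)
    var = float(cov[0, 0])
    auc = float(aucs[0])
    if var <= 0:
        return auc, auc, True
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half), False


def delong_paired_test(scores_a, scores_b, labels,
                       orientation: str = "lower") -> float:
    """Two-sided DeLong test for equality of two correlated AUCs."""
    a, pos = _check_scores_labels(scores_a, labels)
    b, pos_b = _check_scores_labels(scores_b, labels)
    if not np.array_equal(pos, pos_b):
        raise ValueError("paired scores must share the same labels")
    s = np.vstack([_oriented(a, orientation), _oriented(b, orientation)])
    aucs, cov = _delong_cov(s, pos)
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = float(aucs[0] - aucs[1])
    if var_diff <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var_diff)
    return float(2 * stats.norm.sf(abs(z)))


def youden_cutoff(scores, labels, orientation: str = "lower"
                  ) -> tuple[float, float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between adjacent distinct scores (plus
    open extremes). Ties on J are broken by higher accuracy, then by the
    cutoff classifying fewer subjects positive. Returns
    ``(cutoff, accuracy, sensitivity, specificity)``.
    """
    scores, pos = _check_scores_labels(scores, labels)
    uniq = np.unique(scores)
    if orientation == "lower":
        cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0,
                                [uniq[-1] + 1.0]])
        predicted_pos = scores[None, :] < cands[:, None]
    elif orientation == "higher":
        cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0,
                                [uniq[-1] + 1.0]])
        predicted_pos = scores[None, :] > cands[:, None]
    else:
        raise ValueError("orientation must be 'lower' or 'higher'")

    n_pos = pos.sum()
    n_neg = (~pos).sum()
    tp = (predicted_pos & pos[None, :]).sum(axis=1)
    fp = (predicted_pos & ~pos[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    j = sens + spec - 1.0
    acc = (tp + (n_neg - fp)) / pos.size
    n_predicted = predicted_pos.sum(axis=1)
    order = np.lexsort((n_predicted, -acc, -j))
    k = order[0]
    return float(cands[k]), float(acc[k]), float(sens[k]), float(spec[k])


@dataclasses.dataclass
class RocResult:
    """ROC summary at the Youden operating point (lower = positive)."""

    auc: float
    ci95: tuple[float, float]
    cutoff: float
    accuracy: float
    sensitivity: float
    specificity: float
    degenerate_ci: bool = False
    orientation: str = "lower"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ci95"] = list(self.ci95)
        return d


def roc_analysis(scores, labels, orientation: str = "lower") -> RocResult:
    """AUC with DeLong CI plus the Youden operating point."""
    auc = roc_auc(scores, labels, orientation)
    lo, hi, degen = delong_ci(scores, labels, orientation)
    cutoff, acc, sens, spec = youden_cutoff(scores, labels, orientation)
    return RocResult(auc=auc, ci95=(lo, hi), cutoff=cutoff, accuracy=acc,
                     sensitivity=sens, specificity=spec, degenerate_ci=degen,
                     orientation=orientation)


@dataclasses.dataclass
class BootDist:
    """Bootstrap distribution of an AUC difference."""

    samples: np.ndarray
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.samples.size != self.n_boot:
            raise ValueError("sample count must equal n_boot")

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.samples, [2.5, 97.5])
        return float(lo), float(hi)


def _auc_from_oriented(s: np.ndarray, pos: np.ndarray) -> float:
    ranks = stats.rankdata(s)
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_auc_diff(scores_a, scores_b, labels, n_boot: int = 10_000,
                       seed: int = 0, orientation: str = "lower") -> BootDist:
    """Stratified bootstrap of AUC(a) - AUC(b) on paired scores.

    Cases and controls are resampled separately (preserving prevalence and
    guaranteeing both classes in every replicate); the pairing of the two
    scores within a subject is preserved.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    a, pos = _check_scores_labels(scores_a, labels)
    b, pos_b = _check_scores_labels(scores_b, labels)
    if not np.array_equal(pos, pos_b):
        raise ValueError("paired scores must share the same labels")
    a = _oriented(a, orientation)
    b = _oriented(b, orientation)
    idx_pos = np.flatnonzero(pos)
    idx_neg = np.flatnonzero(~pos)
    rng = np.random.default_rng(seed)
    samples = np.empty(n_boot)
    new_pos = np.zeros(pos.size, bool)
    new_pos[: idx_pos.size] = True
    assert new_pos.any() and not new_pos.all()
    for i in range(n_boot):
        take = np.concatenate([
            rng.choice(idx_pos, idx_pos.size, replace=True),
            rng.choice(idx_neg, idx_neg.size, replace=True),
        ])
        samples[i] = (_auc_from_oriented(a[take], new_pos)
                      - _auc_from_oriented(b[take], new_pos))
    return BootDist(samples=samples, n_boot=n_boot, seed=seed)


def sign_test_double_diff(dist_multi: BootDist, dist_mono: BootDist,
                          n_pairs: int = 10_000, seed: int = 0) -> float:
    """Random-pair comparison of two bootstrap AUC-difference distributions.

    Draws ``n_pairs`` independent pairs (x from the MULTI distribution, y
    from the MONO distribution) and returns the counted fraction of pairs
    with x <= y — the event against the hypothesis that the AUC advantage
    is larger in the MULTI setting. Reported exactly as the counted
    fraction, without continuity correction.
    """
    if n_pairs < 1000:
        raise ValueError("n_pairs must be >= 1000")
    if dist_multi.samples.size == 0 or dist_mono.samples.size == 0:
        raise ValueError("bootstrap distributions must be non-empty")
    rng = np.random.default_rng(seed)
    x = rng.choice(dist_multi.samples, n_pairs, replace=True)
    y = rng.choice(dist_mono.samples, n_pairs, replace=True)
    return float(np.mean(x <= y))


def welch_t_test(x, y, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided unequal-variance t test (Welch-Satterthwaite df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least two observations")
    if np.var(x) == 0 and np.var(y) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def two_way_anova(values, factor_a, factor_b) -> pd.DataFrame:
    """2x2 two-way ANOVA with interaction, Type-III SS on effect coding.

    Returns a DataFrame indexed by ('A', 'B', 'A:B', 'Residual') with
    sum_sq, df, F and p columns. Raises on empty cells; warns (in the
    result attrs) when any cell has fewer than 3 observations.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({
        "value": np.asarray(values, float),
        "a": pd.Categorical(np.asarray(factor_a).astype(str)),
        "b": pd.Categorical(np.asarray(factor_b).astype(str)),
    })
    if df["a"].nunique() != 2 or df["b"].nunique() != 2:
        raise ValueError("both factors must have exactly two levels")
    cells = df.groupby(["a", "b"], observed=False).size()
    if (cells == 0).any():
        raise ValueError(f"empty design cell(s): {cells[cells == 0].index.tolist()}")
    if np.ptp(df["value"].to_numpy()) == 0:
        # degenerate: constant response, all effects exactly zero
        out = pd.DataFrame(
            {"sum_sq": 0.0, "df": [1.0, 1.0, 1.0, len(df) - 4.0],
             "F": [0.0, 0.0, 0.0, np.nan], "p": [1.0, 1.0, 1.0, np.nan]},
            index=["A", "B", "A:B", "Residual"],
        )
        out.attrs["small_cells"] = bool((cells < 3).any())
        return out
    model = ols("value ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    table = table.rename(index={
        "C(a, Sum)": "A", "C(b, Sum)": "B", "C(a, Sum):C(b, Sum)": "A:B",
    }).drop(index="Intercept")
    table = table.rename(columns={"PR(>F)": "p"})
    table.attrs["small_cells"] = bool((cells < 3).any())
    return table


def classification_report(quant: pd.DataFrame, method: str, region: str,
                          other_method: str | None = None,
                          label_col: str = "label",
                          positive_label: str = "disease") -> pd.DataFrame:
    """Per-subject classification at the in-sample Youden cutoff.

    ``method`` is 'susi' or 'sbr'; scores are the hemisphere minima
    ``{method}_{region}_min``. Subjects strictly below the cutoff are
    positive; at-cutoff subjects are negative. The output has one row per
    subject with columns: score, truth, predicted, status (TP/TN/FP/FN),
    correct, d{method} (percentage deviation of the score from the cutoff),
    and, if ``other_method`` is given, the same for the second method plus
    a ``discrepant`` flag.
    """
    def one(method_name: str) -> pd.DataFrame:
        col = f"{method_name}_{region}_min"
        if col not in quant.columns:
            raise ValueError(f"missing measure column {col!r}")
        scores = quant[col].to_numpy(float)
        truth = (quant[label_col] == positive_label).to_numpy()
        cutoff, *_ = youden_cutoff(scores, truth, "lower")
        predicted = scores < cutoff
        status = np.where(
            truth & predicted, "TP",
            np.where(~truth & ~predicted, "TN",
                     np.where(~truth & predicted, "FP", "FN")),
        )
        return pd.DataFrame({
            f"score_{method_name}": scores,
            f"cutoff_{method_name}": cutoff,
            f"predicted_{method_name}": predicted,
            f"status_{method_name}": status,
            f"correct_{method_name}": truth == predicted,
            f"d{method_name}": 100.0 * (scores - cutoff) / cutoff,
        })

    out = pd.concat(
        [quant[["subject_id", label_col]].reset_index(drop=True)]
        + [one(m).reset_index(drop=True)
           for m in ([method] if other_method is None else [method, other_method])],
        axis=1,
    )
    if other_method is not None:
        out["discrepant"] = (
            out[f"predicted_{method}"] != out[f"predicted_{other_method}"]
        )
    if "rel_iqr" in quant.columns:
        out["rel_iqr"] = quant["rel_iqr"].to_numpy()
    return out
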