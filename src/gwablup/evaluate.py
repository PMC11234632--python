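"""Forward-validation statistics for genomic predictions.

Prediction quality is measured on validation animals whose phenotypes
never entered the fit: the squared correlation cor(y_v, g_hat_v)^2 between
validation yield deviations and predictions (a proxy for reliability,
usually reported relative to a reference method), the regression slope of
y_v on g_hat_v (1 = unbiased, < 1 = inflated / over-dispersed predictions,
> 1 = deflated), and a paired case-resampling bootstrap for differences in
validation correlation between two methods that share the same y_v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def prediction_reliability(y_v: np.ndarray, g_hat_v: np.ndarray) -> float:
    """Squared Pearson correlation between validation YD and predictions."""
    y_v = np.asarray(y_v, dtype=float)
    g_hat_v = np.asarray(g_hat_v, dtype=float)
    if y_v.shape != g_hat_v.shape or y_v.ndim != 1:
        raise ValueError("y_v and g_hat_v must be equal-length vectors")
    if len(y_v) < 10:
        raise ValueError("need at least 10 validation animals")
    if not (np.isfinite(y_v).all() and np.isfinite(g_hat_v).all()):
        raise ValueError("non-finite values in validation data")
    if np.std(y_v) == 0 or np.std(g_hat_v) == 0:
        raise ValueError("zero variance in validation phenotypes or predictions")
    return float(np.corrcoef(y_v, g_hat_v)[0, 1] ** 2)


def relative_to(cor2: float, cor2_reference: float) -> float:
    """Reliability expressed relative to a reference method's reliability."""
    if cor2_reference <= 0:
        raise ValueError("reference reliability must be > 0")
    return cor2 / cor2_reference


def bias_regression(y_v: np.ndarray, g_hat_v: np.ndarray) -> tuple[float, float, str]:
    """OLS slope of y_v on g_hat_v with its standard error and a verdict.

    Returns (beta, se, flag) with flag one of ``inflated`` (beta < 1),
    ``deflated`` (beta > 1) or ``unbiased`` (beta within 2 se of 1).
    """
    y_v = np.asarray(y_v, dtype=float)
    g_hat_v = np.asarray(g_hat_v, dtype=float)
    if np.std(g_hat_v) == 0:
        raise ValueError("zero variance in predictions")
    res = stats.linregress(g_hat_v, y_v)
    beta, se = float(res.slope), float(res.stderr)
    if abs(beta - 1.0) <= 2.0 * se:
        flag = "unbiased"
    else:
        flag = "inflated" if beta < 1.0 else "deflated"
    return beta, se, flag


def bootstrap_compare(
    y_v: np.ndarray,
    g_hat_k: np.ndarray,
    g_hat_l: np.ndarray,
    B: int = 10_000,
    seed: int = 0,
) -> dict:
    """Paired bootstrap test of cor(y, g_k) = cor(y, g_l).

    Validation animals are resampled with replacement as (y, g_k, g_l)
    triples, so the shared phenotype dependence of the two correlations is
    respected.  The statistic is the difference of correlations; the
    two-sided p-value uses the standard +1 small-sample correction and is
    bit-reproducible given (B, seed).  Degenerate resamples (zero variance
    in any vector) are redrawn and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y_v = np.asarray(y_v, dtype=float)
    g_hat_k = np.asarray(g_hat_k, dtype=float)
    g_hat_l = np.asarray(g_hat_l, dtype=float)
    n = len(y_v)
    if not (len(g_hat_k) == len(g_hat_l) == n):
        raise ValueError("vectors must be aligned")
    rng = np.random.default_rng(seed)

    def _cors(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row-wise correlations of resampled (y, g_k), (y, g_l)."""
        ys, gk, gl = y_v[idx], g_hat_k[idx], g_hat_l[idx]
        ys = ys - ys.mean(axis=1, keepdims=True)
        gk = gk - gk.mean(axis=1, keepdims=True)
        gl = gl - gl.mean(axis=1, keepdims=True)
        sy = np.sqrt((ys**2).sum(axis=1))
        sk = np.sqrt((gk**2).sum(axis=1))
        sl = np.sqrt((gl**2).sum(axis=1))
        bad = (sy == 0) | (sk == 0) | (sl == 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ck = (ys * gk).sum(axis=1) / (sy * sk)
            cl = (ys * gl).sum(axis=1) / (sy * sl)
        return ck, cl, bad

    diffs = np.empty(B)
    filled = 0
    redrawn = 0
    while filled < B:
        todo = B - filled
        idx = rng.integers(0, n, size=(todo, n))
        ck, cl, bad = _cors(idx)
        good = ~bad
        ngood = int(good.sum())
        diffs[filled:filled + ngood] = (ck - cl)[good]
        filled += ngood
        redrawn += int(bad.sum())

    observed = float(
        np.corrcoef(y_v, g_hat_k)[0, 1] - np.corrcoef(y_v, g_hat_l)[0, 1]
    )
    n_le = int(np.sum(diffs <= 0.0))
    n_ge = int(np.sum(diffs >= 0.0))
    p = 2.0 * min((n_le + 1) / (B + 1), (n_ge + 1) / (B + 1))
    return {
        "observed_diff": observed,
        "p_value": float(min(1.0, p)),
        "B": B,
        "seed": seed,
        "n_redrawn": redrawn,
    }


@dataclass
class EvaluationReport:
    """Method x trait forward-validation summary with pairwise tests."""

    table: pd.DataFrame  # method, trait, cor2, relative_reliability, beta, se
    pairwise_p: pd.DataFrame  # method_k, method_l, trait, p_value
    B: int
    seed: int


def evaluate_methods(
    y_v: np.ndarray,
    predictions: dict[str, np.ndarray],
    reference: str,
    trait: str = "trait",
    B: int = 10_000,
    seed: int = 0,
) -> EvaluationReport:
    """Compare prediction methods on one validation set.

    ``predictions`` maps method name to validation predictions; the
    reference method anchors the relative reliabilities (its own is exactly
    1).  Pairwise bootstrap tests at the given B/seed and a compact-letter
    display column summarize significance groups at P < 0.05.
    """
    if reference not in predictions:
        raise ValueError(f"reference method {reference!r} not among predictions")
    methods = list(predictions)
    cor2 = {m: prediction_reliability(y_v, predictions[m]) for m in methods}
    rows = []
    for m in methods:
        beta, se, flag = bias_regression(y_v, predictions[m])
        rel = 1.0 if m == reference else relative_to(cor2[m], cor2[reference])
        rows.append(
            {
                "method": m, "trait": trait, "cor2": cor2[m],
                "relative_reliability": rel, "beta": beta, "beta_se": se,
                "bias_flag": flag,
            }
        )
    pairs = []
    distinct = {m: set() for m in methods}
    for i, mk in enumerate(methods):
        for ml in methods[i + 1:]:
            out = bootstrap_compare(
                y_v, predictions[mk], predictions[ml], B=B, seed=seed
            )
            pairs.append(
                {"method_k": mk, "method_l": ml, "trait": trait,
                 "p_value": out["p_value"]}
            )
            if out["p_value"] < 0.05:
                distinct[mk].add(ml)
                distinct[ml].add(mk)
    letters = _compact_letter_display(methods, distinct)
    table = pd.DataFrame(rows)
    table["group"] = table["method"].map(letters)
    return EvaluationReport(
        table=table, pairwise_p=pd.DataFrame(pairs), B=B, seed=seed
    )


def _compact_letter_display(methods, distinct) -> dict[str, str]:
    """Greedy letter assignment: methods sharing a letter do not differ."""
    groups: list[set] = []
    for m in methods:
        placed = False
        for grp in groups:
            if not grp & distinct[m]:
                grp.add(m)
                placed = True
        if not placed:
            groups.append({m})
    letters = {m: "" for m in methods}
    for gi, grp in enumerate(groups):
        for m in methods:
            if m in grp:
                letters[m] += chr(ord("a") + gi)
    return letters
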