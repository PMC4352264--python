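"""Relative qPCR quantification by the ΔΔCt method with replicate statistics.

Per replicate, ΔCt = Ct(target) − mean Ct(reference genes); combining the
references by arithmetic mean of Ct is the geometric mean of their
expression.  ΔΔCt compares a (treatment, timepoint) group's mean ΔCt with
the 0 h control of the same treatment, and fold change is 2^(−ΔΔCt)
(amplification efficiency fixed at 2 by default; configurable).  Induction
is called at a symmetric 2-fold cut-off.  Significance between a timepoint
and its control is Welch's t on log2 replicate folds; a Tukey HSD over the
joint timepoint layout is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "FoldChangeResult",
    "read_ct_table",
    "ddct_fold",
    "significance",
    "tukey_hsd",
]

CT_COLUMNS = ["gene", "treatment", "timepoint_h", "replicate", "ct"]


@dataclass(frozen=True)
class QpcrMeasurement:
    gene: str
    treatment: str
    timepoint_h: float
    replicate: str
    ct: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct) and self.ct > 0):
            raise ValueError(f"bad Ct {self.ct} for {self.gene}")


@dataclass
class FoldChangeResult:
    gene: str
    treatment: str
    timepoint_h: float
    fold: float
    induced: bool
    replicate_folds: list[float]
    control_folds: list[float]
    p_value: float | None = None
    significant: bool | None = None


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(df["ct"])) or (df["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    return df


def _delta_ct(df: pd.DataFrame, target: str, references: Sequence[str]) -> pd.DataFrame:
    """Per (treatment, timepoint, replicate): Ct(target) − mean Ct(references)."""
    out = []
    grouped = df.groupby(["treatment", "timepoint_h", "replicate"])
    for (treatment, tp, rep), block in grouped:
        by_gene = block.set_index("gene")["ct"]
        if target not in by_gene.index:
            continue
        missing = [r for r in references if r not in by_gene.index]
        if missing:
            raise ValueError(
                f"reference gene(s) {missing} missing in ({treatment}, {tp} h, rep {rep})"
            )
        ref_ct = float(np.mean([by_gene[r] for r in references]))
        out.append((treatment, tp, rep, float(by_gene[target]) - ref_ct))
    if not out:
        raise ValueError(f"target {target!r} not measured")
    return pd.DataFrame(out, columns=["treatment", "timepoint_h", "replicate", "dct"])


def ddct_fold(df: pd.DataFrame, target: str, references: Sequence[str],
              control_timepoint: float = 0.0, cutoff: float = 2.0,
              efficiency: float = 2.0, test: str = "welch_t",
              alpha: float = 0.05) -> list[FoldChangeResult]:
    """ΔΔCt fold changes of one target gene vs the control timepoint.

    Returns one result per (treatment, non-control timepoint), carrying the
    group fold change E^(−ΔΔCt), replicate-level folds for both groups, the
    induction call (fold >= cutoff or <= 1/cutoff), and a significance test
    against the control replicates.
    """
    dct = _delta_ct(df, target, references)
    results: list[FoldChangeResult] = []
    for treatment, block in dct.groupby("treatment"):
        control = block[block["timepoint_h"] == control_timepoint]
        if control.empty:
            raise ValueError(f"no control ({control_timepoint} h) for treatment {treatment!r}")
        control_mean = control["dct"].mean()
        control_folds = [float(efficiency ** (-(v - control_mean))) for v in control["dct"]]
        for tp, grp in block.groupby("timepoint_h"):
            if tp == control_timepoint:
                continue
            ddct = grp["dct"].mean() - control_mean
            fold = float(efficiency ** (-ddct))
            rep_folds = [float(efficiency ** (-(v - control_mean))) for v in grp["dct"]]
            res = FoldChangeResult(
                gene=target, treatment=str(treatment), timepoint_h=float(tp),
                fold=fold, induced=(fold >= cutoff or fold <= 1.0 / cutoff),
                replicate_folds=rep_folds, control_folds=control_folds,
            )
            sig, p = significance(rep_folds, control_folds, method=test, alpha=alpha)
            res.significant, res.p_value = sig, p
            results.append(res)
    return results


def significance(folds_treated: Sequence[float], folds_control: Sequence[float],
                 method: str = "welch_t", alpha: float = 0.05,
                 n_permutations: int = 10000, seed: int = 0) -> tuple[bool | None, float | None]:
    """Two-sided test on log2 folds between treated and control replicates.

    Returns (significant, p).  With fewer than 2 replicates in either group
    the result is (None, None) with a warning.  ``method`` is 'welch_t' or
    'permutation' (exact small-sample permutation of group labels).
    """
    if len(folds_treated) < 2 or len(folds_control) < 2:
        import warnings

        warnings.warn("insufficient replicates for a significance test")
        return None, None
    a = np.log2(np.asarray(folds_treated, dtype=float))
    b = np.log2(np.asarray(folds_control, dtype=float))
    if method == "welch_t":
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            return False, 1.0
        t = stats.ttest_ind(a, b, equal_var=False)
        p = float(t.pvalue)
    elif method == "permutation":
        res = stats.permutation_test(
            (a, b), lambda x, y: np.mean(x) - np.mean(y),
            permutation_type="independent", alternative="two-sided",
            n_resamples=n_permutations, rng=np.random.default_rng(seed),
        )
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return bool(p < alpha), p


def tukey_hsd(groups: dict[str, Sequence[float]], alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD over >2 groups of log2 folds (e.g. all timepoints jointly).

    Standard studentized-range procedure on the pooled within-group
    variance; returns one row per group pair with the adjusted p and the
    significance call at ``alpha``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {g: np.log2(np.asarray(v, dtype=float)) for g, v in groups.items()}
    k = len(names)
    n_total = sum(len(v) for v in data.values())
    df_err = n_total - k
    if df_err < 1:
        raise ValueError("insufficient replicates for Tukey HSD")
    mse = sum(((v - v.mean()) ** 2).sum() for v in data.values()) / df_err
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = data[names[i]], data[names[j]]
            se = math.sqrt(mse / 2 * (1 / len(a) + 1 / len(b)))
            if se == 0:
                q = 0.0 if a.mean() == b.mean() else math.inf
            else:
                q = abs(a.mean() - b.mean()) / se
            p = float(stats.studentized_range.sf(q, k, df_err))
            rows.append((names[i], names[j], a.mean() - b.mean(), q, p, p < alpha))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff_log2",
                                       "q_statistic", "p_adj", "significant"])
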