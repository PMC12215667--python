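"""Metrics, phase partitioning, and multi-run statistical comparison.

Binary detection metrics follow the conventions of the shock-advice
literature, on the 0-100 scale: sensitivity (Se) and specificity (Sp) with
LTA as the positive class, balanced accuracy BAC = (Se + Sp)/2, balanced
error rate BER = 100 - BAC, accuracy, Cohen's kappa, and the weighted and
macro averages of per-class F1 (wF1, MF1).  A report is AHA-compliant when
Se >= 90 and Sp >= 95 (the American Heart Association floor for
shock-advice algorithms).  Metrics undefined on a degenerate input (an
absent class) are NaN, never a silent zero.

Ground-truth rhythm-change points split segments into *stationary* and
*transitory* phases: the three segments before a change and the three from
the change onward are transitory (the change segment is the first segment
of the new rhythm; an exclusive reading that leaves the change segment out
is available), windows from nearby changes take their union, and phases
never cross recording boundaries.

Model comparison uses the one-sided Mann-Whitney U test over per-run
metric samples, with exact enumeration for small samples (handling ties by
enumeration) and the tie-corrected normal approximation otherwise, plus
the rank-biserial effect size r = 1 - 2U/(n1*n2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import cohen_kappa_score, f1_score

__all__ = [
    "MetricsReport",
    "compute_metrics",
    "partition_phases",
    "ComparisonResult",
    "compare_models",
    "summarize_runs",
    "METRIC_DIRECTIONS",
]

#: Comparison direction per metric ("greater" = larger is better).
METRIC_DIRECTIONS = {
    "se": "greater", "sp": "greater", "acc": "greater", "kappa": "greater",
    "wf1": "greater", "mf1": "greater", "bac": "greater", "ber": "less",
}


@dataclass
class MetricsReport:
    """Binary detection metrics on the 0-100 scale (kappa unitless)."""

    se: float
    sp: float
    bac: float
    ber: float
    acc: float
    kappa: float
    wf1: float
    mf1: float
    n_positive: int
    n_negative: int
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def aha_compliant(self) -> bool:
        return bool(self.se >= 90.0 and self.sp >= 95.0)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("se", "sp", "bac", "ber", "acc", "kappa", "wf1", "mf1")}


def compute_metrics(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    positive_class: int = 1,
    mask: np.ndarray | None = None,
) -> MetricsReport:
    """Compute the full metric set over a labeled prediction set.

    ``mask`` (True = keep) excludes noise-masked segments.  Lengths must
    match; an empty unmasked set is an error.
    """
    t = np.asarray(true_labels).ravel()
    p = np.asarray(predicted_labels).ravel()
    if len(t) != len(p):
        raise ValueError("true and predicted label vectors differ in length")
    if mask is not None:
        m = np.asarray(mask).ravel().astype(bool)
        if len(m) != len(t):
            raise ValueError("mask length mismatch")
        t, p = t[m], p[m]
    if len(t) == 0:
        raise ValueError("no unmasked segments to evaluate")
    tpos = t == positive_class
    ppos = p == positive_class
    tp = int(np.sum(tpos & ppos))
    fn = int(np.sum(tpos & ~ppos))
    tn = int(np.sum(~tpos & ~ppos))
    fp = int(np.sum(~tpos & ppos))
    se = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    bac = (se + sp) / 2.0
    acc = 100.0 * (tp + tn) / len(t)
    tb = tpos.astype(int)
    pb = ppos.astype(int)
    if tp + fn and tn + fp:
        kappa = float(cohen_kappa_score(tb, pb))
        wf1 = 100.0 * float(f1_score(tb, pb, average="weighted", zero_division=np.nan))
        mf1 = 100.0 * float(f1_score(tb, pb, average="macro", zero_division=np.nan))
    else:
        kappa = float("nan")
        wf1 = 100.0 * float(f1_score(tb, pb, average="weighted", zero_division=np.nan))
        mf1 = float("nan")
    return MetricsReport(
        se=se, sp=sp, bac=bac, ber=100.0 - bac, acc=acc, kappa=kappa, wf1=wf1, mf1=mf1,
        n_positive=tp + fn, n_negative=tn + fp, tp=tp, fn=fn, tn=tn, fp=fp,
    )


def partition_phases(
    labels_per_recording: list[np.ndarray],
    n_before: int = 3,
    n_after: int = 3,
    include_change_segment: bool = True,
) -> list[np.ndarray]:
    """Mark each segment stationary (False) or transitory (True).

    A change point is the first segment whose label differs from its
    predecessor.  With the default inclusive reading the transitory window
    at change index ``c`` is ``{c-3 .. c+2}`` (three before, three from the
    change on); the exclusive reading uses ``{c-3 .. c-1} u {c+1 .. c+3}``.
    Windows are clipped to the recording and overlapping windows merge.
    """
    out = []
    for labels in labels_per_recording:
        labels = np.asarray(labels).ravel()
        trans = np.zeros(len(labels), dtype=bool)
        changes = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        for c in changes:
            if include_change_segment:
                lo, hi = c - n_before, c + n_after  # [lo, hi)
            else:
                trans[max(c - n_before, 0) : c] = True
                lo, hi = c + 1, c + 1 + n_after
            trans[max(lo, 0) : min(hi, len(labels))] = True
        out.append(trans)
    return out


@dataclass
class ComparisonResult:
    """One-sided Mann-Whitney comparison of two metric samples."""

    metric: str
    u: float
    p: float
    direction: str  # "greater": H1 says A exceeds B; "less": A below B
    r: float  # rank-biserial, 1 - 2U/(n1*n2)
    n1: int
    n2: int
    method: str
    significant: bool

    def __post_init__(self) -> None:
        assert self.u == self.u or True


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U counting pairs where a > b (ties count half)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_p(a: np.ndarray, b: np.ndarray, direction: str) -> tuple[float, str]:
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = sstats.rankdata(pooled)  # midranks handle ties
    r1_obs = ranks[:n1].sum()
    count = 0
    total = comb(n1 + n2, n1)
    # enumerate rank-sum distribution over all group-A index choices
    for idx in combinations(range(n1 + n2), n1):
        r1 = ranks[list(idx)].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        u_obs = r1_obs - n1 * (n1 + 1) / 2.0
        if direction == "greater":
            count += u >= u_obs - 1e-9
        else:
            count += u <= u_obs + 1e-9
    return count / total, "exact_enumeration"


def compare_models(
    samples_a: list[float] | np.ndarray,
    samples_b: list[float] | np.ndarray,
    direction: str = "greater",
    metric: str = "",
    alpha: float = 0.05,
    exact_max_n: int = 20,
) -> ComparisonResult:
    """One-sided Mann-Whitney U with rank-biserial effect size.

    ``direction="greater"`` tests whether A tends to exceed B (Se, Sp,
    Acc, kappa, wF1, MF1); ``"less"`` is for error-type metrics (BER).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 samples per group")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    n1, n2 = len(a), len(b)
    u = _u_statistic(a, b)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("identical constant samples: p-value undefined", stacklevel=2)
        return ComparisonResult(metric, u, float("nan"), direction,
                                1.0 - 2.0 * u / (n1 * n2), n1, n2, "degenerate", False)
    if n1 + n2 <= exact_max_n:
        p, method = _exact_p(a, b, direction)
    else:
        res = sstats.mannwhitneyu(a, b, alternative=direction, method="asymptotic")
        p, method = float(res.pvalue), "normal_tie_corrected"
    r = 1.0 - 2.0 * u / (n1 * n2)
    return ComparisonResult(metric, u, float(p), direction, float(r), n1, n2,
                            method, bool(p < alpha))


def summarize_runs(reports: list[MetricsReport]) -> dict[str, tuple[float, float, str]]:
    """Per-metric mean and sample sd over repeated runs, formatted "xx.xx (y.yy)"."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to summarize")
    out = {}
    for key in ("se", "sp", "bac", "ber", "acc", "kappa", "wf1", "mf1"):
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        out[key] = (mean, sd, f"{mean:.2f} ({sd:.2f})")
    return out
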