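"""Study-level aggregation, method-comparison statistics, sensitivity.

Trials are grouped per subject; the subject mean and sample SD of every
scalar outcome feed a three-level summary: the overall mean is the mean
of subject means, the intra-subject variability is the mean of subject
SDs, and the inter-subject variability is the SD of subject means.

Method comparison uses a Friedman test across the five energy measures
(W, W_Z, dE_e, dE_p, dE_p_CS as columns, subjects as rows) followed by
exact Wilcoxon signed-rank tests on paired differences; with a
Bonferroni correction over five comparisons the per-test significance
level is 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .config import PipelineConfig
from .energetics import TrialEnergetics, process_records
from .errors import InputError
from .forceplate import ChannelRecord, GRFSeries
from .kinematics import MarkerSeries

__all__ = [
    "SubjectSummary",
    "StudySummary",
    "trials_frame",
    "aggregate",
    "friedman_statistic",
    "signed_rank_exact",
    "heel_point_sensitivity",
]

#: scalar outcomes carried through aggregation
AGG_VARIABLES = list(TrialEnergetics.SCALAR_FIELDS) + [
    "M_e_pct", "M_p_pct", "M_p_CS_pct", "t_e_over_t_p",
]


@dataclass
class SubjectSummary:
    subject_id: str
    n_trials: int
    mean: pd.Series
    sd: pd.Series | None  # None when n_trials < 2


@dataclass
class StudySummary:
    """Three-level summary over subjects (index = variable name)."""

    overall_mean: pd.Series
    intra_subject: pd.Series   # mean of subject SDs
    inter_subject: pd.Series   # SD of subject means
    subject_min: pd.Series
    subject_max: pd.Series
    n_subjects: int

    def table(self) -> pd.DataFrame:
        """Publication-style table: mean, range of subject means, intra; inter."""
        return pd.DataFrame({
            "overall_mean": self.overall_mean,
            "subject_min": self.subject_min,
            "subject_max": self.subject_max,
            "intra_subject": self.intra_subject,
            "inter_subject": self.inter_subject,
        })


def trials_frame(trials: list[TrialEnergetics]) -> pd.DataFrame:
    """One row per trial, one column per scalar outcome plus subject id."""
    rows = []
    for i, tr in enumerate(trials):
        d = tr.to_dict()
        rows.append({
            "subject_id": d["subject_id"] or f"S{i:03d}",
            "trial_id": d["trial_id"] or f"T{i:03d}",
            **{k: d[k] for k in AGG_VARIABLES},
        })
    return pd.DataFrame(rows)


def aggregate(
    trials: list[TrialEnergetics],
) -> tuple[list[SubjectSummary], StudySummary]:
    """Per-subject and study-level summaries of all scalar outcomes.

    SDs use the n-1 (sample) denominator; a subject with a single trial
    gets no SD and is excluded from the intra-subject mean.
    """
    if not trials:
        raise InputError("no trials to aggregate")
    df = trials_frame(trials)
    grouped = df.groupby("subject_id", sort=True)

    subjects: list[SubjectSummary] = []
    for sid, g in grouped:
        n = len(g)
        subjects.append(SubjectSummary(
            subject_id=str(sid), n_trials=n,
            mean=g[AGG_VARIABLES].mean(),
            sd=g[AGG_VARIABLES].std(ddof=1) if n >= 2 else None,
        ))

    means = pd.DataFrame({s.subject_id: s.mean for s in subjects}).T
    sds = pd.DataFrame({s.subject_id: s.sd for s in subjects if s.sd is not None}).T
    study = StudySummary(
        overall_mean=means.mean(),
        intra_subject=sds.mean() if len(sds) else means.mean() * np.nan,
        inter_subject=means.std(ddof=1) if len(means) >= 2 else means.mean() * np.nan,
        subject_min=means.min(),
        subject_max=means.max(),
        n_subjects=len(subjects),
    )
    return subjects, study


def friedman_statistic(values: np.ndarray) -> tuple[float, int, float]:
    """Friedman test for k related samples over n blocks.

    Rows are blocks (subjects), columns are methods; ranks within rows
    use mid-ranks for ties.  Returns (chi2, df, p) with

        chi2 = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1),   df = k - 1

    and the p-value from the chi-square upper tail.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise InputError("values must be an (n_blocks, k_methods) matrix")
    n, k = values.shape
    if n < 2 or k < 2:
        raise InputError(f"need at least 2 blocks and 2 methods, got {n}x{k}")
    if not np.isfinite(values).all():
        raise InputError("missing value in Friedman input")
    ranks = rankdata(values, axis=1, method="average")
    R = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float(np.sum(R**2)) - 3.0 * n * (k + 1)
    df = k - 1
    p = float(chi2.sf(stat, df))
    return float(stat), df, p


def _signed_rank_null_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled W+ over all 2^n sign patterns.

    Polynomial product of (1 + x^(2 r_i)); doubling keeps mid-ranks
    integral.  Index = doubled statistic value, entry = pattern count.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def signed_rank_exact(
    paired_diffs: np.ndarray, alpha: float = 0.01
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; |differences| are ranked with
    mid-ranks and W+ is the rank sum of the positive ones.  For n <= 20
    the p-value is exact, by enumeration of all 2^n sign assignments
    (via the generating-polynomial recursion — identical counts);
    beyond that a normal approximation with tie correction is used.
    Returns (W+, p, significant at the supplied alpha).
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise InputError("all paired differences are zero; signed-rank undefined")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= 20:
        doubled = np.rint(2.0 * ranks).astype(int)
        counts = _signed_rank_null_counts(doubled)
        total = counts.sum()  # = 2**n
        w2 = int(round(2.0 * w_plus))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        tie_term = float(np.sum(ranks**3 - ranks)) / 48.0 if ranks.size else 0.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        zstat = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(zstat)))
    return w_plus, float(p), bool(p < alpha)


def heel_point_sensitivity(
    rec: ChannelRecord | GRFSeries,
    markers: MarkerSeries,
    config: PipelineConfig | None = None,
    offset: tuple[float, float, float] = (0.01, -0.01, -0.01),
) -> tuple[TrialEnergetics, TrialEnergetics, dict[str, float]]:
    """Re-run a trial with the heel point displaced in the local frame.

    The default offset (+1 cm lateral x, -1 cm posterior y, -1 cm
    downward z) probes a point well outside any plausible heel-point
    estimation error.  Returns (baseline, shifted, per-variable relative
    change); a zero offset reproduces the baseline bit-for-bit.
    """
    base = process_records(rec, markers, config)
    shifted = process_records(rec, markers, config, r_H_offset=np.asarray(offset, float))
    deltas: dict[str, float] = {}
    for key in TrialEnergetics.SCALAR_FIELDS:
        b = getattr(base, key)
        s = getattr(shifted, key)
        if b != 0:
            deltas[key] = float((s - b) / abs(b))
        else:
            deltas[key] = 0.0 if s == b else float("inf")
    return base, shifted, deltas
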