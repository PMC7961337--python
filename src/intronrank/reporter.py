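"""Luciferase reporter-assay statistics.

Each well carries a firefly-luciferase signal (the construct under test) and
a β-galactosidase signal from a co-transfected control plasmid; the per-well
ratio firefly/β-gal removes transfection-efficiency differences. Ratios are
then expressed as fold change over the mean ratio of the promoter-only
reference construct, so the reference averages to exactly 1 by construction.
Per-construct summaries report the mean fold, the standard error of the mean
(sample SD / sqrt(n)), an unpaired two-sided t-test against the reference
(Student's pooled-variance by default, Welch optional), and the star
annotation used in the figures: ``**`` for p < 1e-10, ``*`` for p < 0.002.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateAnalysisError, FormatError, NotFoundError

__all__ = [
    "RelativeActivity",
    "normalize",
    "summarize",
    "unpaired_t",
    "stars",
    "ReporterAssay",
    "ReporterResults",
    "read_reporter_table",
]

REQUIRED_COLUMNS = ("construct_id", "replicate_id", "firefly", "betagal")

STAR_STRONG = 1e-10
STAR_WEAK = 0.002


@dataclass(frozen=True)
class RelativeActivity:
    construct_id: str
    fold_mean: float
    sem: Optional[float]
    n: int
    p_vs_reference: Optional[float] = None
    t_vs_reference: Optional[float] = None
    df_vs_reference: Optional[float] = None
    stars: str = ""


def read_reporter_table(source: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"reporter table is missing required column {col!r}")
    return df


def _validate(df: pd.DataFrame, reference: str) -> None:
    if reference not in set(df["construct_id"]):
        raise NotFoundError(f"reference construct {reference!r} not in table")
    if (df["firefly"] < 0).any():
        raise ValueError("negative firefly signal")
    zero = df.loc[df["betagal"] <= 0]
    if len(zero):
        wells = [
            f"{r.construct_id}/{r.replicate_id}" for r in zero.itertuples(index=False)
        ]
        raise ValueError(f"non-positive betagal signal in wells: {', '.join(wells)}")


def normalize(table: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Per-well fold change over the reference construct's mean ratio.

    Adds columns ``ratio`` (firefly/betagal) and ``fold`` (ratio divided by
    the mean reference ratio). Invariant under separate rescaling of all
    firefly and all betagal signals.
    """
    _validate(table, reference)
    out = table.copy()
    out["ratio"] = out["firefly"] / out["betagal"]
    ref_mean = out.loc[out["construct_id"] == reference, "ratio"].mean()
    out["fold"] = out["ratio"] / ref_mean
    return out


def summarize(folds: Sequence[float], construct_id: str = "") -> RelativeActivity:
    """Mean fold and SEM (sample SD with n-1 denominator over sqrt(n))."""
    arr = np.asarray(folds, dtype=float)
    n = arr.size
    if n == 0:
        raise ValueError("no fold values")
    if n == 1:
        warnings.warn(f"construct {construct_id!r} has a single well; SEM undefined")
        return RelativeActivity(construct_id, float(arr[0]), None, 1)
    sem = float(arr.std(ddof=1) / np.sqrt(n))
    return RelativeActivity(construct_id, float(arr.mean()), sem, n)


def unpaired_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_variance: bool = True,
) -> tuple:
    """Two-sided unpaired t-test: returns (t, df, p).

    Student's pooled-variance test by default; Welch when
    ``equal_variance=False``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise DegenerateAnalysisError(
            "zero pooled variance with unequal means; review the raw wells"
        )
    res = sps.ttest_ind(a, b, equal_var=equal_variance)
    return float(res.statistic), float(res.df), float(res.pvalue)


def stars(p: float) -> str:
    """Figure-style significance annotation: ** p<1e-10, * p<0.002."""
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    if p < STAR_STRONG:
        return "**"
    if p < STAR_WEAK:
        return "*"
    return ""


class ReporterAssay:
    """Model: per-well reporter measurements for a set of constructs.

    Parameters
    ----------
    table
        Frame with columns construct_id, replicate_id, firefly, betagal.
    reference
        The promoter-only construct whose activity defines fold = 1.
    """

    def __init__(self, table: pd.DataFrame, reference: str):
        for col in REQUIRED_COLUMNS:
            if col not in table.columns:
                raise FormatError(f"reporter table is missing column {col!r}")
        _validate(table, reference)
        counts = table.groupby("construct_id").size()
        low = counts[counts < 2]
        if reference in low.index:
            raise ValueError("reference construct needs >= 2 wells")
        self.table = table.reset_index(drop=True)
        self.reference = reference

    @classmethod
    def from_tsv(cls, source: Union[str, Path], reference: str) -> "ReporterAssay":
        return cls(read_reporter_table(source), reference)

    def fit(self, equal_variance: bool = True) -> "ReporterResults":
        norm = normalize(self.table, self.reference)
        ref_folds = norm.loc[norm["construct_id"] == self.reference, "fold"].to_numpy()
        activities = []
        for cid, grp in norm.groupby("construct_id", sort=False):
            folds = grp["fold"].to_numpy()
            base = summarize(folds, cid)
            if cid == self.reference:
                # exactly 1 by construction; remove float fuzz
                activities.append(
                    RelativeActivity(cid, 1.0, base.sem, base.n)
                )
                continue
            if folds.size >= 2:
                t, df, p = unpaired_t(folds, ref_folds, equal_variance)
                activities.append(
                    RelativeActivity(
                        cid, base.fold_mean, base.sem, base.n,
                        p_vs_reference=p, t_vs_reference=t, df_vs_reference=df,
                        stars=stars(p),
                    )
                )
            else:
                activities.append(base)
        return ReporterResults(self, norm, activities)


class ReporterResults:
    """Fitted reporter analysis: per-construct relative activities."""

    def __init__(
        self,
        model: ReporterAssay,
        normalized: pd.DataFrame,
        activities: list,
    ):
        self.model = model
        self.normalized = normalized
        self.activities = activities

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "construct_id": a.construct_id,
                    "fold_mean": a.fold_mean,
                    "sem": a.sem,
                    "n": a.n,
                    "p_vs_reference": a.p_vs_reference,
                    "stars": a.stars,
                }
                for a in self.activities
            ]
        )

    def summary(self) -> str:
        lines = [
            f"Relative luciferase activity (reference = {self.model.reference})",
            "=" * 60,
            self.summary_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        self.summary_frame().to_csv(path, sep="\t", index=False)
        return path
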