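"""Sequential intron enrichment: the step-down Wilcoxon exclusion procedure.

Given per-intron collections of variant functional scores, the procedure

1. gates the analysis with a tie-corrected Kruskal-Wallis test over all
   non-empty introns (a global "is anything different?" statistic),
2. in each round tests every remaining intron's scores against the pooled
   scores of all *other remaining* introns with a one-sided Mann-Whitney U
   test (upper tail: higher functional scores),
3. removes the most significant intron if its p-value clears a fixed
   Bonferroni threshold alpha/m (m = number of introns at the start, never
   recomputed), records the p-value and round, and repeats,
4. stops when no remaining intron clears the threshold; each survivor keeps
   its final-round p-value.

The ranking is: removed introns in removal order, then survivors by
ascending final-round p, then introns that never had a scored variant.
Ties for the round minimum are broken toward the intron with more variants,
then the lower index, and are logged — the removal order is deterministic.

The public surface follows the Model/Results convention: build an
``IntronEnrichment`` from score sets, a long-format DataFrame, or the
standard input files; ``fit`` returns an ``IntronEnrichmentResults`` with
the global test, the sequential ranking, per-intron distribution summaries
and TSV/JSON writers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import rank_stats
from .errors import EmptyAnalysisError
from .rank_stats import RankTestResult, bonferroni_threshold, kruskal_wallis, mwu_one_sided_greater
from .score_table import IntronScoreSet

__all__ = [
    "IntronRank",
    "SequentialResult",
    "sequential_enrichment",
    "global_test",
    "boxplot_summary",
    "IntronEnrichment",
    "IntronEnrichmentResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntronRank:
    intron_index: int
    p_last: Optional[float]  # None for never-testable (empty) introns
    round_assigned: Optional[int]
    significant: bool
    n_variants: int
    method: Optional[str] = None  # provenance of the last test


@dataclass
class SequentialResult:
    """Ordered intron ranking with per-round one-sided Wilcoxon p-values."""

    ranking: list  # list[IntronRank], best first
    alpha: float
    m: int
    threshold: float
    tie_events: list = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return sum(1 for r in self.ranking if r.significant)

    @property
    def significant_indices(self) -> list:
        """Intron indices declared significant, in removal order."""
        return [r.intron_index for r in self.ranking if r.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "intron_index": r.intron_index,
                    "p_last": r.p_last,
                    "round_assigned": r.round_assigned,
                    "significant": r.significant,
                    "n_variants": r.n_variants,
                    "method": r.method,
                }
                for i, r in enumerate(self.ranking)
            ]
        )


def sequential_enrichment(
    score_sets: Sequence[IntronScoreSet],
    alpha: float = 0.05,
) -> SequentialResult:
    """Run the sequential one-sided Wilcoxon exclusion over ``score_sets``.

    The Bonferroni threshold is alpha/m with m = len(score_sets), fixed for
    every round. Previously removed introns' variants are excluded from the
    pooled background of later rounds.
    """
    m = len(score_sets)
    if m < 2:
        raise EmptyAnalysisError("sequential procedure requires >= 2 introns")
    threshold = bonferroni_threshold(alpha, m)

    by_index = {s.intron_index: s for s in score_sets}
    if len(by_index) != m:
        raise ValueError("duplicate intron indices in score sets")
    empty = [s for s in score_sets if s.n_variants == 0]
    remaining = [s for s in score_sets if s.n_variants > 0]

    removed: list = []
    tie_events: list = []
    last_round: dict = {}
    round_no = 0
    while len(remaining) >= 2:
        round_no += 1
        results = []
        for s in remaining:
            background = np.concatenate(
                [o.scores for o in remaining if o.intron_index != s.intron_index]
            )
            res = mwu_one_sided_greater(s.scores, background)
            results.append((s, res))
            last_round[s.intron_index] = (res, round_no)
        p_min = min(r.p for _, r in results)
        candidates = [(s, r) for s, r in results if r.p == p_min]
        if len(candidates) > 1:
            # deterministic tie-break: larger n_variants, then lower index
            candidates.sort(key=lambda sr: (-sr[0].n_variants, sr[0].intron_index))
            tie_events.append(
                {
                    "round": round_no,
                    "p": p_min,
                    "introns": [s.intron_index for s, _ in candidates],
                }
            )
            logger.info(
                "round %d: %d introns tied at p=%.3g; kept intron %d",
                round_no,
                len(candidates),
                p_min,
                candidates[0][0].intron_index,
            )
        winner, winner_res = candidates[0]
        if winner_res.p < threshold:
            removed.append(
                IntronRank(
                    intron_index=winner.intron_index,
                    p_last=winner_res.p,
                    round_assigned=round_no,
                    significant=True,
                    n_variants=winner.n_variants,
                    method=winner_res.method,
                )
            )
            remaining = [s for s in remaining if s.intron_index != winner.intron_index]
        else:
            break

    survivors = []
    for s in remaining:
        if s.intron_index in last_round:
            res, rnd = last_round[s.intron_index]
            survivors.append(
                IntronRank(
                    intron_index=s.intron_index,
                    p_last=res.p,
                    round_assigned=rnd,
                    significant=False,
                    n_variants=s.n_variants,
                    method=res.method,
                )
            )
        else:
            # sole survivor of a fully significant cascade never got a final
            # round of its own; it keeps no p-value
            survivors.append(
                IntronRank(
                    intron_index=s.intron_index,
                    p_last=None,
                    round_assigned=None,
                    significant=False,
                    n_variants=s.n_variants,
                )
            )
    survivors.sort(
        key=lambda r: (
            r.p_last if r.p_last is not None else np.inf,
            -r.n_variants,
            r.intron_index,
        )
    )
    never_testable = [
        IntronRank(
            intron_index=s.intron_index,
            p_last=None,
            round_assigned=None,
            significant=False,
            n_variants=0,
        )
        for s in sorted(empty, key=lambda s: s.intron_index)
    ]
    return SequentialResult(
        ranking=removed + survivors + never_testable,
        alpha=alpha,
        m=m,
        threshold=threshold,
        tie_events=tie_events,
    )


def global_test(score_sets: Sequence[IntronScoreSet]) -> RankTestResult:
    """Kruskal-Wallis gate over all non-empty introns (df = k - 1)."""
    groups = [s.scores for s in score_sets if s.n_variants > 0]
    if len(groups) < 2:
        raise EmptyAnalysisError("global test requires >= 2 non-empty introns")
    return kruskal_wallis(groups)


def boxplot_summary(score_sets: Sequence[IntronScoreSet]) -> pd.DataFrame:
    """Per-intron five-number summary plus mean and variant count.

    Quartiles use linear interpolation; empty introns yield all-NaN rows
    with n_variants = 0.
    """
    rows = []
    for s in sorted(score_sets, key=lambda s: s.intron_index):
        if s.n_variants == 0:
            rows.append(
                {
                    "intron_index": s.intron_index,
                    "min": np.nan,
                    "q1": np.nan,
                    "median": np.nan,
                    "q3": np.nan,
                    "max": np.nan,
                    "mean": np.nan,
                    "n_variants": 0,
                }
            )
            continue
        q1, med, q3 = np.quantile(s.scores, [0.25, 0.5, 0.75])
        rows.append(
            {
                "intron_index": s.intron_index,
                "min": float(s.scores.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(s.scores.max()),
                "mean": float(s.scores.mean()),
                "n_variants": s.n_variants,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results


class IntronEnrichment:
    """Model: per-intron functional-score distributions for one gene.

    Parameters
    ----------
    score_sets
        One :class:`IntronScoreSet` per intron (empty sets allowed; they
        keep the Bonferroni family size honest and are ranked last).
    legacy_map
        Optional current->legacy intron nomenclature mapping carried through
        to reports.
    """

    def __init__(
        self,
        score_sets: Sequence[IntronScoreSet],
        legacy_map: Optional[Mapping[int, int]] = None,
    ):
        self.score_sets = sorted(score_sets, key=lambda s: s.intron_index)
        self.legacy_map = dict(legacy_map or {})
        self.assignment_counts: dict = {}

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        intron_col: str = "intron_index",
        score_col: str = "score",
        n_introns: Optional[int] = None,
        **kwargs,
    ) -> "IntronEnrichment":
        """Build from a long-format frame with one row per scored variant."""
        idx = df[intron_col].astype(int)
        top = n_introns if n_introns is not None else int(idx.max())
        sets = []
        for i in range(1, top + 1):
            sets.append(
                IntronScoreSet(
                    intron_index=i,
                    scores=df.loc[idx == i, score_col].to_numpy(dtype=float),
                )
            )
        return cls(sets, **kwargs)

    @classmethod
    def from_files(
        cls,
        annotation: Union[str, Path],
        vcf: Union[str, Path],
        scores_tsv: Union[str, Path],
        gene_or_transcript_id: str,
        *,
        score_column: str = "GWAS3D",
        build: str = "unspecified",
        legacy_map: Optional[Mapping[int, int]] = None,
    ) -> "IntronEnrichment":
        """Standard-pipeline constructor: annotation + VCF + score TSV."""
        from .gene_model import extract_introns, read_gene_model, read_variants
        from .score_table import build_intron_score_sets, read_scores

        model = read_gene_model(annotation, gene_or_transcript_id, build=build)
        introns = extract_introns(model, legacy_map)
        variants = read_variants(vcf, build=build)
        scores = read_scores(scores_tsv, score_column=score_column)
        assignment = build_intron_score_sets(variants, scores, introns, model)
        obj = cls(
            assignment.score_sets,
            legacy_map={i.index: i.legacy_index for i in introns if i.legacy_index},
        )
        obj.assignment_counts = {
            "n_total": assignment.n_total,
            "n_scored_intronic": assignment.n_scored_intronic,
            "n_unmatched": assignment.n_unmatched,
            "n_nonintronic": assignment.n_nonintronic,
        }
        return obj

    def fit(self, alpha: float = 0.05) -> "IntronEnrichmentResults":
        """Run the global gate and the sequential exclusion procedure."""
        gate = global_test(self.score_sets)
        seq = sequential_enrichment(self.score_sets, alpha=alpha)
        return IntronEnrichmentResults(self, gate, seq)


class IntronEnrichmentResults:
    """Fitted enrichment analysis: gate statistic, ranking, summaries."""

    def __init__(
        self,
        model: IntronEnrichment,
        global_result: RankTestResult,
        sequential: SequentialResult,
    ):
        self.model = model
        self.global_result = global_result
        self.sequential = sequential

    @property
    def n_significant(self) -> int:
        return self.sequential.n_significant

    @property
    def significant_introns(self) -> list:
        return self.sequential.significant_indices

    def ranking_frame(self) -> pd.DataFrame:
        df = self.sequential.to_frame()
        df.insert(
            2,
            "legacy_index",
            df["intron_index"].map(self.model.legacy_map).astype("Int64"),
        )
        return df

    def boxplot_frame(self) -> pd.DataFrame:
        return boxplot_summary(self.model.score_sets)

    def manifest(self) -> dict:
        return {
            "alpha": self.sequential.alpha,
            "m": self.sequential.m,
            "threshold": self.sequential.threshold,
            "n_significant": self.n_significant,
            "significant_introns": self.significant_introns,
            "global_test": self.global_result.to_dict(),
            "tie_events": self.sequential.tie_events,
            "assignment_counts": self.model.assignment_counts,
        }

    def summary(self) -> str:
        g = self.global_result
        lines = [
            "Intron enrichment (sequential one-sided Wilcoxon exclusion)",
            "=" * 60,
            f"Introns (m): {self.sequential.m}    alpha: {self.sequential.alpha}"
            f"    threshold: {self.sequential.threshold:.3g}",
            f"Global Kruskal-Wallis: H = {g.statistic:.4g}, df = {g.df}, "
            f"p = {g.p:.3g}",
            f"Significant introns: {self.n_significant} "
            f"{self.significant_introns}",
            "",
            self.ranking_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    def save(self, outdir: Union[str, Path]) -> dict:
        """Write ranking TSV, boxplot-summary TSV and the JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ranking": outdir / "ranking.tsv",
            "boxplot_summary": outdir / "boxplot_summary.tsv",
            "manifest": outdir / "manifest.json",
        }
        self.ranking_frame().to_csv(paths["ranking"], sep="\t", index=False)
        self.boxplot_frame().to_csv(paths["boxplot_summary"], sep="\t", index=False)
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest(), fh, indent=2, default=float)
            fh.write("\n")
        return paths
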