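"""Per-variant functional-score input and per-intron score sets.

Scores arrive as a (possibly bgzipped) TSV with at least chrom, pos, ref,
alt and one score column; they are joined to variants on the full
(chrom, pos, ref, alt) tuple because multi-allelic sites carry
allele-specific scores. The join product is a list of per-intron score
collections — the unit on which all rank tests operate. Introns without any
scored variant are retained with empty score lists so intron indexing stays
stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import EmptyAnalysisError, FormatError
from .gene_model import GeneModel, IntronRecord, Variant, assign_variant

__all__ = ["IntronScoreSet", "IntronAssignment", "read_scores", "build_intron_score_sets"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class IntronScoreSet:
    """Functional scores of the variants assigned to one intron."""

    intron_index: int
    scores: np.ndarray
    variant_ids: Optional[list] = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def n_variants(self) -> int:
        return int(self.scores.size)


@dataclass
class IntronAssignment:
    """Join product plus the filtering tallies the inputs never report."""

    score_sets: list
    n_unmatched: int  # intronic variants with no score record
    n_nonintronic: int  # variants outside every intron (exonic/intergenic)
    n_total: int  # alt-allele records considered

    @property
    def n_scored_intronic(self) -> int:
        return sum(s.n_variants for s in self.score_sets)


def read_scores(
    source: Union[str, Path],
    *,
    score_column: str = "GWAS3D",
) -> pd.DataFrame:
    """Read a per-variant score TSV into a frame keyed by (chrom, pos, ref, alt).

    Exact-duplicate keys keep the first record (warned); rows with missing or
    non-numeric scores are dropped and counted in ``df.attrs``.
    """
    df = pd.read_csv(
        source,
        sep="\t",
        dtype={"chrom": str, "ref": str, "alt": str},
        compression="infer",
    )
    df.columns = [c.lstrip("#") for c in df.columns]
    for col in (*REQUIRED_COLUMNS, score_column):
        if col not in df.columns:
            raise FormatError(f"score table is missing required column {col!r}")
    df = df[[*REQUIRED_COLUMNS, score_column]].rename(
        columns={score_column: "score"}
    )
    df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(int)
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    bad = ~np.isfinite(df["score"].to_numpy())
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning("dropped %d rows with missing/non-numeric scores", n_dropped)
        df = df.loc[~bad]
    dup = df.duplicated(subset=list(REQUIRED_COLUMNS), keep="first")
    n_duplicates = int(dup.sum())
    if n_duplicates:
        logger.warning("dropped %d duplicate (chrom,pos,ref,alt) rows", n_duplicates)
        df = df.loc[~dup]
    df = df.reset_index(drop=True)
    df.attrs["n_dropped_scores"] = n_dropped
    df.attrs["n_duplicates"] = n_duplicates
    return df


def build_intron_score_sets(
    variants: Sequence[Variant],
    scores: pd.DataFrame,
    introns: Sequence[IntronRecord],
    model: Optional[GeneModel] = None,
) -> IntronAssignment:
    """Join variants to scores and group the scores by containing intron.

    A variant contributes one score per matching (chrom, pos, ref, alt)
    record; intronic variants lacking a score record are counted and
    excluded. Every intron appears in the output, possibly empty. The result
    is invariant to input row order.
    """
    lookup = {
        (r.chrom, int(r.pos), r.ref, r.alt): float(r.score)
        for r in scores.itertuples(index=False)
    }
    per_intron: dict = {i.index: ([], []) for i in introns}
    n_unmatched = 0
    n_nonintronic = 0
    for v in variants:
        idx = assign_variant(v, introns, model)
        if idx is None:
            n_nonintronic += 1
            continue
        key = (v.chrom, v.pos, v.ref, v.alt)
        if key not in lookup:
            n_unmatched += 1
            continue
        vals, vids = per_intron[idx]
        vals.append(lookup[key])
        vids.append(v.vid)
    # deterministic order regardless of input row order
    sets = []
    for i in sorted(per_intron):
        vals, vids = per_intron[i]
        pairs = sorted(zip(vals, vids), key=lambda p: (p[0], str(p[1])))
        sets.append(
            IntronScoreSet(
                intron_index=i,
                scores=np.asarray([p[0] for p in pairs], dtype=float),
                variant_ids=[p[1] for p in pairs],
            )
        )
    assignment = IntronAssignment(
        score_sets=sets,
        n_unmatched=n_unmatched,
        n_nonintronic=n_nonintronic,
        n_total=len(variants),
    )
    if assignment.n_scored_intronic == 0:
        raise EmptyAnalysisError("no scored intronic variants; nothing to analyse")
    logger.info(
        "assigned %d/%d variants to introns (%d unmatched, %d non-intronic)",
        assignment.n_scored_intronic,
        len(variants),
        n_unmatched,
        n_nonintronic,
    )
    return assignment


def score_sets_to_tsv(score_sets: Sequence[IntronScoreSet], path_or_buf) -> pd.DataFrame:
    """Long-format per-intron score dump (intron_index, vid, score)."""
    rows = []
    for s in score_sets:
        vids = s.variant_ids or [None] * s.n_variants
        for vid, sc in zip(vids, s.scores):
            rows.append({"intron_index": s.intron_index, "vid": vid, "score": sc})
    df = pd.DataFrame(rows, columns=["intron_index", "vid", "score"])
    df.to_csv(path_or_buf, sep="\t", index=False)
    return df
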