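"""Gene structure: exon/intron coordinates, variant assignment, legacy labels.

The coordinate authority for the whole analysis is a single transcript's exon
chain. Internally everything is 1-based inclusive (the VCF convention); BED12
input is converted on read. Introns are numbered in transcription order, so
on the minus strand intron 1 is the gap with the highest genomic coordinates.

The "legacy DHS label" reproduces the historical way regulatory elements in
this locus are named: the coding-sequence ordinal of the last coding base of
the exon immediately upstream of the intron, plus the intronic offset in kb
(e.g. ``"4374 + 1.3 kb"``). The offset is measured to the queried position
itself; callers wanting the conventional label for an interval should pass
the 5'-most base of the element in transcription order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import (
    BuildMismatchError,
    MalformedAnnotationError,
    NotFoundError,
    UnusableModelError,
)

__all__ = [
    "GeneModel",
    "IntronRecord",
    "Variant",
    "DEFAULT_LEGACY_MAP",
    "read_gene_model",
    "read_variants",
    "extract_introns",
    "assign_variant",
    "legacy_dhs_label",
    "introns_to_tsv",
]

#: legacy <-> current intron nomenclature correspondences that are published
#: for this locus; anything else must be supplied by the user
DEFAULT_LEGACY_MAP: Mapping[int, int] = {12: 11, 24: 21, 26: 23}


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vid: Optional[str] = None
    build: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are 1-based inclusive (start, end) tuples sorted by genomic
    start, pairwise non-overlapping. ``cds_start``/``cds_end`` bound the
    coding region genomically (strand-independent); they may be None for a
    non-coding annotation, in which case legacy labels are unavailable.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    build: str = "unspecified"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if s > e:
                raise MalformedAnnotationError(f"exon ({s},{e}) has start > end")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise MalformedAnnotationError(
                    f"exons ({s1},{e1}) and ({s2},{e2}) overlap"
                )
        object.__setattr__(self, "exons", exons)
        if (self.cds_start is None) != (self.cds_end is None):
            raise MalformedAnnotationError("cds_start/cds_end must be set together")
        if self.cds_start is not None:
            if not (exons[0][0] <= self.cds_start <= self.cds_end <= exons[-1][1]):
                raise MalformedAnnotationError("CDS interval outside exon span")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class IntronRecord:
    index: int  # 1-based, transcription order
    start: int  # genomic, 1-based inclusive
    end: int
    legacy_index: Optional[int] = None

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# readers


def _dedupe_exons(exons: Sequence[tuple]) -> list:
    seen = set()
    out = []
    for iv in sorted(exons):
        if iv not in seen:
            seen.add(iv)
            out.append(iv)
    return out


def _read_bed12(path: Path, name: str) -> dict:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise MalformedAnnotationError(
                    f"BED12 requires 12 columns, got {len(fields)}"
                )
            if fields[3] == name:
                rows.append(fields)
    if not rows:
        raise NotFoundError(f"no BED12 record named {name!r}")
    if len(rows) > 1:
        raise MalformedAnnotationError(f"multiple BED12 records named {name!r}")
    f = rows[0]
    chrom, chrom_start = f[0], int(f[1])
    strand = f[5] if f[5] in ("+", "-") else "+"
    thick_start, thick_end = int(f[6]), int(f[7])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
        raise MalformedAnnotationError("blockCount disagrees with block lists")
    exons = [
        (chrom_start + bs + 1, chrom_start + bs + sz)
        for bs, sz in zip(starts, sizes)
    ]
    cds = None
    if thick_end > thick_start:
        cds = (thick_start + 1, thick_end)
    return {
        "gene_id": name,
        "transcript_id": name,
        "chrom": chrom,
        "strand": strand,
        "exons": exons,
        "cds": cds,
    }


def _read_gff3(path: Path, name: str) -> dict:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    def _matches(feat) -> bool:
        parents = feat.attributes.get("Parent", [])
        tid = feat.attributes.get("transcript_id", [])
        return name in parents or name in tid

    exon_feats = [f for f in db.features_of_type("exon") if _matches(f)]
    transcript_id = name
    if not exon_feats:
        # maybe a gene id: require exactly one child transcript with exons
        children = [
            f
            for t in ("mRNA", "transcript")
            for f in db.features_of_type(t)
            if name in f.attributes.get("Parent", [])
        ]
        if len(children) == 1:
            transcript_id = children[0].id
            exon_feats = [
                f
                for f in db.features_of_type("exon")
                if transcript_id in f.attributes.get("Parent", [])
            ]
        elif len(children) > 1:
            raise MalformedAnnotationError(
                f"gene {name!r} has {len(children)} transcripts; pass a transcript id"
            )
    if not exon_feats:
        raise NotFoundError(f"no exon features for {name!r}")

    chroms = {f.seqid for f in exon_feats}
    strands = {f.strand for f in exon_feats}
    if len(chroms) != 1 or len(strands) != 1:
        raise MalformedAnnotationError("exons span multiple chromosomes/strands")
    cds_feats = [
        f
        for f in db.features_of_type("CDS")
        if transcript_id in f.attributes.get("Parent", []) or _matches(f)
    ]
    cds = None
    if cds_feats:
        cds = (min(f.start for f in cds_feats), max(f.end for f in cds_feats))
    gene_id = exon_feats[0].attributes.get("gene_id", [name])[0]
    return {
        "gene_id": gene_id,
        "transcript_id": transcript_id,
        "chrom": chroms.pop(),
        "strand": strands.pop(),
        "exons": [(f.start, f.end) for f in exon_feats],
        "cds": cds,
    }


def read_gene_model(
    annotation: Union[str, Path],
    gene_or_transcript_id: str,
    *,
    build: str = "unspecified",
    fmt: Optional[str] = None,
) -> GeneModel:
    """Read one transcript's exon/CDS structure from GFF3 or BED12.

    ``fmt`` may be "gff3" or "bed12"; by default it is inferred from the
    file extension, falling back to content sniffing.
    """
    path = Path(annotation)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in (".gff", ".gff3"):
            fmt = "gff3"
        elif suffix == ".bed":
            fmt = "bed12"
        else:
            with open(path) as fh:
                head = fh.readline()
            fmt = "gff3" if ("gff" in head or "=" in head.split("\t")[-1]) else "bed12"
    if fmt == "gff3":
        raw = _read_gff3(path, gene_or_transcript_id)
    elif fmt == "bed12":
        raw = _read_bed12(path, gene_or_transcript_id)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    exons = _dedupe_exons(raw["exons"])
    if len(exons) < 2:
        raise UnusableModelError(
            f"{gene_or_transcript_id!r} has {len(exons)} exon(s); "
            "intron analysis requires at least 2"
        )
    cds = raw["cds"]
    return GeneModel(
        gene_id=raw["gene_id"],
        transcript_id=raw["transcript_id"],
        chrom=raw["chrom"],
        strand=raw["strand"],
        exons=tuple(exons),
        cds_start=None if cds is None else cds[0],
        cds_end=None if cds is None else cds[1],
        build=build,
    )


def read_variants(
    vcf_path: Union[str, Path], *, build: str = "unspecified"
) -> list:
    """Read a VCF into a list of Variant records, one per alt allele."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(vcf_path)):
        for alt in rec.ALT:
            out.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    vid=rec.ID,
                    build=build,
                )
            )
    return out


# ---------------------------------------------------------------------------
# intron machinery


def extract_introns(
    model: GeneModel,
    legacy_map: Optional[Mapping[int, int]] = None,
) -> list:
    """Introns of ``model`` in transcription order.

    Intron i spans the gap strictly between exons i and i+1; on the minus
    strand indices are assigned from the highest-coordinate gap downwards.
    Zero-length gaps (abutting exons) consume an index but yield no record.
    """
    if model.n_exons < 2:
        raise UnusableModelError("intron extraction requires >= 2 exons")
    if legacy_map is None:
        legacy_map = DEFAULT_LEGACY_MAP
    gaps = []
    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        gaps.append((e1 + 1, s2 - 1))
    n = len(gaps)
    records = []
    for genomic_i, (gs, ge) in enumerate(gaps, start=1):
        index = genomic_i if model.strand == "+" else n + 1 - genomic_i
        if gs > ge:
            warnings.warn(
                f"zero-length intron at transcription index {index}; "
                "record omitted, index preserved"
            )
            continue
        records.append(
            IntronRecord(
                index=index,
                start=gs,
                end=ge,
                legacy_index=legacy_map.get(index),
            )
        )
    records.sort(key=lambda r: r.index)
    return records


def assign_variant(
    variant: Variant,
    introns: Sequence[IntronRecord],
    model: Optional[GeneModel] = None,
) -> Optional[int]:
    """Index of the intron containing ``variant.pos``, or None.

    Assignment is by VCF position only; exonic and intergenic positions map
    to None. If ``model`` is given, chromosome and genome build are checked.
    """
    if model is not None:
        if variant.build and model.build and variant.build != model.build:
            raise BuildMismatchError(
                f"variant build {variant.build!r} != model build {model.build!r}"
            )
        if variant.chrom != model.chrom:
            return None
    for intron in introns:
        if intron.contains(variant.pos):
            return intron.index
    return None


def _coding_bases_through_exon(model: GeneModel, tx_exon_ordinal: int) -> int:
    """Coding bases from the CDS start (transcription order) through the end
    of transcription-order exon ``tx_exon_ordinal`` (1-based)."""
    exons = list(model.exons)
    if model.strand == "-":
        exons = exons[::-1]
    total = 0
    for s, e in exons[:tx_exon_ordinal]:
        lo = max(s, model.cds_start)
        hi = min(e, model.cds_end)
        if hi >= lo:
            total += hi - lo + 1
    return total


def legacy_dhs_label(
    pos: int,
    model: GeneModel,
    introns: Sequence[IntronRecord],
) -> str:
    """Historical label "C + O kb" for an intronic position.

    C is the CDS ordinal of the last coding base of the exon immediately
    upstream (transcription order) of the containing intron; O is the
    distance from the first intronic base (transcription order) to ``pos``
    in kb, one decimal.
    """
    if model.cds_start is None:
        raise ValueError("model has no CDS; legacy label undefined")
    hit = next((i for i in introns if i.contains(pos)), None)
    if hit is None:
        raise ValueError(f"position {pos} is not intronic")
    coding = _coding_bases_through_exon(model, hit.index)
    if coding == 0:
        raise ValueError(
            f"position {pos} lies upstream of the CDS; label undefined"
        )
    offset = pos - hit.start if model.strand == "+" else hit.end - pos
    return f"{coding} + {offset / 1000:.1f} kb"


def introns_to_tsv(
    model: GeneModel,
    introns: Iterable[IntronRecord],
    path_or_buf,
) -> pd.DataFrame:
    """Write the intron table (index, chrom, start, end, legacy_index,
    length_bp) as TSV and return it as a DataFrame."""
    df = pd.DataFrame(
        [
            {
                "index": i.index,
                "chrom": model.chrom,
                "start": i.start,
                "end": i.end,
                "legacy_index": i.legacy_index,
                "length_bp": i.length_bp,
            }
            for i in sorted(introns, key=lambda r: r.index)
        ]
    )
    df.to_csv(path_or_buf, sep="\t", index=False)
    return df
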