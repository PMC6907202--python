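"""Genomic feature classification and length-normalized variant rates.

Every base of every contig is assigned to exactly one of four classes:
exon, intron, intergenic repeat, or non-repetitive intergenic space.
Precedence is exon > intron > repeat > remaining intergenic, so repeat
intervals overlapping genic bases contribute only their intergenic portion
("repeats" always means intergenic repeats).  The index is a per-contig byte
array, which makes the tiling invariant (no overlap, no gap) hold by
construction and position lookup O(1).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .genes import GeneModel

EXON = "exon"
INTRON = "intron"
REPEAT = "intergenic-repeat"
NONREP = "intergenic-nonrepetitive"
FEATURE_CLASSES: tuple[str, ...] = (EXON, INTRON, REPEAT, NONREP)

_CODE = {name: i for i, name in enumerate(FEATURE_CLASSES)}


class AnnotationError(ValueError):
    """An annotation interval is inconsistent with the contigs."""


@dataclass
class FeatureIndex:
    """Per-contig feature-class code arrays plus class length totals."""

    codes: dict[str, np.ndarray]  # uint8 per base, values index FEATURE_CLASSES

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.codes.items()}

    @property
    def class_lengths(self) -> dict[str, int]:
        totals = np.zeros(len(FEATURE_CLASSES), dtype=np.int64)
        for arr in self.codes.values():
            totals += np.bincount(arr, minlength=len(FEATURE_CLASSES))
        return {name: int(totals[i]) for name, i in _CODE.items()}

    def class_of(self, contig: str, position: int) -> str:
        """Feature class of a 1-based position."""
        arr = self.codes[contig]
        if not 1 <= position <= len(arr):
            raise AnnotationError(
                f"position {contig}:{position} outside contig (length {len(arr)})"
            )
        return FEATURE_CLASSES[arr[position - 1]]

    def intervals(self) -> Iterator[tuple[str, int, int, str]]:
        """Yield maximal runs as (contig, start0, end0, class), half-open."""
        for contig in sorted(self.codes):
            arr = self.codes[contig]
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [len(arr)]))
            for s, e in zip(starts, ends):
                yield contig, int(s), int(e), FEATURE_CLASSES[arr[s]]


def build_feature_index(
    genes: Sequence[GeneModel],
    repeats: Iterable[tuple[str, int, int]],
    contig_lengths: Mapping[str, int],
) -> FeatureIndex:
    """Tile contigs into the four classes.

    ``repeats`` are BED-style (contig, start0, end0) half-open intervals.
    Overlapping exons of different transcripts merge implicitly; genic bases
    always win over repeat bases.
    """
    codes = {
        c: np.full(n, _CODE[NONREP], dtype=np.uint8)
        for c, n in contig_lengths.items()
    }
    for contig, s, e in repeats:
        if contig not in codes:
            raise AnnotationError(f"repeat interval on unknown contig {contig!r}")
        if s < 0 or e > len(codes[contig]) or s >= e:
            raise AnnotationError(
                f"repeat interval {contig}:{s}-{e} outside contig bounds"
            )
        codes[contig][s:e] = _CODE[REPEAT]
    # paint gene spans intron first, then exons on top: precedence exon>intron
    for g in genes:
        if g.contig not in codes:
            raise AnnotationError(f"gene {g.gene_id} on unknown contig {g.contig!r}")
        if g.end > len(codes[g.contig]) or g.start < 1:
            raise AnnotationError(
                f"gene {g.gene_id} span {g.start}-{g.end} outside contig bounds"
            )
        codes[g.contig][g.start - 1:g.end] = _CODE[INTRON]
    for g in genes:
        for s, e in g.exons:
            codes[g.contig][s - 1:e] = _CODE[EXON]
    return FeatureIndex(codes=codes)


def classify_position(index: FeatureIndex, contig: str, position: int) -> str:
    return index.class_of(contig, position)


def affected_position(position: int, ref: str, alt: str) -> int:
    """Leftmost reference base an allele change affects (1-based).

    SNVs and insertions affect the anchor base; deletions affect the first
    deleted base (anchor + 1).
    """
    if len(ref) > 1 and len(alt) < len(ref):
        return position + 1
    return position


def normalized_rates(
    counts: pd.DataFrame,
    index: FeatureIndex,
    *,
    per_clone: int | None = None,
) -> pd.DataFrame:
    """Attach per-kb rates to a count table.

    ``counts`` needs a ``feature`` column and a ``count`` column; any other
    columns (variant type, zygosity, sample group) pass through.  The rate is
    count / class_bp * 1000, optionally divided by ``per_clone`` to express a
    per-clone rate.
    """
    lengths = index.class_lengths
    out = counts.copy()
    bp = out["feature"].map(lengths)
    if (bp.isna() | (bp == 0)).any():
        bad = out.loc[bp.isna() | (bp == 0), "feature"].unique()
        if (out.loc[bp.isna() | (bp == 0), "count"] > 0).any():
            raise AnnotationError(
                f"nonzero variant count in zero-length feature class(es): {bad}"
            )
    out["feature_bp"] = bp.astype("Int64")
    denom = bp.astype(float) * (per_clone if per_clone else 1)
    out["rate_per_kb"] = out["count"] / denom * 1000.0
    return out


def nearest_gene_distances(
    te_table: pd.DataFrame,
    genes: Sequence[GeneModel],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distances from TE insertion points to the closest gene on each side.

    Returns (per-insertion table, summary).  Genic insertions get distance 0
    on both sides and ``genic=True``.  Where no gene lies on one side of an
    intergenic insertion, that distance is NA.  The summary reports the
    median up/downstream distance of intergenic insertions and the 25th
    percentile of the per-insertion minimum distance.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        spans.setdefault(g.contig, []).append((g.start, g.end))
    rows = []
    for rec in te_table.itertuples(index=False):
        contig, pos = rec.contig, int(rec.position)
        gspans = spans.get(contig, [])
        genic = any(s <= pos <= e for s, e in gspans)
        if genic:
            up: float | None = 0.0
            down: float | None = 0.0
        else:
            lefts = [pos - e for _, e in gspans if e < pos]
            rights = [s - pos for s, _ in gspans if s > pos]
            up = float(min(lefts)) if lefts else None
            down = float(min(rights)) if rights else None
        rows.append({"contig": contig, "position": pos, "genic": genic,
                     "upstream": up, "downstream": down})
    table = pd.DataFrame(rows)
    inter = table.loc[~table["genic"]]
    nearest = inter[["upstream", "downstream"]].min(axis=1, skipna=True)
    summary = pd.DataFrame([{
        "n_genic": int(table["genic"].sum()),
        "n_intergenic": int((~table["genic"]).sum()),
        "median_upstream": inter["upstream"].median(),
        "median_downstream": inter["downstream"].median(),
        "q25_nearest": nearest.quantile(0.25) if len(nearest) else np.nan,
    }])
    return table, summary


def summarize_svs(
    svs: pd.DataFrame,
    genes: Sequence[GeneModel],
    assembly_length: int,
) -> pd.DataFrame:
    """Per-type structural-variant summary.

    ``svs`` columns: ``svtype``, ``contig``, ``start``, ``end`` (1-based
    closed span on the reference; for insertions start == end) and ``length``.
    Records without a usable length are skipped and counted in the
    ``n_skipped`` column of the output.
    """
    rows = []
    for svtype, grp in svs.groupby("svtype", sort=True):
        lengths = pd.to_numeric(grp["length"], errors="coerce").abs()
        ok = lengths.notna() & (lengths > 0)
        sub = grp.loc[ok]
        ls = lengths[ok]
        hit_genes: set[str] = set()
        for rec in sub.itertuples(index=False):
            for g in genes:
                if g.contig == rec.contig and not (
                    g.end < rec.start or g.start > rec.end
                ):
                    hit_genes.add(g.gene_id)
        rows.append({
            "svtype": svtype,
            "count": int(len(sub)),
            "n_skipped": int((~ok).sum()),
            "median_size": float(ls.median()) if len(ls) else np.nan,
            "total_size": float(ls.sum()),
            "pct_assembly": float(ls.sum()) / assembly_length * 100.0,
            "genes_intersected": len(hit_genes),
            "q25_size": float(ls.quantile(0.25)) if len(ls) else np.nan,
            "q75_size": float(ls.quantile(0.75)) if len(ls) else np.nan,
            "mean_log10_size": float(np.log10(ls).mean()) if len(ls) else np.nan,
        })
    return pd.DataFrame(rows)


def filter_svs_in_repeats(
    svs: pd.DataFrame,
    index: FeatureIndex,
) -> pd.DataFrame:
    """Drop SV records whose span intersects intergenic repeat annotation."""
    keep = []
    for i, rec in enumerate(svs.itertuples(index=False)):
        arr = index.codes[rec.contig]
        s = max(0, int(rec.start) - 1)
        e = min(len(arr), int(rec.end))
        keep.append(not bool((arr[s:e] == _CODE[REPEAT]).any()))
    return svs.loc[keep].reset_index(drop=True)
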