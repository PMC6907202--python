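"""Gene models and GFF3 input/output.

A :class:`GeneModel` is the minimal transcript representation the rest of the
pipeline needs: genomic exon and CDS intervals (1-based, closed, ascending)
plus strand.  CDS intervals ordered 5'→3' on the coding strand are derived on
demand.  Real annotations with multiple transcripts per gene are represented
as one :class:`GeneModel` per transcript sharing a ``gene_id``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils

Interval = tuple[int, int]  # 1-based, closed


@dataclass
class GeneModel:
    gene_id: str
    transcript_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: list[Interval] = field(default_factory=list)  # genomic ascending
    cds: list[Interval] = field(default_factory=list)    # genomic ascending

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for name, ivs in (("exon", self.exons), ("CDS", self.cds)):
            for (s, e), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e:
                    raise ValueError(
                        f"{self.transcript_id}: overlapping {name} intervals "
                        f"({s},{e}) and ({s2},{e2})"
                    )

    # -- derived geometry ---------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_coding_order(self) -> list[Interval]:
        """CDS intervals ordered 5'→3' along the coding strand."""
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def introns(self) -> list[Interval]:
        """Intervals strictly between consecutive exons (1-based closed)."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 - e1 > 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def cds_offset(self, pos: int) -> int | None:
        """0-based coding-strand offset of a genomic position, or None if the
        position is not inside any CDS interval."""
        off = 0
        for s, e in self.cds_coding_order():
            if s <= pos <= e:
                return off + (pos - s if self.strand == "+" else e - pos)
            off += e - s + 1
        return None


def load_gene_models(gff3_path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from a GFF3 file (in-memory gffutils db).

    Transcripts lacking CDS records are kept (noncoding); transcripts whose
    exon set is absent fall back to their CDS intervals as exons.
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons:
            exons = list(cds)
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                contig=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene/mRNA/exon/CDS records, 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda g: (g.contig, g.start)):
            cols = [m.contig, "clonediv", "gene", str(m.start), str(m.end),
                    ".", m.strand, ".", f"ID={m.gene_id}"]
            fh.write("\t".join(cols) + "\n")
            cols[2] = "mRNA"
            cols[8] = f"ID={m.transcript_id};Parent={m.gene_id}"
            fh.write("\t".join(cols) + "\n")
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write("\t".join([
                    m.contig, "clonediv", "exon", str(s), str(e), ".",
                    m.strand, ".",
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}",
                ]) + "\n")
            # phase is derivable from cumulative CDS length on the coding strand
            phase = 0
            for s, e in m.cds_coding_order():
                fh.write("\t".join([
                    m.contig, "clonediv", "CDS", str(s), str(e), ".",
                    m.strand, str(phase),
                    f"ID={m.transcript_id}.cds;Parent={m.transcript_id}",
                ]) + "\n")
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3


def read_repeats_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Read repeat intervals from BED (0-based, half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_repeats_bed(repeats: Iterable[tuple[str, int, int]],
                      path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for contig, start, end in sorted(repeats):
            fh.write(f"{contig}\t{start}\t{end}\n")
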