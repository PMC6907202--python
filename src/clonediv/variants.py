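"""Multi-sample variant table: VCF I/O, hard filtering, and sanitation.

The filtering model mirrors GATK VariantFiltration: each rule names a site
metric and a "bad" direction; a record failing any enabled rule is annotated
with every failed rule name, never deleted.  Downstream stages consume PASS
records only by default.  Rules whose metric is absent on a record are not
evaluated for it (logged once per run), so a record with no metrics at all
passes vacuously.

Sanitation follows the two per-record predicates used for clone panels:
dropping records where the reference-derived sample carries a non-reference
allele (self-mapping artifacts), and restricting to sites genotyped in every
sample.  Both are order-independent.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

METRIC_FIELDS = ("DP", "QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

Genotype = tuple[int, int] | None  # None = missing ("./.")


@dataclass(frozen=True)
class VariantRecord:
    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    metrics: Mapping[str, float]
    genotypes: Mapping[str, Genotype]
    filters: tuple[str, ...] | None = None  # None = unfiltered, () = PASS
    variant_id: str = "."

    @property
    def is_pass(self) -> bool:
        return self.filters is not None and len(self.filters) == 0

    @property
    def is_symbolic(self) -> bool:
        return any(a.startswith("<") or "[" in a or "]" in a for a in self.alts)

    def key(self, alt_index: int = 1) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alts[alt_index - 1])


@dataclass
class VariantTable:
    samples: list[str]
    records: list[VariantRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def passing(self) -> "VariantTable":
        return VariantTable(self.samples, [r for r in self.records if r.is_pass])


class VCFParseError(ValueError):
    pass


def read_variant_table(path: str | os.PathLike) -> VariantTable:
    """Load a multi-sample VCF losslessly (records, samples, site metrics)."""
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for i, v in enumerate(vcf, 1):
        gts: dict[str, Genotype] = {}
        for s, g in zip(samples, v.genotypes):
            a, b = g[0], g[1]
            gts[s] = None if a < 0 or b < 0 else (a, b)
        if not gts and samples:
            raise VCFParseError(f"record {i}: no GT field")
        metrics = {}
        for m in METRIC_FIELDS:
            val = v.INFO.get(m)
            if val is not None:
                metrics[m] = float(val)
        filt: tuple[str, ...] | None
        raw = v.FILTER  # cyvcf2: None for PASS/'.', string otherwise
        filt = () if raw is None else tuple(raw.split(";"))
        records.append(VariantRecord(
            contig=v.CHROM, pos=v.POS, ref=v.REF,
            alts=tuple(v.ALT), qual=v.QUAL, metrics=metrics,
            genotypes=gts, filters=filt,
            variant_id=v.ID or ".",
        ))
    return VariantTable(samples=samples, records=records)


def write_variant_table(
    table: VariantTable,
    path: str | os.PathLike,
    contig_lengths: Mapping[str, int] | None = None,
    extra_filters: Sequence[str] = (),
) -> None:
    """Write VCF v4.2 deterministically (no timestamps)."""
    filter_ids = sorted(
        {f for r in table.records for f in (r.filters or ())} | set(extra_filters)
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clonediv\n")
        if contig_lengths:
            for c in sorted(contig_lengths):
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
        for m in METRIC_FIELDS:
            mtype = "Integer" if m == "DP" else "Float"
            fh.write(f'##INFO=<ID={m},Number=1,Type={mtype},Description="{m}">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        for fid in filter_ids:
            fh.write(f'##FILTER=<ID={fid},Description="{fid}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for r in table.records:
            info_parts = []
            for m in METRIC_FIELDS:
                if m in r.metrics:
                    val = r.metrics[m]
                    info_parts.append(
                        f"{m}={int(val)}" if m == "DP" else f"{m}={val:g}"
                    )
            for extra in ("SVTYPE", "SVLEN", "END"):
                if extra in r.metrics:
                    val = r.metrics[extra]
                    info_parts.append(
                        f"{extra}={val:g}" if isinstance(val, (int, float))
                        else f"{extra}={val}")
            info = ";".join(info_parts) if info_parts else "."
            if r.filters is None:
                filt = "."
            elif r.is_pass:
                filt = "PASS"
            else:
                filt = ";".join(r.filters)
            qual = "." if r.qual is None else f"{r.qual:g}"
            gt_strs = []
            for s in table.samples:
                g = r.genotypes.get(s)
                gt_strs.append("./." if g is None else f"{g[0]}/{g[1]}")
            fh.write("\t".join([
                r.contig, str(r.pos), r.variant_id, r.ref, ",".join(r.alts),
                qual, filt, info, "GT", *gt_strs,
            ]) + "\n")


# -- hard filtering ---------------------------------------------------------

@dataclass(frozen=True)
class FilterRule:
    name: str          # VCF-legal id
    metric: str        # metric name or "QUAL"
    op: str            # ">" or "<": direction in which the value FAILS
    threshold: float
    enabled: bool = True

    def fails(self, value: float) -> bool:
        return value > self.threshold if self.op == ">" else value < self.threshold

    def describe(self) -> str:
        return f"{self.metric} {self.op} {self.threshold:g}"


@dataclass
class FilterConfig:
    """Hard-filter thresholds, applied exactly as configured.

    The defaults are the standard GATK-style short-variant thresholds used
    for ~30x clone panels, including both depth flags as printed in that
    protocol (DP > 20 and DP < 5); each rule can be disabled independently.
    """

    rules: list[FilterRule] = field(default_factory=lambda: [
        FilterRule("DP_high", "DP", ">", 20.0),
        FilterRule("DP_low", "DP", "<", 5.0),
        FilterRule("LowQual", "QUAL", "<", 20.0),
        FilterRule("QD2", "QD", "<", 2.0),
        FilterRule("FS60", "FS", ">", 60.0),
        FilterRule("MQ40", "MQ", "<", 40.0),
        FilterRule("MQRankSum", "MQRankSum", "<", -12.5),
        FilterRule("ReadPosRankSum", "ReadPosRankSum", "<", -8.0),
    ])

    def __post_init__(self) -> None:
        for r in self.rules:
            if not np.isfinite(r.threshold):
                raise ValueError(f"non-finite threshold in rule {r.name}")

    def enabled_rules(self) -> list[FilterRule]:
        return [r for r in self.rules if r.enabled]

    def disable(self, *names: str) -> "FilterConfig":
        return FilterConfig(rules=[
            replace(r, enabled=False) if r.name in names else r
            for r in self.rules
        ])


def apply_hard_filters(table: VariantTable, cfg: FilterConfig) -> VariantTable:
    """Annotate every record PASS or with each failed rule name."""
    rules = cfg.enabled_rules()
    if not rules:
        raise ValueError("filtering requested with no enabled rules")
    skipped_metrics: set[str] = set()
    out: list[VariantRecord] = []
    for r in table.records:
        failed: list[str] = []
        for rule in rules:
            if rule.metric == "QUAL":
                value = r.qual
            else:
                value = r.metrics.get(rule.metric)
            if value is None:
                skipped_metrics.add(rule.metric)
                continue
            if rule.fails(value):
                failed.append(rule.name)
        out.append(replace(r, filters=tuple(failed)))
    if skipped_metrics:
        logger.warning(
            "metric(s) absent on some records, rule(s) not evaluated there: %s",
            ", ".join(sorted(skipped_metrics)),
        )
    return VariantTable(table.samples, out)


# -- sanitation -------------------------------------------------------------

def drop_reference_nonref(
    table: VariantTable, ref_sample: str
) -> tuple[VariantTable, float]:
    """Remove records where the reference sample carries a non-ref allele.

    Returns (filtered table, removed fraction).  Reads mapped back to the
    assembly they produced should genotype 0/0 everywhere; a non-reference
    call in that sample flags the site as a self-mapping artifact.
    """
    if ref_sample not in table.samples:
        raise KeyError(f"unknown reference sample {ref_sample!r}")
    kept = []
    removed = 0
    for r in table.records:
        g = r.genotypes.get(ref_sample)
        if g is not None and (g[0] > 0 or g[1] > 0):
            removed += 1
        else:
            kept.append(r)
    frac = removed / len(table.records) if table.records else 0.0
    logger.info("drop_reference_nonref: removed %d/%d records (%.1f%%)",
                removed, len(table.records), 100 * frac)
    return VariantTable(table.samples, kept), frac


def complete_call_sites(table: VariantTable) -> VariantTable:
    """Retain records genotyped (no missing call) in every sample."""
    kept = [
        r for r in table.records
        if all(r.genotypes.get(s) is not None for s in table.samples)
    ]
    return VariantTable(table.samples, kept)


def limit_alts(table: VariantTable, max_alts: int = 2) -> VariantTable:
    """Drop ALT alleles beyond the first ``max_alts`` (logged count).

    Genotypes referencing a dropped allele become missing.
    """
    dropped = 0
    out = []
    for r in table.records:
        if len(r.alts) <= max_alts:
            out.append(r)
            continue
        dropped += 1
        gts = {
            s: (g if g is not None and max(g) <= max_alts else None)
            for s, g in r.genotypes.items()
        }
        out.append(replace(r, alts=r.alts[:max_alts], genotypes=gts))
    if dropped:
        logger.info("limit_alts: truncated ALTs on %d records", dropped)
    return VariantTable(table.samples, out)


# -- classification ---------------------------------------------------------

def classify_variant_type(ref: str, alt: str) -> str:
    """SNV | INDEL | SV (symbolic or breakend alts pass through as SV)."""
    if alt.startswith("<") or "[" in alt or "]" in alt:
        return "SV"
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "INDEL"


def record_variant_types(record: VariantRecord) -> tuple[str, ...]:
    return tuple(classify_variant_type(record.ref, a) for a in record.alts)


# -- multi-caller concordance ----------------------------------------------

def call_set_concordance(
    call_sets: Mapping[str, Iterable],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Venn partition of variant-site sets keyed by (contig, pos, ref, alt).

    Returns (partition table, per-set table).  The partition table has one
    row per non-empty membership pattern; the per-set table reports the
    fraction of each set unique to it and unsupported by any other set
    (identical by definition for >= 2 sets, both reported for clarity).
    """
    names = list(call_sets)
    if not names:
        raise ValueError("no call sets supplied")
    sets = {n: set(call_sets[n]) for n in names}
    union = set().union(*sets.values())
    counts: dict[tuple[bool, ...], int] = {}
    for site in union:
        patt = tuple(site in sets[n] for n in names)
        counts[patt] = counts.get(patt, 0) + 1
    rows = []
    for patt in sorted(counts, reverse=True):
        rows.append({
            "pattern": "&".join(n for n, inc in zip(names, patt) if inc),
            **{n: inc for n, inc in zip(names, patt)},
            "count": counts[patt],
        })
    partition = pd.DataFrame(rows)
    per_set = []
    for n in names:
        only = tuple(m == n for m in names)
        unique = counts.get(only, 0)
        size = len(sets[n])
        per_set.append({
            "set": n,
            "size": size,
            "unique_count": unique,
            "unique_fraction": unique / size if size else np.nan,
            "unsupported_fraction": unique / size if size else np.nan,
        })
    return partition, pd.DataFrame(per_set)


def read_sv_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read VCF-like structural-variant records into a flat table.

    Columns: sv_id, contig, start (1-based), end, svtype, length, carriers
    (comma-joined sample labels with a non-reference genotype).
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows = []
    for v in vcf:
        svtype = v.INFO.get("SVTYPE")
        if svtype is None and v.ALT and v.ALT[0].startswith("<"):
            svtype = v.ALT[0].strip("<>")
        length = v.INFO.get("SVLEN")
        end = v.INFO.get("END", v.POS)
        carriers = [
            s for s, g in zip(samples, v.genotypes)
            if g[0] > 0 or g[1] > 0
        ]
        rows.append({
            "sv_id": v.ID or ".", "contig": v.CHROM, "start": v.POS,
            "end": int(end), "svtype": svtype,
            "length": abs(int(length)) if length is not None else None,
            "carriers": ",".join(carriers),
        })
    return pd.DataFrame(rows)


def brute_force_concordance(call_sets: Mapping[str, Iterable]) -> dict[str, int]:
    """Independent enumeration oracle: pattern-name -> count."""
    names = list(call_sets)
    sets = {n: set(call_sets[n]) for n in names}
    out = {}
    for flags in product([True, False], repeat=len(names)):
        if not any(flags):
            continue
        inside = [sets[n] for n, f in zip(names, flags) if f]
        outside = [sets[n] for n, f in zip(names, flags) if not f]
        members = set.intersection(*inside)
        for o in outside:
            members -= o
        out["&".join(n for n, f in zip(names, flags) if f)] = len(members)
    return out
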