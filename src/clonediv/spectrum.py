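"""The clone-sharing spectrum: variants "shared by only N clones".

For a panel of clones descending from one mother, heterozygous variant
sites split into inherited ancestral heterozygosity (carried by the whole
panel, N = panel size) and somatic mutations acquired during propagation
(N = 1 for private events, intermediate N for subclades).  The spectrum is
the histogram of N, per variant type and per feature class.

Carrier definition: a clone carries a site iff it is heterozygous for the
considered ALT allele; homozygous-reference and (by default) homozygous-alt
genotypes are non-carriers — clone panels are expected to be heterozygous
for true somatic events, and hom-alt calls are treated as technical
artifacts.  At multi-allelic sites a clone heterozygous for a different ALT
is a non-carrier for this one.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureIndex, FEATURE_CLASSES, affected_position
from .variants import VariantRecord, VariantTable, classify_variant_type

logger = logging.getLogger(__name__)


class MissingGenotypeError(ValueError):
    """Sharing level requested on a record with missing genotypes."""


def sharing_level(
    record: VariantRecord,
    clone_samples: Sequence[str],
    alt_index: int = 1,
) -> int:
    """Number of clones heterozygous for the given ALT (1-based index)."""
    n = 0
    for s in clone_samples:
        g = record.genotypes.get(s)
        if g is None:
            raise MissingGenotypeError(
                f"missing genotype for {s} at {record.contig}:{record.pos}; "
                "apply complete_call_sites first"
            )
        if alt_index in g and g[0] != g[1]:
            n += 1
    return n


def _is_uniform_het(record: VariantRecord, clone_samples: Sequence[str],
                    alt_index: int) -> bool:
    gts = {record.genotypes[s] for s in clone_samples}
    return len(gts) == 1 and all(
        alt_index in g and g[0] != g[1] for g in gts)


def build_spectrum(
    table: VariantTable,
    clone_samples: Sequence[str],
    index: FeatureIndex | None = None,
    te_table: pd.DataFrame | None = None,
    sv_table: pd.DataFrame | None = None,
    *,
    exclude_uniform_het: bool = False,
) -> pd.DataFrame:
    """Sharing spectrum per variant type, overall and per feature class.

    ``table`` should already be sanitized (PASS hard filters, reference
    sample dropped, complete calls).  SNVs/INDELs are stratified by the
    feature class of the leftmost affected base ("all" rows aggregate);
    TE insertions use presence/absence carrier sets; SVs use genotype
    presence from their own table.  Sites with N = 0 are excluded.

    Returns rows (vartype, feature, N, count, proportion); proportions are
    within (vartype, feature) strata.
    """
    n_clones = len(clone_samples)
    rows: list[dict] = []
    for rec in table.records:
        for ai in range(1, len(rec.alts) + 1):
            alt = rec.alts[ai - 1]
            vtype = classify_variant_type(rec.ref, alt)
            if vtype == "SV":
                continue  # symbolic records live in the SV table
            n = sharing_level(rec, clone_samples, ai)
            if n == 0:
                continue
            if (exclude_uniform_het and n == n_clones
                    and _is_uniform_het(rec, clone_samples, ai)):
                continue
            feature = "all"
            if index is not None:
                feature = index.class_of(
                    rec.contig, affected_position(rec.pos, rec.ref, alt))
            rows.append({"vartype": vtype, "feature": feature, "N": n})
    df = pd.DataFrame(rows, columns=["vartype", "feature", "N"])

    spectra = []
    if len(df):
        for vtype, grp in df.groupby("vartype"):
            spectra.append(_histogram(grp, vtype, "all", n_clones))
            if index is not None:
                for feat in FEATURE_CLASSES:
                    sub = grp[grp["feature"] == feat]
                    spectra.append(_histogram(sub, vtype, feat, n_clones))
    if te_table is not None and len(te_table):
        te_n = te_table["carriers"].str.split(",").map(len)
        spectra.append(_histogram(
            pd.DataFrame({"N": te_n}), "TEI", "all", n_clones))
    if sv_table is not None and len(sv_table):
        sv_n = sv_table["carriers"].str.split(",").map(
            lambda c: len([x for x in c if x]))
        sv_n = sv_n[sv_n > 0]
        spectra.append(_histogram(
            pd.DataFrame({"N": sv_n}), "SV", "all", n_clones))
    if not spectra:
        logger.warning("build_spectrum: empty input")
        return pd.DataFrame(
            columns=["vartype", "feature", "N", "count", "proportion"])
    return pd.concat(spectra, ignore_index=True)


def _histogram(df: pd.DataFrame, vtype: str, feature: str,
               n_clones: int) -> pd.DataFrame:
    counts = (df.groupby("N").size()
              .reindex(range(1, n_clones + 1), fill_value=0))
    total = counts.sum()
    out = counts.rename("count").reset_index()
    out.insert(0, "vartype", vtype)
    out.insert(1, "feature", feature)
    out["proportion"] = out["count"] / total if total else np.nan
    return out


def headline_fractions(spectrum: pd.DataFrame, n_clones: int) -> pd.DataFrame:
    """Share of each variant type at N = n_clones and at N <= 2."""
    rows = []
    for vtype, grp in spectrum[spectrum["feature"] == "all"].groupby("vartype"):
        total = grp["count"].sum()
        shared_all = grp.loc[grp["N"] == n_clones, "count"].sum()
        rare = grp.loc[grp["N"] <= 2, "count"].sum()
        rows.append({
            "vartype": vtype,
            "total": int(total),
            "fraction_shared_by_all": shared_all / total if total else np.nan,
            "fraction_in_le2_clones": rare / total if total else np.nan,
        })
    return pd.DataFrame(rows)


def merge_svs(sv_table: pd.DataFrame, reciprocal_overlap: float = 0.8,
              position_window: int = 10) -> pd.DataFrame:
    """Unify "the same" SV seen in different samples.

    Records of the same type on the same contig merge when their spans have
    reciprocal overlap >= the threshold (insertions: positions within the
    window and length ratio >= threshold); carrier sets union.  Single-table
    simulated input is already unified, so this is usually an identity.
    """
    merged_rows: list[dict] = []
    for (contig, svtype), grp in sv_table.groupby(["contig", "svtype"]):
        grp = grp.sort_values("start").reset_index(drop=True)
        used = np.zeros(len(grp), dtype=bool)
        for i in range(len(grp)):
            if used[i]:
                continue
            base = grp.loc[i].to_dict()
            carriers = set(str(base["carriers"]).split(","))
            for j in range(i + 1, len(grp)):
                if used[j]:
                    continue
                other = grp.loc[j]
                if _same_sv(base, other, reciprocal_overlap, position_window):
                    carriers |= set(str(other["carriers"]).split(","))
                    used[j] = True
            base["carriers"] = ",".join(sorted(c for c in carriers if c))
            merged_rows.append(base)
            used[i] = True
    return pd.DataFrame(merged_rows, columns=sv_table.columns)


def _same_sv(a, b, threshold: float, window: int) -> bool:
    if a["svtype"] == "insertion":
        la, lb = a["length"], b["length"]
        ratio = min(la, lb) / max(la, lb) if max(la, lb) else 0.0
        return abs(a["start"] - b["start"]) <= window and ratio >= threshold
    lo = max(a["start"], b["start"])
    hi = min(a["end"], b["end"])
    ov = max(0, hi - lo + 1)
    la = a["end"] - a["start"] + 1
    lb = b["end"] - b["start"] + 1
    return ov / la >= threshold and ov / lb >= threshold
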