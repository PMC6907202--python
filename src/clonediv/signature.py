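"""Transition/transversion accounting and cytosine-context signatures.

Plant DNA methylation occurs at cytosines in CpG, CHG and CHH contexts
(H = A, C or T); methylated cytosines deaminate to thymine, so an excess of
C→T transitions at these contexts — concentrated in repeat-rich, heavily
methylated intergenic space — is the expected fingerprint of
methylation-driven somatic mutation.  This module extracts contexts from the
reference (both strands: a genomic G is a minus-strand C), tallies Ti/Tv per
feature class, and computes the percentage of context cytosine sites per
feature class that carry a clone-unique heterozygous transition.

A "site" is strand-specific: a CpG dinucleotide contributes two cytosine
sites, one per strand, and the denominators count sites, not dinucleotides.
Only C→T on the site's strand (G→A in genome coordinates for minus-strand
sites) counts as that site experiencing a transition; the deamination
mechanism is directional.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .features import FeatureIndex, FEATURE_CLASSES

BASES = ("A", "C", "G", "T")
CONTEXTS = ("CpG", "CHG", "CHH")
_PURINES = {"A", "G"}


def is_transition(ref_base: str, alt_base: str) -> bool:
    """True iff {ref, alt} is {A,G} or {C,T}."""
    a, b = ref_base.upper(), alt_base.upper()
    if a not in BASES or b not in BASES:
        raise ValueError(f"ambiguity codes not supported: {ref_base}>{alt_base}")
    if a == b:
        raise ValueError(f"not a substitution: {ref_base}>{alt_base}")
    return (a in _PURINES) == (b in _PURINES)


def _fetch(reference, contig: str, start0: int, end0: int) -> str:
    """Sequence slice from a dict-of-strings or a pyfaidx.Fasta."""
    seq = reference[contig][max(start0, 0):end0]
    return str(seq).upper()


def cytosine_context(reference, contig: str, position: int) -> str:
    """Methylation context of a reference C or G at a 1-based position.

    For a plus-strand C at i: CpG if i+1 is G, else CHG if i+2 is G, else
    CHH.  A genomic G is evaluated as the minus-strand C symmetrically
    (upstream bases, complemented).  Non-C/G bases and positions lacking the
    needed flanking bases return "none".
    """
    i = position - 1
    base = _fetch(reference, contig, i, i + 1)
    if base == "C":
        flank = _fetch(reference, contig, i + 1, i + 3)
        if len(flank) >= 1 and flank[0] == "G":
            return "CpG"
        if len(flank) < 2 or any(b not in BASES for b in flank[:2]):
            return "none"
        if flank[1] == "G":
            return "CHG"
        return "CHH"
    if base == "G":
        flank = _fetch(reference, contig, i - 2, i)  # genomic i-2, i-1
        if len(flank) >= 1 and flank[-1] == "C":
            return "CpG"
        if len(flank) < 2 or any(b not in BASES for b in flank):
            return "none"
        if flank[0] == "C":
            return "CHG"
        return "CHH"
    return "none"


def context_site_table(reference, index: FeatureIndex) -> pd.DataFrame:
    """All strand-specific cytosine context sites in the genome.

    Columns: contig, position (1-based), strand ('+' for genomic C, '-' for
    genomic G), context, feature.  Vectorized scan; near-end positions with
    insufficient context are excluded (context "none").
    """
    frames = []
    for contig in sorted(index.codes):
        seq = np.frombuffer(_fetch(reference, contig, 0, len(index.codes[contig]))
                            .encode(), dtype="S1")
        n = len(seq)
        codes = index.codes[contig]
        for strand, cbase, gnext in (("+", b"C", b"G"), ("-", b"G", b"C")):
            pos0 = np.flatnonzero(seq == cbase)
            if strand == "+":
                n1 = np.where(pos0 + 1 < n, pos0 + 1, pos0)  # clamp, mask later
                n2 = np.where(pos0 + 2 < n, pos0 + 2, pos0)
                has1 = pos0 + 1 < n
                has2 = pos0 + 2 < n
            else:
                n1 = np.where(pos0 - 1 >= 0, pos0 - 1, pos0)
                n2 = np.where(pos0 - 2 >= 0, pos0 - 2, pos0)
                has1 = pos0 - 1 >= 0
                has2 = pos0 - 2 >= 0
            b1 = seq[n1]
            b2 = seq[n2]
            acgt = np.frombuffer(b"ACGT", dtype="S1")
            b1_ok = np.isin(b1, acgt)
            b2_ok = np.isin(b2, acgt)
            cpg = has1 & (b1 == gnext)
            chg = has2 & ~cpg & b1_ok & (b1 != gnext) & (b2 == gnext)
            chh = has2 & ~cpg & b1_ok & b2_ok & (b1 != gnext) & (b2 != gnext)
            ctx = np.full(len(pos0), "none", dtype=object)
            ctx[cpg] = "CpG"
            ctx[chg] = "CHG"
            ctx[chh] = "CHH"
            keep = ctx != "none"
            frames.append(pd.DataFrame({
                "contig": contig,
                "position": pos0[keep] + 1,
                "strand": strand,
                "context": ctx[keep],
                "feature": [FEATURE_CLASSES[codes[p]] for p in pos0[keep]],
            }))
    if not frames:
        return pd.DataFrame(
            columns=["contig", "position", "strand", "context", "feature"])
    return pd.concat(frames, ignore_index=True)


def context_census(reference, index: FeatureIndex) -> pd.DataFrame:
    """Count of cytosine context sites per (feature class, context)."""
    sites = context_site_table(reference, index)
    census = (
        sites.groupby(["feature", "context"]).size().rename("n_sites")
        .reindex(pd.MultiIndex.from_product(
            [FEATURE_CLASSES, CONTEXTS], names=["feature", "context"]),
            fill_value=0)
        .reset_index()
    )
    return census


def titv_ratio(
    snvs: pd.DataFrame,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Transition/transversion ratio per group.

    ``snvs`` needs ``ref`` and ``alt`` single-base columns (an
    ``is_transition`` column is used directly if present).  Groups with zero
    transversions report a NaN ratio (undefined), never infinity.
    """
    df = snvs.copy()
    if "is_transition" not in df.columns:
        df["is_transition"] = [
            is_transition(r, a) for r, a in zip(df["ref"], df["alt"])
        ]
    by = by or []
    if by:
        grouped = df.groupby(by)["is_transition"].agg(["sum", "count"])
    else:
        grouped = pd.DataFrame(
            {"sum": [df["is_transition"].sum()], "count": [len(df)]})
    out = grouped.reset_index()
    out = out.rename(columns={"sum": "transitions"})
    out["transitions"] = out["transitions"].astype(int)
    out["transversions"] = (out["count"] - out["transitions"]).astype(int)
    out["titv"] = np.where(
        out["transversions"] > 0,
        out["transitions"] / out["transversions"].replace(0, np.nan),
        np.nan,
    )
    return out.drop(columns=["count"])


def context_transition_percentages(
    unique_snvs: pd.DataFrame,
    reference,
    index: FeatureIndex,
    clones: list[str],
    *,
    pooled: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentage of context cytosine sites carrying a clone-unique C→T.

    ``unique_snvs``: columns clone, contig, position, ref, alt — the
    heterozygous SNVs private to single clones (sharing level N = 1).
    Numerators count sites whose strand-oriented change is C→T (genomic C→T
    on '+' sites, G→A on '-' sites).  Returns (per-clone table, summary with
    mean and standard error across clones).  With ``pooled=True`` the summary
    instead divides pooled counts by (sites x clones).
    """
    census = context_census(reference, index)
    df = unique_snvs.copy()
    contexts = []
    features = []
    oriented_ct = []
    for rec in df.itertuples(index=False):
        ctx = cytosine_context(reference, rec.contig, int(rec.position))
        contexts.append(ctx)
        features.append(index.class_of(rec.contig, int(rec.position)))
        if rec.ref == "C":
            oriented_ct.append(rec.alt == "T")
        elif rec.ref == "G":
            oriented_ct.append(rec.alt == "A")
        else:
            oriented_ct.append(False)
    df["context"] = contexts
    df["feature"] = features
    df["oriented_ct"] = oriented_ct
    hits = df[(df["context"] != "none") & df["oriented_ct"]]
    full_index = pd.MultiIndex.from_product(
        [clones, FEATURE_CLASSES, CONTEXTS],
        names=["clone", "feature", "context"])
    counts = (
        hits.groupby(["clone", "feature", "context"]).size()
        .reindex(full_index, fill_value=0).rename("n_mutated").reset_index()
    )
    per_clone = counts.merge(census, on=["feature", "context"], how="left")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_clone["percent"] = np.where(
            per_clone["n_sites"] > 0,
            100.0 * per_clone["n_mutated"] / per_clone["n_sites"],
            np.nan,
        )
    if pooled:
        pooled_df = (
            per_clone.groupby(["feature", "context"])
            .agg(n_mutated=("n_mutated", "sum"), n_sites=("n_sites", "first"))
            .reset_index()
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled_df["mean_percent"] = np.where(
                pooled_df["n_sites"] > 0,
                100.0 * pooled_df["n_mutated"]
                / (pooled_df["n_sites"] * len(clones)),
                np.nan,
            )
        pooled_df["se_percent"] = np.nan
        return per_clone, pooled_df
    summary = (
        per_clone.groupby(["feature", "context"])["percent"]
        .agg(mean_percent="mean",
             se_percent=lambda x: x.std(ddof=1) / np.sqrt(x.notna().sum())
             if x.notna().sum() > 1 else 0.0)
        .reset_index()
    )
    return per_clone, summary
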