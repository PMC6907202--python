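"""Independent brute-force oracles used by the tests.

Each function here recomputes a quantity by the most direct route available
(full-sequence reconstruction, naive scans, explicit agglomeration) and is
deliberately kept separate from the library implementations it checks.
"""

from __future__ import annotations

import numpy as np

GENETIC_CODE = {}
_bases = "TCAG"
_aas = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
for _i, _a in enumerate(_aas):
    GENETIC_CODE[_bases[_i // 16] + _bases[(_i // 4) % 4] + _bases[_i % 4]] = _a


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def translate(seq: str) -> str:
    n = len(seq) - len(seq) % 3
    return "".join(GENETIC_CODE[seq[i:i + 3]] for i in range(0, n, 3))


def translate_and_diff(model, genome, pos, ref, alt) -> str:
    """Effect category by rebuilding and translating the mutated CDS.

    Assumes the variant's edited bases lie inside one CDS interval of the
    transcript.  Categories: start_lost, frameshift, synonymous, missense,
    stop_gained, stop_lost, inframe_indel.
    """
    contig_seq = str(genome[model.contig])
    mutated_contig = (contig_seq[:pos - 1] + alt
                      + contig_seq[pos - 1 + len(ref):])
    shift = len(alt) - len(ref)
    new_cds = []
    for s, e in model.cds:
        if e < pos:
            new_cds.append((s, e))
        elif s <= pos <= e:
            new_cds.append((s, e + shift))
        else:
            new_cds.append((s + shift, e + shift))
    ref_seq = "".join(contig_seq[s - 1:e] for s, e in model.cds)
    alt_seq = "".join(mutated_contig[s - 1:e] for s, e in new_cds)
    if model.strand == "-":
        ref_seq = revcomp(ref_seq)
        alt_seq = revcomp(alt_seq)
    if alt_seq[:3] != "ATG":
        return "start_lost"
    if shift % 3 != 0:
        return "frameshift"
    ref_prot = translate(ref_seq)
    alt_prot = translate(alt_seq)
    if shift == 0:
        if ref_prot == alt_prot:
            return "synonymous"
        diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot))
                 if a != b]
        i = diffs[0]
        if ref_prot[i] == "*" and alt_prot[i] != "*":
            return "stop_lost"
        if alt_prot[i] == "*" and ref_prot[i] != "*":
            return "stop_gained"
        return "missense"
    ref_premature = "*" in ref_prot[:-1]
    alt_premature = "*" in alt_prot[:-1]
    if alt_premature and not ref_premature:
        return "stop_gained"
    return "inframe_indel"


def naive_cytosine_context(seq: str, position: int) -> str:
    """Context via explicit reverse-complement remapping (plus-rule only)."""
    i = position - 1
    if seq[i] == "C":
        s, j = seq, i
    elif seq[i] == "G":
        s, j = revcomp(seq), len(seq) - 1 - i
    else:
        return "none"
    if j + 1 < len(s) and s[j + 1] == "G":
        return "CpG"
    if j + 2 >= len(s):
        return "none"
    if any(b not in "ACGT" for b in s[j + 1:j + 3]):
        return "none"
    if s[j + 2] == "G":
        return "CHG"
    return "CHH"


def naive_average_linkage(dist: np.ndarray):
    """Explicit agglomeration: returns the merge sequence as
    (frozenset_a, frozenset_b, height) triples."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                members_a = clusters[a]
                members_b = clusters[b]
                d = np.mean([dist[i, j] for i in members_a for j in members_b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        clusters[min(a, b)] = clusters[a] | clusters[b]
        del clusters[max(a, b)]
    return merges


def naive_nearest_gene(pos: int, gene_spans: list[tuple[int, int]]):
    """(genic, upstream, downstream) by scanning every gene boundary."""
    if any(s <= pos <= e for s, e in gene_spans):
        return True, 0.0, 0.0
    ups = [pos - e for s, e in gene_spans if e < pos]
    downs = [s - pos for s, e in gene_spans if s > pos]
    return (False,
            float(min(ups)) if ups else None,
            float(min(downs)) if downs else None)
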