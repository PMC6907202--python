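"""Length-normalized somatic mutation rates by genome feature.

Counts each clone's heterozygous somatic variants (sharing level N < 15)
per feature class, normalizes by feature length (per kb), and compares the
classes with Tukey HSD — the repeat-rich intergenic space should lead,
exons trail.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from _common import CLONES, TABLES, ensure_fixture, load_index_and_genes, \
    load_sanitized

from clonediv.features import FEATURE_CLASSES, normalized_rates
from clonediv.pipeline import _per_variant_frame
from clonediv.stats import tukey_hsd


def main() -> None:
    ensure_fixture()
    table = load_sanitized()
    _, _, index = load_index_and_genes()
    pv = _per_variant_frame(table, CLONES, index)
    somatic = pv[pv["N"] < len(CLONES)]
    rows = []
    for clone in CLONES:
        counts = (somatic[somatic[f"het_{clone}"]]
                  .groupby("feature").size()
                  .reindex(FEATURE_CLASSES, fill_value=0)
                  .rename("count").reset_index())
        counts["clone"] = clone
        rows.append(counts)
    per_clone = normalized_rates(pd.concat(rows, ignore_index=True), index)
    per_clone.to_csv(TABLES / "feature_rates_per_clone.tsv", sep="\t",
                     index=False)
    mean_rates = per_clone.groupby("feature")["rate_per_kb"].mean()
    print("mean per-clone somatic rate (per kb):")
    print(mean_rates.round(3).to_string())
    groups = {f: per_clone.loc[per_clone["feature"] == f, "rate_per_kb"]
              .to_numpy() for f in FEATURE_CLASSES}
    tukey, letters = tukey_hsd(groups)
    tukey.to_csv(TABLES / "feature_rates_tukey.tsv", sep="\t", index=False)
    print("\nTukey HSD letters (shared letter = not distinguishable):")
    for f in FEATURE_CLASSES:
        print(f"  {f:26s} {letters[f]}")


if __name__ == "__main__":
    main()
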