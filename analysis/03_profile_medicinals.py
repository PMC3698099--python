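#!/usr/bin/env python
"""Potency profiles, chromatin calls and score-potency correlations.

Maps each medicinal's chemicals through the interaction table onto the 18
modification attributes (unspecified interactions counted as inhibiting),
classifies each medicinal as condensing / unpacking / poising from the
net of heterochromatic vs euchromatic marks touched, and screens all 18
attributes for Pearson correlation with each score mode at alpha = 0.05
(no multiple-testing correction -- a per-attribute screen).  Finding at
the default conditions: roughly a third of medicinals are
histone-modifying, and the planted cold-H3K9 association surfaces as a
significant negative correlation.
"""

from pathlib import Path

import pandas as pd

from tcmchromatin.catalog import (
    read_interaction_table,
    read_medicinal_catalog,
    read_modification_catalog,
)
from tcmchromatin.profiling import (
    build_potency_profiles,
    chromatin_call,
    correlation_screen,
    materia_medica_summary,
    profiles_to_tsv,
)
from tcmchromatin.scoring import score_catalog

BUNDLE = Path("results/bundle")
OUT = Path("results")


def main() -> None:
    catalog = read_medicinal_catalog(BUNDLE / "medicinals.tsv")
    interactions = read_interaction_table(BUNDLE / "interactions.tsv")
    modcat = read_modification_catalog(BUNDLE / "modification_catalog.tsv")
    profiles = build_potency_profiles(catalog, interactions, modcat)
    calls = [chromatin_call(p, modcat) for p in profiles]
    profiles_to_tsv(profiles, OUT / "profiles.tsv", calls)
    summary = materia_medica_summary(calls)
    print(f"histone-modifying: {summary['n_modifying']}/{summary['n_total']} "
          f"({100 * summary['frac_modifying']:.0f}%)")
    print(f"  condensing {100 * summary['frac_condensing']:.0f}%  "
          f"unpacking {100 * summary['frac_unpacking']:.0f}%  "
          f"poising {100 * summary['frac_poising']:.0f}%")
    scores = score_catalog(catalog)
    frames = [correlation_screen(scores, profiles, mode)
              for mode in ("nature_only", "full", "flavor_only")]
    corr = pd.concat(frames, ignore_index=True)
    corr.to_csv(OUT / "correlations.tsv", sep="\t", index=False)
    sig = corr[corr["significant"]]
    print("significant score-potency correlations (alpha = 0.05):")
    for row in sig.itertuples(index=False):
        print(f"  {row.attribute_code:7s} {row.score_mode:12s} "
              f"r={row.r:+.3f} p={row.p:.3g} n={row.n}")
    print(f"wrote {OUT}/profiles.tsv and {OUT}/correlations.tsv")


if __name__ == "__main__":
    main()
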