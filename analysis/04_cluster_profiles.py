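#!/usr/bin/env python
"""Hierarchically cluster the histone-modifying medicinals.

Rows (medicinals) and columns (the 18 modification attributes) are
clustered by complete-linkage agglomeration under Euclidean distance on
the potency matrix, and the reordered matrix plus both dendrograms are
exported.  The column dendrogram groups attributes by how similarly the
medicinals use them -- at the default conditions the chemistry families
(acetylation, phosphorylation, methylation) tend to separate.
"""

from pathlib import Path

import pandas as pd

from tcmchromatin.cluster import export_clustered_matrix, hierarchical_cluster
from tcmchromatin.constants import ATTRIBUTE_ORDER

OUT = Path("results")


def main() -> None:
    df = pd.read_csv(OUT / "profiles.tsv", sep="\t", index_col="entity_id")
    mat = df[list(ATTRIBUTE_ORDER)]
    mat = mat[mat.sum(axis=1) > 0]
    rows = hierarchical_cluster(mat, axis="rows", linkage="complete")
    cols = hierarchical_cluster(mat, axis="columns", linkage="complete")
    files = export_clustered_matrix(mat, rows, cols,
                                    str(OUT / "medicinal_cluster"))
    print(f"clustered {len(mat)} histone-modifying medicinals x 18 attributes")
    order = [cols.labels[i] for i in cols.leaf_order()]
    print("attribute leaf order:", " ".join(order))
    print("wrote " + ", ".join(files.values()))


if __name__ == "__main__":
    main()
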