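"""Order multicolour-FISH patterns into an evolutionary diagram.

Emulates a typical scoring table: normal cells (two co-localised
red-green pairs, two copies of each locus), a major clone with the
fusion plus bi-allelic 9p21.3/CDKN2A loss, and a derived clone that has
additionally lost one PTEN copy.  Containment ordering recovers the
chain normal -> fusion+CDKN2A-/- -> +PTEN loss.
"""

import pandas as pd

from talclone.fishpatterns import (
    FishCellTable,
    FishProbe,
    build_containment_tree,
    tabulate_fish_patterns,
)
from talclone.io import tree_to_newick

probes = [
    FishProbe("STIL_TAL1", "fusion_indicator"),
    FishProbe("CDKN2A", "locus_cn"),
    FishProbe("PTEN", "locus_cn"),
]
rows = [(2, 2, 2)] * 8 + [(1, 0, 2)] * 55 + [(1, 0, 1)] * 37
tbl = FishCellTable(
    counts=pd.DataFrame(rows, columns=[p.id for p in probes],
                        index=[f"cell{i}" for i in range(len(rows))]),
    probes=probes,
)

patterns, below = tabulate_fish_patterns(tbl, min_cells=2)
for p in patterns:
    print(f"pattern {p.states}: {p.n_cells} cells ({p.frequency_pct:.0f}%)")

tree = build_containment_tree(patterns, probes)
print("containment diagram:", tree_to_newick(tree))
print()
print("Signal tuples are (intact fusion pairs, CDKN2A copies, PTEN copies);")
print("percentages are subclone frequencies among scored nuclei, and the")
print("diagram orders patterns by which lesions contain which.")
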