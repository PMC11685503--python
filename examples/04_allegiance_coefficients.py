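"""Module allegiance, recruitment and integration on a toy cohort.

Nine regions in three predefined networks, three participants (layers); one
region defects from its community in one layer.  Allegiance P_ij is the
fraction of layers in which two regions share a community; recruitment and
integration summarize P against the predefined networks.
"""

import numpy as np

from netlayers import ParcelAtlas, allegiance_matrix, coefficient_table

atlas = ParcelAtlas(
    parcel_ids=tuple(range(1, 10)),
    names=tuple(f"region_{i}" for i in range(1, 10)),
    hemispheres=("L",) * 4 + ("R",) * 5,
    networks=("S1",) * 3 + ("S2",) * 3 + ("S3",) * 3,
)

labels = np.tile(np.repeat([0, 1, 2], 3)[:, None], (1, 3))
labels[0, 2] = 1  # region 1 joins community 2 in participant 3

P = allegiance_matrix(labels)
print(f"allegiance of region 1 with its own network : {P.values[0, 1]:.3f}")
print(f"allegiance of region 1 with network S2      : {P.values[0, 3]:.3f}")

table = coefficient_table(P, atlas)
print(table.round(3).to_string(index=False))
# Region 1's recruitment drops below 1 (it left its network once in three
# layers) and its integration rises above 0 (it joined another network once);
# all other regions are perfectly recruited and never integrated.
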