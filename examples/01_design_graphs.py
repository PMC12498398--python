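"""Build the two factory mixture designs and inspect their bonding graphs.

The N2c8 design is bond-exclusive (every patch has exactly one partner),
which pins an azeotrope at equimolar composition when all bond energies
are equal.  The "ideal azeotropic" design gives every patch one partner on
each species, which makes the mixture azeotropic at every composition.
"""

from azeopatch import (
    build_ideal_azeotrope_binary,
    build_n2c8,
    is_bond_exclusive,
    is_ideal_azeotropic,
)

for name, design in [
    ("N2c8 (uniform)", build_n2c8(1.0, 1.0)),
    ("N2c8 (eps' = 1.35)", build_n2c8(1.35, 1.0)),
    ("ideal azeotropic", build_ideal_azeotrope_binary()),
]:
    adj = design.bonding_adjacency()
    print(f"{name}:")
    print(f"  species: {design.n_species}, patch types: {design.n_patch_types}")
    print(f"  bond-exclusive:   {is_bond_exclusive(design)}")
    print(f"  ideal-azeotropic: {is_ideal_azeotropic(design)}")
    pairs = [
        (design.patch_type_order[i], design.patch_type_order[j])
        for i in range(design.n_patch_types)
        for j in range(i, design.n_patch_types)
        if adj[i, j]
    ]
    print(f"  bonding edges: {pairs}")
# The edge list is the design's single source of truth: the Wertheim module
# and the Monte Carlo engine both read bonding exclusively from it.
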