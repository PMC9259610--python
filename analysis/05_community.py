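"""Denitrifier community structure: diversity, niche, ordination, networks.

Computes alpha-diversity per sample, habitat-level Levins niche breadth,
Bray-Curtis distances with PCoA and ANOSIM, and per-habitat co-occurrence
networks (r^2 > 0.90, p < 0.05) with degree-ranked keystone taxa.
"""

import warnings

import pandas as pd
from _common import parse_args, seeds_for

from plastisphere_n2o import ecology as eco
from plastisphere_n2o import tables


def main() -> None:
    args = parse_args(__doc__)
    seeds = seeds_for(args.seed)
    otu = tables.read_table(args.out / "data" / "otu.csv").set_index("sample_id")
    markers = tables.read_table(args.out / "data" / "otu_markers.csv").set_index("taxon")["marker"]
    habitat = otu.index.to_series().map(
        lambda s: "bulk" if s.startswith("BW") else "plastisphere"
    )

    diversity = pd.DataFrame({s: eco.diversity_indices(otu, s) for s in otu.index}).T
    diversity["habitat"] = habitat
    tables.write_table(diversity.reset_index(names="sample_id"), args.out / "diversity.csv")
    print("alpha diversity by habitat:")
    print(diversity.groupby("habitat")[["shannon", "simpson", "chao1", "ace"]].mean().round(2))

    dist = eco.bray_curtis(otu)
    ordination = eco.pcoa(dist, k=2)
    ordination["coordinates"].to_csv(args.out / "pcoa_coordinates.csv")
    ano = eco.anosim(dist, habitat.to_numpy(), n_perm=999, seed=seeds["anosim"])
    print(f"ANOSIM: R = {ano['R']:.3f}, p = {ano['p']:.3f} (999 permutations)")

    for h in ("plastisphere", "bulk"):
        sub = otu.loc[habitat == h]
        niche = eco.niche_metrics(sub)
        tables.write_table(niche.reset_index(names="taxon"), args.out / f"niche_{h}.csv")
        community_breadth = (niche["breadth"] * niche["weight"]).sum()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = eco.build_network(sub, markers=markers, seed=seeds["network"])
        ks = eco.keystone_taxa(net, top_k=5)
        tables.write_table(ks, args.out / f"keystones_{h}.csv")
        print(
            f"{h}: community niche breadth {community_breadth:.2f}; "
            f"network {net.summary['n_nodes']} nodes / {net.summary['n_edges']} edges; "
            f"keystone markers {ks['marker'].tolist()}"
        )


if __name__ == "__main__":
    main()
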