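"""Chip qPCR Ct records -> 16S-normalised gene abundances and nir/nos ratios.

The (nirS+nirK)/nosZ ratio summarises the genetic potential for net N2O
release: nitrite reductases make N2O, N2O reductase consumes it.
"""

from _common import parse_args

from plastisphere_n2o import qpcr, tables


def main() -> None:
    args = parse_args(__doc__)
    ct = tables.read_table(args.out / "data" / "ct.csv", tables.SCHEMAS["ct"])

    abundance = qpcr.ct_table_to_abundance(ct)
    normalized = qpcr.normalize_to_16S(abundance)
    tables.write_table(normalized.reset_index(), args.out / "gene_abundance.csv")

    ratios = qpcr.nir_nos_ratio(normalized).rename("nir_nos_ratio").reset_index()
    ratios["group"] = ratios["sample_id"].str.rsplit("-", n=1).str[0]
    ratios["habitat"] = ratios["group"].map(
        lambda g: "bulk" if g == "BW" else "plastisphere"
    )
    tables.write_table(ratios, args.out / "nir_nos_ratios.csv")

    by_habitat = ratios.groupby("habitat")["nir_nos_ratio"].agg(["mean", "min", "max"])
    print("(nirS+nirK)/nosZ by habitat:")
    print(by_habitat.round(3))


if __name__ == "__main__":
    main()
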