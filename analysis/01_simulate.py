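"""Generate the synthetic study: isotope, OTU, qPCR, Raman and 15N tables.

The scenario mirrors the incubation design (PE/PS/PP/PVC plastisphere in
triplicate, bulk water in quintuplicate) with ground-truth sidecars so
every later stage can be checked against what was planted.
"""

from _common import parse_args, seeds_for

from plastisphere_n2o import simulate as sim
from plastisphere_n2o import tables
from plastisphere_n2o.raman import spectra_to_long


def main() -> None:
    args = parse_args(__doc__)
    seeds = seeds_for(args.seed)
    cfg = sim.default_scenario()
    data = args.out / "data"

    iso, iso_truth = sim.gen_isotopes(cfg, seeds["isotopes"])
    otu, markers, otu_truth = sim.gen_otu_table(cfg, seeds["otu"])
    ct, _ = sim.gen_ct_table(cfg, seeds["ct"])
    spectra, raman_truth = sim.gen_raman(cfg, seeds["raman"])
    ipt, c2h2 = sim.gen_ipt(cfg, seeds["ipt"])

    tables.write_table(iso, data / "isotopes.csv")
    tables.write_table(iso_truth, data / "truth_isotopes.csv")
    tables.write_table(otu.reset_index(names="sample_id"), data / "otu.csv")
    tables.write_table(
        markers.rename_axis("taxon").reset_index(), data / "otu_markers.csv"
    )
    hubs = [
        {"habitat": h, "taxon": t}
        for h, taxa in otu_truth["hubs"].items()
        for t in taxa
    ]
    tables.write_table(
        __import__("pandas").DataFrame(hubs), data / "truth_hubs.csv"
    )
    tables.write_table(ct, data / "ct.csv")
    tables.write_table(spectra_to_long(spectra), data / "raman_long.csv")
    tables.write_table(raman_truth, data / "truth_raman.csv")
    tables.write_table(ipt, data / "ipt.csv")
    tables.write_table(c2h2, data / "acetylene.csv")

    print(f"wrote synthetic study to {data}")
    print(f"  {len(iso)} isotope samples in {iso['group'].nunique()} groups")
    print(f"  OTU table {otu.shape[0]} samples x {otu.shape[1]} taxa")
    print(f"  {len(spectra)} single-cell spectra, {len(ipt)} 15N incubations")


if __name__ == "__main__":
    main()
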