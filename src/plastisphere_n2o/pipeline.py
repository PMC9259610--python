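"""End-to-end driver: simulate -> isotopes -> partition -> rates -> qPCR ->
community -> Raman, with one global seed fanned out deterministically.

Each stage is also importable on its own; the numbered scripts under
``analysis/`` are thin wrappers over these functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecology, qpcr, raman, rates, tables
from .isotopocule import annotate_measurements
from .mass_balance import partition_table
from .simulate import (
    ScenarioConfig,
    default_scenario,
    gen_ct_table,
    gen_ipt,
    gen_isotopes,
    gen_otu_table,
    gen_raman,
)

__all__ = ["stage_seeds", "run_pipeline", "PipelineResult"]

_STAGES = ("isotopes", "otu", "ct", "raman", "ipt", "partition", "network", "anosim")


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan one global seed out to per-stage seeds (< 2**31).

    Uses numpy's SeedSequence spawning in a fixed stage order, so any
    stage can be re-run standalone with its own seed and reproduce the
    pipeline's output.
    """
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class PipelineResult:
    out_dir: Path
    summary: dict


def _group_fraction_summary(fractions: pd.DataFrame, habitat_of: dict) -> pd.DataFrame:
    df = fractions.copy()
    df["habitat"] = df["group"].map(habitat_of)
    return (
        df.groupby("habitat")[["f_BD", "f_FD", "f_CD"]]
        .agg(["mean", "sem"])
        .round(6)
    )


def run_pipeline(
    out_dir: str | Path,
    seed: int = 42,
    cfg: ScenarioConfig | None = None,
    n_draws: int = 10_000,
    network_permutations: int = 999,
) -> PipelineResult:
    """Run every stage on a synthetic scenario and write its tables.

    Writes per-stage CSVs plus ``summary.json`` under ``out_dir`` and
    returns the summary.  Fully reproducible under (seed, cfg).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cfg or default_scenario()
    seeds = stage_seeds(seed)
    habitat_of = {g.name: g.habitat for g in cfg.groups}

    # -- synthesis ---------------------------------------------------------
    iso, iso_truth = gen_isotopes(cfg, seeds["isotopes"])
    otu, markers, otu_truth = gen_otu_table(cfg, seeds["otu"])
    ct, _ = gen_ct_table(cfg, seeds["ct"])
    spectra, raman_truth = gen_raman(cfg, seeds["raman"])
    ipt, c2h2 = gen_ipt(cfg, seeds["ipt"])
    tables.write_table(iso, out / "synthetic" / "isotopes.csv")
    tables.write_table(iso_truth, out / "synthetic" / "truth_isotopes.csv")
    tables.write_table(otu.reset_index(names="sample_id"), out / "synthetic" / "otu.csv")
    tables.write_table(ct, out / "synthetic" / "ct.csv")
    tables.write_table(ipt, out / "synthetic" / "ipt.csv")
    tables.write_table(c2h2, out / "synthetic" / "acetylene.csv")
    tables.write_table(raman_truth, out / "synthetic" / "truth_raman.csv")

    # -- isotopocules and source partition ---------------------------------
    annotated = annotate_measurements(iso, ox=cfg.oxygen)
    tables.write_table(annotated, out / "isotopes_annotated.csv")
    fractions = partition_table(
        annotated,
        endmembers=cfg.endmembers,
        ox=cfg.oxygen,
        red=cfg.reduction,
        n_draws=n_draws,
        seed=seeds["partition"],
    )
    tables.write_table(fractions, out / "source_fractions.csv")
    frac_summary = _group_fraction_summary(fractions, habitat_of)
    frac_summary.to_csv(out / "source_fractions_by_habitat.csv")

    # -- rates -------------------------------------------------------------
    rate_rows = []
    for rec, c2 in zip(ipt.itertuples(), c2h2.itertuples()):
        m = rates.IPTMeasurement(rec.sample_id, rec.t29, rec.t30, rec.fn)
        share = rates.denit_anammox_share(m)
        pair = rates.AcetylenePair(c2.n2o_without_c2h2, c2.n2o_with_c2h2)
        norm = rates.CellNormalizer(c2.abundance_16S)
        rate = rates.denitrification_rate(m)
        rate_rows.append(
            {
                "sample_id": rec.sample_id,
                "group": rec.group,
                "denitrification_rate": rate,
                "rate_per_cell": rates.per_cell(rate, norm),
                "share_denitrification": share["share_denitrification"],
                "share_anammox": share["share_anammox"],
                "codenit_indicator": rates.codenitrification_indicator(m),
                "f_R": rates.n2o_reduction_ratio(pair),
            }
        )
    rate_table = pd.DataFrame(rate_rows)
    tables.write_table(rate_table, out / "rates.csv")

    # -- qPCR --------------------------------------------------------------
    abundance = qpcr.ct_table_to_abundance(ct)
    normalized = qpcr.normalize_to_16S(abundance)
    ratios = qpcr.nir_nos_ratio(normalized).rename("nir_nos_ratio").reset_index()
    ratios["group"] = ratios["sample_id"].str.rsplit("-", n=1).str[0]
    ratios["habitat"] = ratios["group"].map(habitat_of)
    tables.write_table(normalized.reset_index(), out / "gene_abundance.csv")
    tables.write_table(ratios, out / "nir_nos_ratios.csv")

    # -- community ---------------------------------------------------------
    habitat_labels = otu.index.to_series().map(otu_truth["habitat"])
    diversity = pd.DataFrame(
        {s: ecology.diversity_indices(otu, s) for s in otu.index}
    ).T
    diversity["habitat"] = habitat_labels
    tables.write_table(diversity.reset_index(names="sample_id"), out / "diversity.csv")
    dist = ecology.bray_curtis(otu)
    ord_res = ecology.pcoa(dist, k=2)
    ord_res["coordinates"].to_csv(out / "pcoa_coordinates.csv")
    ano = ecology.anosim(
        dist, habitat_labels.to_numpy(), n_perm=999, seed=seeds["anosim"]
    )
    niche = {
        h: ecology.niche_metrics(otu.loc[habitat_labels == h])
        for h in ("plastisphere", "bulk")
    }
    for h, df in niche.items():
        tables.write_table(df.reset_index(names="taxon"), out / f"niche_{h}.csv")
    keystones = {}
    for h in ("plastisphere", "bulk"):
        sub = otu.loc[habitat_labels == h]
        net = ecology.build_network(
            sub,
            markers=markers,
            n_perm=network_permutations,
            seed=seeds["network"],
        )
        ks = ecology.keystone_taxa(net, top_k=5)
        tables.write_table(ks, out / f"keystones_{h}.csv")
        keystones[h] = {
            "network": net.summary,
            "top_marker": ks["marker"].mode().iat[0] if len(ks) else None,
        }

    # -- Raman -------------------------------------------------------------
    cells = raman.process_spectra(spectra)
    cells["habitat"] = cells["group"].map(habitat_of)
    tables.write_table(cells, out / "raman_cells.csv")
    cd_by_group = cells.groupby("group")["cd_ratio"].mean()

    summary = {
        "seed": seed,
        "n_draws": n_draws,
        "fractions_by_habitat": {
            h: {
                src: float(frac_summary.loc[h, (f"f_{src}", "mean")])
                for src in ("BD", "FD", "CD")
            }
            for h in frac_summary.index
        },
        "mean_f_R": float(rate_table["f_R"].mean()),
        "mean_denit_share": float(rate_table["share_denitrification"].mean()),
        "nir_nos_by_habitat": {
            h: float(v)
            for h, v in ratios.groupby("habitat")["nir_nos_ratio"].mean().items()
        },
        "anosim": ano,
        "keystones": keystones,
        "cd_ratio_by_group": {g: float(v) for g, v in cd_by_group.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return PipelineResult(out_dir=out, summary=summary)
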