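"""Seeded generators for every table the pipeline consumes.

The default scenario mirrors the study design: four plastisphere groups
(PE, PS, PP, PVC biofilm suspensions, triplicate) and one bulk-water group
(quintuplicate).  Generated artifacts:

* N2O isotope measurements — either drawn from configured measured
  (SP, d18O) ranges per group (the default, calibrated to the observed
  habitat contrasts) or forward-modelled from true source fractions
  (used for parameter-recovery checks), with Gaussian measurement noise
  (0.9 permil site deltas, 0.6 permil d18O);
* denitrifier OTU tables — Dirichlet-multinomial counts with distinct
  habitat centroids, higher plastisphere richness, and planted
  high-degree hub taxa (bnirK in the plastisphere, bnirS in bulk water);
* chip qPCR Ct tables — Gaussian Ct per gene per habitat, configured so
  the (nirS+nirK)/nosZ ratio lands in distinct habitat bands;
* single-cell Raman spectra — Gaussian peaks at the lipid, C-D and C-H
  bands over a drifting baseline with multiplicative jitter, with the
  true per-cell C-D ratio recorded;
* isotope-pairing and acetylene tables consistent with the configured
  denitrification share and N2O reduction ratio.

Every generator is a pure function of (config, seed); ground-truth
sidecars accompany each table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .isotopocule import OExchangeParams
from .mass_balance import EndmemberSet, ReductionParams, forward_model
from .raman import RamanSpectrum

__all__ = [
    "GroupSpec",
    "ScenarioConfig",
    "default_scenario",
    "gen_isotopes",
    "gen_otu_table",
    "gen_ct_table",
    "gen_raman",
    "gen_ipt",
]


@dataclass(frozen=True)
class GroupSpec:
    """One habitat group of the incubation design.

    Exactly one of ``sp_range``/``d18o_range`` (measured-range mode) or
    ``true_fractions`` (forward-model mode) drives the isotope generator.
    """

    name: str
    habitat: str  # "plastisphere" | "bulk"
    n_samples: int
    sp_range: tuple[float, float] | None = None
    d18o_range: tuple[float, float] | None = None
    true_fractions: tuple[float, float, float] | None = None
    cd_ratio_mean: float = 0.1

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        range_mode = self.sp_range is not None and self.d18o_range is not None
        frac_mode = self.true_fractions is not None
        if range_mode == frac_mode:
            raise ValueError(
                "give either (sp_range, d18o_range) or true_fractions, not both"
            )
        if frac_mode and abs(sum(self.true_fractions) - 1.0) > 1e-9:
            raise ValueError("true_fractions must sum to 1")


@dataclass(frozen=True)
class ScenarioConfig:
    groups: tuple[GroupSpec, ...]
    endmembers: EndmemberSet = EndmemberSet()
    reduction: ReductionParams = ReductionParams()
    oxygen: OExchangeParams = OExchangeParams()
    # measurement noise (per-mil); printed instrument precisions
    site_delta_sd: float = 0.9
    d18o_sd: float = 0.6
    d15n_bulk_center: float = -20.0  # typical denitrification N2O bulk d15N
    # community structure
    n_taxa_per_marker: dict = field(
        default_factory=lambda: {"bnirS": 15, "bnirK": 15, "fnirK": 10}
    )
    separation: float = 0.85  # 0 = identical centroids, 1 = disjoint
    sequencing_depth: int = 2000
    dirichlet_concentration: float = 60.0
    n_hub_taxa: int = 5
    hub_factor_sd: float = 0.7
    richness_penalty: float = 0.7  # fraction of taxa suppressed in bulk
    # qPCR: per-habitat normalised-to-16S targets
    qpcr_targets: dict = field(
        default_factory=lambda: {
            "plastisphere": {"narG": 0.12, "nirS": 0.09, "nirK": 0.09, "nosZ": 0.10},
            "bulk": {"narG": 0.04, "nirS": 0.0185, "nirK": 0.0185, "nosZ": 0.10},
        }
    )
    ct_16s_mean: float = 12.0
    ct_sd: float = 0.15
    # Raman
    n_cells_per_group: int = 20
    cd_ratio_sd: float = 0.03
    raman_noise_sd: float = 0.01
    # isotope pairing
    fn: float = 0.99
    denit_rate: float = 0.05  # mg 15N L^-1 h^-1 scale of the incubations
    denit_share: float = 0.78  # denitrification share of N2 production
    f_r_true: float = 0.75
    n2o_total: float = 2.4
    abundance_16s: float = 4.1e9  # copies L^-1

    def __post_init__(self) -> None:
        for sd in (self.site_delta_sd, self.d18o_sd, self.ct_sd, self.cd_ratio_sd):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")


def default_scenario(**overrides) -> ScenarioConfig:
    """The study-design scenario: measured-range isotope mode, habitat
    contrasts in community, gene ratios and C-D activity."""
    plast_sp = (15.56, 26.21)
    plast_o = (64.14, 77.82)
    bulk_sp = (7.53, 8.68)
    bulk_o = (55.62, 59.93)
    cd_means = {"PE": 0.18, "PS": 0.22, "PP": 0.25, "PVC": 0.29}
    groups = tuple(
        GroupSpec(
            name=n,
            habitat="plastisphere",
            n_samples=3,
            sp_range=plast_sp,
            d18o_range=plast_o,
            cd_ratio_mean=cd_means[n],
        )
        for n in ("PE", "PS", "PP", "PVC")
    ) + (
        GroupSpec(
            name="BW",
            habitat="bulk",
            n_samples=5,
            sp_range=bulk_sp,
            d18o_range=bulk_o,
            cd_ratio_mean=0.09,
        ),
    )
    return replace(ScenarioConfig(groups=groups), **overrides) if overrides else ScenarioConfig(groups=groups)


def _sample_ids(g: GroupSpec) -> list[str]:
    return [f"{g.name}-{i + 1}" for i in range(g.n_samples)]


def gen_isotopes(cfg: ScenarioConfig, seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample (d15N_alpha, d15N_beta, d18O) plus a ground-truth sidecar.

    Range mode draws the noise-free measured (SP, d18O) uniformly from the
    group's configured ranges; fraction mode forward-models them from the
    group's true source fractions.  Site deltas are reconstructed around a
    bulk d15N and measurement noise added.
    """
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for g in cfg.groups:
        for sid in _sample_ids(g):
            if g.true_fractions is not None:
                sp_true, d18o_true = forward_model(
                    g.true_fractions, cfg.endmembers, cfg.oxygen, cfg.reduction
                )
            else:
                sp_true = rng.uniform(*g.sp_range)
                d18o_true = rng.uniform(*g.d18o_range)
            bulk = cfg.d15n_bulk_center + rng.normal(0.0, 2.0)
            alpha = bulk + sp_true / 2.0 + rng.normal(0.0, cfg.site_delta_sd)
            beta = bulk - sp_true / 2.0 + rng.normal(0.0, cfg.site_delta_sd)
            d18o = d18o_true + rng.normal(0.0, cfg.d18o_sd)
            rows.append(
                {
                    "sample_id": sid,
                    "group": g.name,
                    "habitat": g.habitat,
                    "d15N_alpha": alpha,
                    "d15N_beta": beta,
                    "d18O": d18o,
                }
            )
            truth.append(
                {
                    "sample_id": sid,
                    "group": g.name,
                    "sp_true": sp_true,
                    "d18o_true": d18o_true,
                    "f_BD": g.true_fractions[0] if g.true_fractions else np.nan,
                    "f_FD": g.true_fractions[1] if g.true_fractions else np.nan,
                    "f_CD": g.true_fractions[2] if g.true_fractions else np.nan,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def _taxa_labels(cfg: ScenarioConfig) -> tuple[list[str], pd.Series]:
    taxa, markers = [], {}
    for marker, k in cfg.n_taxa_per_marker.items():
        for i in range(k):
            t = f"{marker}_OTU{i + 1:02d}"
            taxa.append(t)
            markers[t] = marker
    return taxa, pd.Series(markers, name="marker")


def gen_otu_table(
    cfg: ScenarioConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Dirichlet-multinomial OTU counts with planted habitat structure.

    Returns (samples x taxa counts, taxon->marker Series, truth dict with
    the planted hub taxa per habitat).  Plastisphere samples keep all
    taxa; in bulk water a ``richness_penalty`` fraction of taxa is
    suppressed (lower richness).  ``separation`` mixes a shared centroid
    with habitat-specific ones; hub taxa share a per-sample multiplicative
    factor that makes them strongly co-occur.
    """
    rng = np.random.default_rng(seed)
    taxa, markers = _taxa_labels(cfg)
    t = len(taxa)
    shared = rng.dirichlet(np.full(t, 2.0))
    centroids = {}
    for habitat in ("plastisphere", "bulk"):
        own = rng.dirichlet(np.full(t, 0.8))
        centroids[habitat] = (1.0 - cfg.separation) * shared + cfg.separation * own
    # bulk richness penalty: suppress a deterministic-by-seed taxon subset
    n_drop = int(round(cfg.richness_penalty * t / 2))
    drop_idx = rng.choice(t, size=n_drop, replace=False)
    bulk_centroid = centroids["bulk"].copy()
    bulk_centroid[drop_idx] *= 1e-3
    centroids["bulk"] = bulk_centroid / bulk_centroid.sum()
    # planted hubs: bnirK in plastisphere, bnirS in bulk
    idx = {m: [i for i, x in enumerate(taxa) if markers[x] == m] for m in cfg.n_taxa_per_marker}
    hubs = {
        "plastisphere": [taxa[i] for i in idx["bnirK"][: cfg.n_hub_taxa]],
        "bulk": [taxa[i] for i in idx["bnirS"][: cfg.n_hub_taxa]],
    }
    # hubs must be reasonably abundant in their own habitat (and the bulk
    # hubs must survive the richness penalty)
    for habitat in ("plastisphere", "bulk"):
        keep = [taxa.index(h) for h in hubs[habitat]]
        centroids[habitat][keep] = np.maximum(centroids[habitat][keep], 0.02)
        centroids[habitat] /= centroids[habitat].sum()
    counts = []
    sample_ids, habitats = [], []
    for g in cfg.groups:
        c = centroids[g.habitat]
        hub_idx = [taxa.index(h) for h in hubs[g.habitat]]
        for sid in _sample_ids(g):
            props = rng.dirichlet(cfg.dirichlet_concentration * c)
            # hub taxa ride a shared per-sample factor with only small
            # idiosyncratic noise, so they co-occur tightly
            factor = np.exp(rng.normal(0.0, cfg.hub_factor_sd))
            props[hub_idx] = (
                c[hub_idx] * factor * np.exp(rng.normal(0.0, 0.05, len(hub_idx)))
            )
            props /= props.sum()
            counts.append(rng.multinomial(cfg.sequencing_depth, props))
            sample_ids.append(sid)
            habitats.append(g.habitat)
    table = pd.DataFrame(counts, index=sample_ids, columns=taxa)
    truth = {"hubs": hubs, "habitat": dict(zip(sample_ids, habitats))}
    return table, markers, truth


def gen_ct_table(cfg: ScenarioConfig, seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Long-format chip qPCR Ct records per sample per gene.

    Gene Ct means are back-computed from the configured normalised
    abundance targets via the 3.33 cycles/decade standard curve, so the
    downstream (nirS+nirK)/nosZ ratios land in the configured habitat
    bands; Gaussian Ct noise of ``ct_sd`` cycles is added.
    """
    rng = np.random.default_rng(seed)
    rows = []
    slope = 3.33
    for g in cfg.groups:
        targets = cfg.qpcr_targets[g.habitat]
        for sid in _sample_ids(g):
            ct16 = cfg.ct_16s_mean + rng.normal(0.0, cfg.ct_sd)
            rows.append({"sample_id": sid, "group": g.name, "gene": "16S", "ct": ct16})
            r16 = 10.0 ** ((31.0 - cfg.ct_16s_mean) / slope)
            for gene, norm in targets.items():
                ct = 31.0 - slope * np.log10(norm * r16) + rng.normal(0.0, cfg.ct_sd)
                rows.append({"sample_id": sid, "group": g.name, "gene": gene, "ct": ct})
    return pd.DataFrame(rows), {"targets": cfg.qpcr_targets}


_GRID = np.arange(600.0, 3200.0 + 1e-9, 2.0)
_CH_CENTER, _CH_WIDTH = 2930.0, 45.0
_CD_CENTER, _CD_WIDTH = 2160.0, 55.0
_LIPID_PEAKS = {972.0: 0.25, 1032.0: 0.35, 1080.0: 0.45, 1250.0: 0.30, 1735.0: 0.40}


def _gaussian(x: np.ndarray, center: float, width: float, area: float) -> np.ndarray:
    return area / (width * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - center) / width) ** 2)


def gen_raman(
    cfg: ScenarioConfig, seed: int | None = None
) -> tuple[list[RamanSpectrum], pd.DataFrame]:
    """Per-cell spectra with drifting baseline and known C-D ratios.

    Each cell's true ratio is drawn around its group mean; the C-D band
    area is set to ratio/(1-ratio) times the C-H area so the true
    (C-D)/(C-D+C-H) equals the drawn ratio exactly.  The baseline is a
    linear ramp plus a broad curved bump; intensities get multiplicative
    log-normal jitter.
    """
    rng = np.random.default_rng(seed)
    spectra, truth = [], []
    for g in cfg.groups:
        for i in range(cfg.n_cells_per_group):
            cell_id = f"{g.name}-cell{i + 1:02d}"
            ratio = float(np.clip(rng.normal(g.cd_ratio_mean, cfg.cd_ratio_sd), 0.0, 0.45))
            ch_area = 50.0 * np.exp(rng.normal(0.0, 0.2))
            cd_area = ratio / (1.0 - ratio) * ch_area
            y = _gaussian(_GRID, _CH_CENTER, _CH_WIDTH, ch_area)
            y += _gaussian(_GRID, _CD_CENTER, _CD_WIDTH, cd_area)
            for center, rel in _LIPID_PEAKS.items():
                y += _gaussian(_GRID, center, 8.0, rel * ch_area * np.exp(rng.normal(0, 0.1)))
            baseline = (
                0.05
                + 2e-5 * (_GRID - 600.0)
                + 0.08 * np.exp(-0.5 * ((_GRID - 1400.0) / 700.0) ** 2)
            ) * rng.uniform(0.5, 1.5)
            y = y * np.exp(rng.normal(0.0, cfg.raman_noise_sd, _GRID.size)) + baseline
            spectra.append(
                RamanSpectrum(_GRID.copy(), y, cell_id=cell_id, group=g.name)
            )
            truth.append(
                {
                    "cell_id": cell_id,
                    "group": g.name,
                    "habitat": g.habitat,
                    "true_cd_ratio": ratio,
                    "true_ch_area": ch_area,
                    "true_cd_area": cd_area,
                }
            )
    return spectra, pd.DataFrame(truth)


def gen_ipt(cfg: ScenarioConfig, seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Isotope-pairing and acetylene tables consistent with the config.

    t30 follows from the configured denitrification rate (rate = 2 t30/fn);
    t29 is the binomial expectation plus the anammox 29N2 implied by the
    configured denitrification share.  Acetylene pairs embed the true f_R.
    Returns (ipt table, acetylene table); the configured truths are the
    config fields themselves.
    """
    rng = np.random.default_rng(seed)
    ipt_rows, c2h2_rows = [], []
    for g in cfg.groups:
        # plastisphere incubations produce ~5x the bulk rate
        scale = 5.0 if g.habitat == "plastisphere" else 1.0
        for sid in _sample_ids(g):
            d = cfg.denit_rate * scale * np.exp(rng.normal(0.0, 0.05))
            t30 = d * cfg.fn / 2.0
            anammox = d * (1.0 - cfg.denit_share) / cfg.denit_share
            t29 = 2.0 * t30 * (1.0 - cfg.fn) / cfg.fn + anammox
            ipt_rows.append(
                {"sample_id": sid, "group": g.name, "t29": t29, "t30": t30, "fn": cfg.fn}
            )
            total = cfg.n2o_total * scale * np.exp(rng.normal(0.0, 0.05))
            residual = cfg.f_r_true * total
            c2h2_rows.append(
                {
                    "sample_id": sid,
                    "group": g.name,
                    "n2o_without_c2h2": residual,
                    "n2o_with_c2h2": total,
                    "abundance_16S": cfg.abundance_16s * scale,
                }
            )
    return pd.DataFrame(ipt_rows), pd.DataFrame(c2h2_rows)
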