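# plastisphere-n2o

Source partitioning of N₂O produced by plastic-surface biofilms
("plastisphere") versus surrounding bulk water, implemented as a tested
Python pipeline: a dual-isotope (site preference, δ¹⁸O) three-endmember
mass balance with Monte Carlo uncertainty, plus the supporting stages —
¹⁵N isotope-pairing rates, acetylene-block N₂O reduction ratio, qPCR
gene-abundance transforms, denitrifier community ecology (niche breadth
and overlap, diversity, PCoA/ANOSIM, co-occurrence networks) and
D₂O-labelled single-cell Raman C–D activity ratios. A seeded
synthetic-data module generates every input, so the whole analysis runs
and is testable with no downloads.

## The model

N₂O site preference SP = δ¹⁵Nᵅ − δ¹⁵Nᵝ and δ¹⁸O jointly discriminate
bacterial denitrification (BD), fungal denitrification (FD) and
chemodenitrification (CD). After subtracting the ambient-water δ¹⁸O
(complete O exchange, 0.91 ‰) and undoing the N₂O-reduction shift
(SP_NR = SP + f_R·SP_ε with f_R = 0.75, SP_ε = −6 ‰, δ¹⁸O_ε = −25 ‰),
the source fractions solve

```
f_BD + f_FD + f_CD = 1
f_BD·SP_BD   + f_FD·SP_FD   + f_CD·SP_CD   = SP_NR
f_BD·δ¹⁸O_BD + f_FD·δ¹⁸O_FD + f_CD·δ¹⁸O_CD = δ¹⁸O_NR
```

with endmembers BD (−1.5, 19), FD (37, 47), CD (16, 30) ‰. Negative
components are zeroed and the survivors rescaled to 100 %; endmember
uncertainty is propagated by 10,000 Monte Carlo draws. See
`docs/methods.md` for the full model, estimator choices and limitations.

## Worked example

```python
from plastisphere_n2o import mass_balance as mb

# a bulk-water-like measurement: SP 8.1 permil, d18O 57.8 permil
summary = mb.monte_carlo_partition(8.1, 57.8, n_draws=10_000, seed=42)
point = mb.partition_once(8.1, 57.8)
print("corrected:", {k: round(v, 2) for k, v in summary.extra.items()})
print("point estimate:", {k: round(float(v), 3) for k, v in zip(mb.SOURCES, point.as_array())})
print("clip frequency:", {k: round(float(v), 3) for k, v in summary.clip_frequency.items()})
```

prints

```
corrected: {'sp_nr': 3.6, 'd18O_nr': 38.14}
point estimate: {'BD': 0.578, 'FD': 0.422, 'CD': 0.0}
clip frequency: {'BD': 0.365, 'FD': 0.366, 'CD': 0.634}
```

i.e. after corrections this sample sits outside the endmember triangle
on the far side of the BD–FD edge: chemodenitrification is clipped to
zero (and, because CD lies close to that edge, the Monte Carlo clips one
source or another in most draws), and bacterial denitrification is the
dominant source at ~58 % — the bulk-water pattern. The full synthetic study runs
as numbered drivers:

```
python analysis/01_simulate.py --seed 42   # synthetic tables + truth sidecars
python analysis/02_partition_sources.py --seed 42
python analysis/03_rates.py --seed 42
python analysis/04_qpcr.py --seed 42
python analysis/05_community.py --seed 42
python analysis/06_raman.py --seed 42
```

writing tables under `results/`; `02` reports BD as the largest N₂O
source in both habitats with a higher fungal share in the plastisphere,
`04` reports (nirS+nirK)/nosZ ≈ 1.8 vs 0.37, `05` reports ANOSIM
R ≈ 0.96 (p = 0.001) with bnirK-type keystones on plastic, and `06`
recovers the planted C–D activity contrast (≈0.18–0.29 vs 0.09). The
same chain is available in one call as
`plastisphere_n2o.pipeline.run_pipeline(out_dir, seed=42)`.

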