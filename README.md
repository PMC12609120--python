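# eoquant

Quantification of **endocrine objects (EOs)** — single endocrine cells up
to whole islets — in bright-field, chromogen-immunolabeled 2D pancreas
sections, with cohort-level statistics for studying how the endocrine
architecture changes with age and with type 1 diabetes (T1D).

It is aimed at researchers analysing insulin/glucagon (DAB / Warp Red over
hematoxylin) stained sections who need per-object hormone areas, size-bin
profiles, density maps and group comparisons, and at methodologists who
want every stage verifiable: the package ships a synthetic-slide and
synthetic-cohort generator with pixel-exact ground truth, so the whole
pipeline can be tested end to end without any tissue images.

## The method

1. **Stain deconvolution.** Transmitted RGB intensities are converted to
   optical density, OD = −log₁₀((I+ε)/I₀), where stains mix additively
   (Beer–Lambert). Each pixel is attributed to the stain vector
   (hematoxylin, DAB = insulin, Warp Red = glucagon) with the largest
   projection, and counts hormone-positive when that projection exceeds a
   per-stain OD threshold. Assignment is winner-take-all, which slightly
   under-counts dual-positive pixels.
2. **EO detection and filtering.** Connected components (8-connectivity)
   of the union of the hormone masks; components below **170 μm²** (one
   endocrine cell) are discarded, and objects are retained only if the
   insulin- or glucagon-labeled area exceeds **40 μm²** (artifact filter).
3. **Classification and binning.** Per-hormone positivity (> 40 μm²)
   yields the content classes Ins⁺Gluc⁻, Ins⁺Gluc⁺, Ins⁻Gluc⁺. The size
   bin is

   EO bin = ⌊log₂(area μm² / 170 μm²)⌋

   i.e. log₂ of the approximate cell count; bins 0–3 are *small*, 4–6
   *medium*, 7–9 *large* (bin 6 starts at exactly 10,880 μm²).
4. **Morphometry.** Circularity 4πA/P², solidity A/convex-hull area,
   max/min Feret (caliper) diameters, equivalent circular diameter.
5. **Annotation matching QC.** Object tables from two platforms are paired
   by a greedy assignment on centroid distance + summed bounding-box
   coordinate differences; pairs whose bins differ by more than 1 are
   rejected, and area agreement is reported as R² before/after.
6. **Cohort statistics.** Sections are averaged within pancreas region,
   then regions within donor. Two-group comparisons use Mann-Whitney U
   with Benjamini-Hochberg adjustment; multi-group, Kruskal-Wallis with
   Tukey post hoc; group × bin designs, type-II two-factor ANOVA with
   Tukey or Dunnett post hoc. T1D donors split into endotypes by age at
   diagnosis (T1DE1 < 13 y, T1DE2 ≥ 13 y); autoantibody-positive donors
   are called high-risk when ≥ 3 of {GRS ≥ 50th percentile, insulitis,
   HLA-I hyperexpression, IA2A⁺} hold.

## Worked example

Simulate a two-group cohort (20 donors per group, two sections each) from
the shipped non-diabetic and T1D profiles, run the table-level pipeline
and compare the groups:

```python
import eoquant as eq
from eoquant.synthetic import eo_table_from_spec

specs, donors = eq.sample_cohort([eq.nd_profile(), eq.t1d_profile()],
                                 n_donors_per_group=20,
                                 sections_per_donor=2, rng_seed=7)
sections = [
    eq.build_section_profile(
        eq.objects_from_table(eo_table_from_spec(s)),
        s.tissue_area_mm2, section_id=s.section_id,
        donor_id=s.donor_id, region=s.region)
    for s in specs
]
metrics = eq.aggregate_cohort(sections)
groups = donors.set_index("donor_id")["group"].loc[metrics.index]
fam = ["count_share_InsOnly", "count_share_GlucOnly",
       "density_small_InsOnly_per_mm2", "eo_density_per_mm2"]
res = eq.compare_groups(metrics[fam], groups)
print(res.group_summary.pivot(index="metric", columns="group",
                              values="mean").round(2))
print(res.tests[["metric", "p_adj"]])
```

prints

```
group                             ND    T1D
metric
count_share_GlucOnly            8.38  79.95
count_share_InsOnly            54.09   5.96
density_small_InsOnly_per_mm2   4.16   0.00
eo_density_per_mm2              8.02   3.94
                          metric         p_adj
0            count_share_InsOnly  6.795615e-08
1           count_share_GlucOnly  6.795615e-08
2  density_small_InsOnly_per_mm2  3.190890e-08
3             eo_density_per_mm2  6.795615e-08
```

— in the simulated non-diabetic group, insulin-only objects are the most
frequent class (54% of EO count) and small insulin-only objects are
abundant (4.2 /mm²); in the simulated T1D group they are virtually absent
(6% and 0.00 /mm²) while glucagon-only objects dominate, and the
Mann-Whitney/Benjamini-Hochberg comparison flags all four metrics at
adjusted p ≪ 0.001.

The same analysis is available from the shell:

```sh
eoquant simulate --out sim --seed 3 --n-donors 4
eoquant cohort --eo-dir sim --donors sim/donors.csv --out results
eoquant quantify --image section.tiff --annotations eos.geojson \
    --mpp 0.5 --out areas.csv
```

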