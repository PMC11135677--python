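# urbantol

Urban tolerance indices for multi-taxon, presence-only occurrence data.

City biodiversity programs increasingly need to track whether urban areas are
gaining or losing the species that historically avoid them. `urbantol`
implements a full pipeline for doing that with unstructured community-science
records (iNaturalist-style exports) and urbanization rasters:

1. **Urban intensity** — co-registered urbanization layers (night lights,
   impervious surface, noise, ...) are standardized and composited by PCA;
   the oriented first component (PC1, larger = more urban) is the single
   spatial index of urban intensity on a quarter-mile analysis grid.
2. **Filtering** — research-grade, georeferenced records inside the study
   window and region; species with > 60% coordinate-obscured records removed
   wholly and all remaining obscured records dropped; subspecies lifted to
   species; expert curation flags (native, terrestrial, usable as an effort
   proxy) applied as a conjunction.
3. **Thinning & effort** — records thinned to one presence per species ×
   grid cell × year. Per detection group, effort `E` in a cell is the number
   of study years (0–11) with at least one record of *any* retained species
   of the group; the per-species count of presence-years `k` then forms a
   binomial response `k` out of `E`.
4. **UAI** — for each species with at least 25 thinned occurrences, a
   binomial GLM `k_i ~ Binomial(E_i, logit⁻¹(α + β·PC1_i))` is fit across
   cells. The logit-linear slope β is the species' **Urban Association
   Index**: positive = urban tolerant, negative = urban intolerant.
5. **CUTI** — the per-cell, per-group **Community Urban Tolerance Index** is
   the mean UAI of scored species detected in the cell, weighted by each
   species' presence-years (1–11), rebinned to a reversed 5-point scale
   (`(-∞,-0.5)→5 … [0.5,∞)→0`; high = natural-area-associated community),
   averaged across groups into a composite, summarized citywide, and tested
   against urban intensity with one-way ANOVA + Tukey HSD.

Because real multi-city downloads and licensed rasters cannot ship with a
package, `urbantol` includes a first-class synthetic-data module
(`urbantol.synthetic`) that generates the whole study system — correlated
environment layers, a species pool with *known* true slopes, and
effort-biased presence-only records — so the pipeline is validated end to
end by parameter recovery.

## Worked example

```python
import urbantol as ut

res = ut.run_synthetic_study(seed=1)
print(len(res.records_raw), "->", len(res.records))   # 463409 -> 263492
print(res.group_summary[["group", "n_fitted", "formatted"]])
print(res.citywide)
a = res.association
print(f"ANOVA: F={a.f_stat:.1f} (df {a.df_between},{a.df_within}), p={a.p_value:.3g}")
```

prints (seed 1, the default 60×60 grid, 3 groups × 30 species):

```
463409 -> 263492
         group  n_fitted              formatted
0        birds        20  -0.52 (-1.40 to 0.82)
1  butterflies        19  -0.44 (-0.91 to 1.00)
2      mammals        18  -0.44 (-1.36 to 0.68)
         group  n_cells  raw_cuti  binned_cuti
0        birds     2285 -0.151043     2.938293
1  butterflies     2240 -0.227136     3.383036
2      mammals     2292 -0.080713     2.678010
3    composite     2292 -0.152964     2.999780
ANOVA: F=2902.3 (df 5,2298), p=0
```

Reading this: of 90 simulated species, 57 retained enough filtered, thinned
occurrences to be scored; every group's mean UAI is negative (most species
were simulated as urban-avoiders), the citywide composite CUTI of ~3.0 says
the average scored community leans natural-area-associated, and the ANOVA
confirms that cells with low binned CUTI (urban-tolerant communities) have
much higher urban intensity. Fitted UAIs correlate ~0.93 with the true
generating slopes in this run.

The same stages run from the shell:

```bash
urbantol simulate --seed 3 --out sim/           # records.csv, truth.csv, rasters
urbantol urbanize --layers sim/layer_0.asc --layers sim/layer_1.asc \
         --layers sim/layer_2.asc --out pc1.asc
urbantol pipeline --seed 2 --out run/           # full chain + reports
```

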