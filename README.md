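# mpq — micropattern colony quantification

`mpq` quantifies spatial phenotypes of human pluripotent stem-cell colonies
grown on circular micropatterns, for two standard assays:

* **Activin A edge-restriction assay.** Wild-type colonies respond to apical
  activin A only at their rim: SMAD2/3 translocates into nuclei near the
  colony edge while central nuclei stay dark. Disease-model lines
  progressively lose this restriction — patchy central activation in
  heterozygous lines, near-uniform activation in HD and knockout lines.
  `mpq` measures this as (i) the **radial profile** of nuclear SMAD2/3,
  the binned mean of per-nucleus median intensities vs distance *r* to the
  colony center, normalized to its maximum; (ii) per-colony **band means**
  (center band 10–25 µm, edge band 175–225 µm); and (iii) the per-colony
  **percentage of SMAD2/3⁺ nuclei** above a recorded threshold.
* **Neuruloid assay.** Day-7 micropatterned neuruloids self-organize a
  central neuroectodermal domain (PAX6, N-CAD lumen) ringed by neural crest
  (SOX10). `mpq` reports each marker's segmented pixel area as a fraction
  of the total DAPI area, `A(marker ∩ DAPI) / A(DAPI)`.

Group comparisons use one-way ANOVA followed by Dunnett's many-to-one test
against the control line (or Tukey's HSD for all pairs), with the usual
star convention (\*p<0.05, \*\*p<0.01, \*\*\*p<0.001, \*\*\*\*p<0.0001).
The statistical unit is always the colony.

Because raw micrographs for assays like these are rarely deposited, the
package ships a first-class **synthetic generator** (`mpq.synthetic`) that
renders colonies and neuruloids with known per-nucleus and per-domain
ground truth, so the whole pipeline is testable end to end.

## The processing chain

1. **Colony detection** (`mpq.colonies`) — Otsu threshold on DAPI, closing +
   hole filling, area window around the predicted pattern size
   (π·(D/2)² ± 35%), alpha-shape boundary polygon whose centroid is the
   colony center.
2. **Nuclear segmentation** (`mpq.nuclei`) — Otsu foreground, watershed
   seeded at peaks of a smoothed-intensity + distance landscape, size
   filter (30–300 µm²), then per-nucleus median/mean intensity and distance
   to the colony center.
3. **Readouts** (`mpq.radial`, `mpq.classify`, `mpq.domains`) — radial
   profiles, band summaries, positive fractions, marker-area fractions.
4. **Statistics** (`mpq.stats`) — ANOVA + Dunnett (deterministic
   multivariate-t quadrature) or Tukey (studentized range).
5. **Orchestration** (`mpq.pipeline`, CLI `mpq`) — synth or TIFF-ingest
   runs with CSV outputs, plots and a JSON provenance record; identical
   (config, seed) runs are byte-identical.

## Worked example

Four synthetic conditions, five colonies each, scaled-down 240 µm patterns
(~420 nuclei per colony), Dunnett vs the WT control:

```python
from mpq.pipeline import RunConfig, run_activin

cfg = RunConfig(
    assay="activin", outdir="out", seed=7,
    conditions={"WT": 5, "HET": 5, "HD": 5, "KO": 5},
    n_nuclei=420, expected_diameter=240, max_radius=120,
    edge_band=(75.0, 100.0),
)
res = run_activin(cfg)
print(res.tables["stats"].query("readout == 'center_mean'"))
```

prints

```
    readout group  n       mean        sd comparison        p_adj stars  method
center_mean    HD  5 100.282602  7.446106   HD vs WT 1.069109e-10  **** dunnett
center_mean   HET  5  49.471034 14.434158  HET vs WT 5.706680e-04   *** dunnett
center_mean    KO  5 104.953490  0.054662   KO vs WT 4.333788e-11  **** dunnett
center_mean    WT  5  24.949981  0.054277        NaN          NaN       dunnett
```

Read: WT colonies average ~25 a.u. of nuclear SMAD2/3 in the center band
(edge restriction intact: their edge-band mean is ~105 a.u.), HET colonies
sit in between with high colony-to-colony spread (patchy central
activation), and HD/KO colonies are uniformly activated (~100–105 a.u.
everywhere); every mutant line differs from WT after Dunnett adjustment.
The same run writes `colonies.csv`, `nuclei.csv`, `profiles.csv`,
`bands.csv`, `positives.csv`, `stats.csv`, plots and `provenance.json`
under `out/`.

From a shell the equivalent is:

```bash
mpq synth colony --phenotype WT --n-colonies 5 --seed 0 --outdir imgs
mpq activin --config run.yaml
mpq stats --input out/bands.csv --value-column center_mean --control WT
```

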