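# eddyomics

Comparative multi-omic analysis of microbial communities in paired
mesoscale ocean eddies of opposite polarity.

Cyclonic eddies lift isopycnals and shoal the deep chlorophyll maximum
(DCM); anticyclones depress it. This restructures light and nutrients at
depth, and with them the *Prochlorococcus* ecotype composition and its
expressed functions. `eddyomics` implements the statistical pipeline for
contrasting two adjacent eddies sampled the same way — a high-resolution
depth survey (15 depths at 5 m intervals around each eddy's DCM) plus a
diel series of 18 DCM samples per eddy — across three data layers:

1. **Amplicon / marker depth profiles.** Counts become within-sample
   relative abundances; a feature's enrichment between eddies inside a
   DCM-relative depth window is tested with a Kruskal–Wallis rank test.
2. **Metagenomes (reads per billion, RPB).** Gene abundances aggregated by
   KEGG Orthology (KO) are screened for an ecotype's functional traits:
   a KO passes when its Pearson correlation with the target ecotype's
   marker RPB satisfies r > 0.5 with p < 0.01 and its difference/total
   ratio D = (C − A)/(C + A) > 0.5, where C and A sum the KO over cyclone
   and anticyclone samples at or above the DCM.
3. **Metatranscriptomes with ERCC spike-ins.** Known molar amounts of
   synthetic RNA standards give each sample a correction factor *f* (the
   forced-origin least-squares slope of spike counts on molecules, i.e.
   counts per molecule) and a detection limit (smallest detected molar
   amount). Raw counts become absolute transcripts per ml as
   count / *f* / volume. Taxon-level sums are compared between eddies with
   fold change FC = mean(anticyclone)/mean(cyclone), Kruskal–Wallis tests
   and Benjamini–Hochberg correction (flags at q < 0.05 and FC > 3 or
   < 1/3); within flagged taxa, per-transcript expression fractions are
   tested with a two-group negative-binomial Wald test (flags at q < 0.05
   and |log2FC| > 2), and significant transcripts are summarized by COG
   category or KEGG pathway (pathways kept only with more than two member
   transcripts, ambiguous both-sides eggNOG annotations excluded).

A synthetic-data module generates complete two-eddy datasets with known
ground truth (planted ecotype peaks, KO couplings, taxon fold changes,
differentially expressed transcripts and spike-in efficiencies), so every
stage can be validated by label recovery without any sequencing data.

## Worked example

```python
from eddyomics import (ErccCalibrationModel, ProfileEnrichmentModel,
                       TraitEnrichmentModel, TaxonDifferentialModel,
                       ExpressionDifferentialModel, sum_by_taxon)
from eddyomics.simulate import simulate_dataset, diel_ids

ds = simulate_dataset(seed=1)
diel = ds.meta.subset(diel_ids(ds.meta))
depth = ds.meta.subset(ds.ecotype_rpb.samples)

cal = ErccCalibrationModel(ds.spike_counts, ds.ercc_reference).fit()
print(cal.summary())
per_ml = cal.normalize(ds.transcript_counts, diel)

print(ProfileEnrichmentModel(ds.ecotype_rpb, depth, "HLI").fit().summary())

species = sum_by_taxon(per_ml, per_ml.annotations["taxon"])
taxa = TaxonDifferentialModel(species, diel).fit()
print(taxa.summary())
```

prints (abridged):

```
Spike-in calibration
====================
samples: 36   standards: 92
correction factor (counts/molecule): median 0.5881, range [0.2078, 0.7747]
detection limit (molecules): median 10

Depth-profile enrichment (Kruskal-Wallis rank test)
===================================================
feature: HLI   window: at_or_above_dcm
groups: cyclone vs anticyclone
H = 11.2941   p = 0.0007775   df = 1
direction: enriched in cyclone

Taxon differential representation (anticyclone / cyclone)
=========================================================
taxa tested: 112   dropped (all-zero): 0
samples: 18 cyclone vs 18 anticyclone
flags at q < 0.05, FC > 3.0 or < 1/3: 6 anticyclone-enriched, 6 cyclone-enriched
```

The correction factors recover the simulated per-sample capture
efficiencies (drawn uniform in 0.2–0.8); the HLI marker, planted with its
peak above the cyclone DCM, is detected as cyclone-enriched; and the
twelve taxa planted with four-fold abundance shifts are the twelve flagged.

The same stages are available from the shell:

```bash
eddyomics simulate --seed 1 --outdir sim/
eddyomics ercc-normalize --counts sim/transcript_counts.tsv \
    --spikes sim/spike_counts.tsv --reference sim/ercc_reference.tsv \
    --meta sim/sample_meta.tsv --out per_ml.tsv
eddyomics diff-taxa --transcripts per_ml.tsv \
    --annotations sim/transcript_annotations.tsv \
    --meta sim/sample_meta.tsv --out taxa.tsv
```

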