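# immigratio

Immigration-aware 16S rRNA amplicon community analysis for anaerobic
digesters.

## The problem

Anaerobic digesters at wastewater treatment plants are continuously fed
primary sludge and surplus activated sludge. A large share of the 16S reads
observed in digester sludge can come from cells (or persistent DNA) that
merely *arrive* with that feed rather than growing in the reactor. Ignoring
this immigration skews correlation analyses and paints a false picture of
the active community. `immigratio` implements the standard amplicon workflow
(rarefaction, relative abundances, taxonomy curation overlay, group-mean
heatmaps, abundant-core statistics, PCA ordination, alpha diversity) plus
the immigration statistic that separates growing from non-growing
populations — for microbial ecologists working with OTU tables from
digester/influent surveys.

## The statistic

For each OTU *i* and digester process group *g* (mesophilic, thermophilic,
or mesophilic with thermal hydrolysis pre-treatment, THP):

```
r_ig = mean digester abundance of i in g  /  max(mean influent abundance of i, ε)
```

where the influent mean is the 50:50 average of the primary- and
surplus-stream means (the feed's organic mass ratio) and ε is a
pseudo-abundance of half a read at the rarefaction depth (5×10⁻⁵ at 10 000
reads). At steady state a population that does not grow can at best hold its
influent abundance, so `r ≤ 1` flags immigrating/non-growing populations and
`r ≫ 1` in-situ growers. The distribution of `log10 r`, weighted by digester
read abundance, is bimodal in ordinary digesters; a two-component weighted
Gaussian mixture locates the split (typically near a ratio of 10). THP
digesters, whose feed biomass is lysed, lack the immigration mode and act as
a no-immigration control. OTUs are classified `growing` (r > 10),
`non_growing` (r ≤ 1) or `intermediate`.

A synthetic source–sink generator (`immigratio.synthetic`) produces
datasets with this exact structure — log-normal influent streams, survival
factors s = 1/(1 + b·θ) for immigrants, feed-independent grower mass,
Dirichlet-multinomial read noise — with per-OTU ground truth, so every
stage of the pipeline is verifiable without external data.

## Worked example

```
$ immigratio simulate --seed 7 --outdir out
balanced accuracy: 0.9716
mesophilic: split=3.57 bimodal=True
thermophilic: split=4.24 bimodal=True
thp: split=10 bimodal=False
```

The simulator generated ~2000 OTUs across three process groups, the
pipeline classified each OTU from its abundance ratio, and 97.2% balanced
accuracy was achieved against the generator's ground truth. The weighted
log-ratio distributions of the two ordinary groups are bimodal with splits
at ratios 3.6 and 4.2; the THP control is unimodal (the reported 10 is the
default fallback split, not a detected one). The per-OTU table
(`out/ratios_mesophilic.tsv`) begins:

```
otu_id    mean_influent  mean_digester     ratio  growth_class
OTU_298          0.0000         0.0176  352.3500       growing
OTU_1082         0.0281         0.0166    0.5902   non_growing
OTU_77           0.0367         0.0141    0.3829   non_growing
```

OTU_298 is absent from the influent and abundant in the digesters — an
in-situ grower. OTU_1082 is *more* abundant in the feed than in the
digesters (ratio 0.59): despite being the second most abundant OTU in the
mesophilic reactors it is non-growing, maintained by immigration — exactly
the pattern that misleads immigration-blind analyses.

To analyze your own tables (OTUs in rows, samples in columns, final
`Taxonomy` column; metadata with sample_id, plant, sample_type ∈
{primary, surplus, digester} and process_type):

```
immigratio analyze --counts counts.tsv --metadata metadata.csv --outdir results/
```

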