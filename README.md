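# trophoweb

Analysis pipeline for asking how the position of a soil invertebrate in the
food web shapes its microbiome. Soil animals — collembolans, nematodes,
potworms, earthworms, oribatid mites, predatory mites — carry bacterial
communities that are partly drawn from the surrounding soil and partly their
own. `trophoweb` quantifies that relationship along four axes:

1. **Diversity structure** — hierarchical additive partitioning of Shannon
   diversity (γ = ᾱ + Σβᵢ, exactly), UniFrac/Jaccard distances, PCoA, and
   PERMANOVA with pairwise tests and compact letter displays.
2. **Community assembly** — the Sloan neutral community model: an OTU with
   mean relative abundance *p* in the source pool is predicted to occur in a
   fraction f̂(p) = 1 − Beta-CDF(d; *Nm·p*, *Nm*(1−*p*)) of hosts, where
   *N* is reads per sample, *m* the migration probability, and *d* the
   detection limit. *Nm* is fitted by least squares; OTUs are classed
   above/within/below a Wilson 95 % band, and the fit is weighed against a
   binomial occurrence null by AIC.
3. **Trophic position** — δ¹⁵N = ((R_sample − R_ref)/R_ref)·10³ vs air,
   adjusted by site litter, binned into integer trophic levels of width
   3.4 ‰, and regressed against microbiome diversity and unique-taxon counts.
4. **Microbial dark matter** — genus/class-level co-occurrence networks
   (CLR + Pearson, thresholded), hub scores, and an Original /
   Without-Unknown / Bootstrap node-removal experiment that tests whether
   unidentified taxa hold the network together.

Because the pipeline is exercised on synthetic data, the package ships a
first-class generator (`trophoweb.simulate`) that plants every signal the
analyses are meant to find: group-specific unique OTUs absent from soil by
construction, per-group migration rates, enterotypes, a δ¹⁵N gradient, and
a configurable dark-matter fraction — so each stage can be validated against
known ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
survey (six sites × farmland/forest × six faunal groups + soil, 420 samples,
rarefied to 13,551 reads):

```bash
python analysis/01_simulate_study.py
python analysis/02_filter_rarefy.py
python analysis/06_neutral_model.py
```

which prints, for the neutral-model stage:

```
collembolan: Nm=3826 (planted 4026), R2=0.978, within=79.4%, AIC neutral -5642 vs binomial -3143
earthworm: Nm=1674 (planted 1802), R2=0.977, within=81.9%, AIC neutral -5287 vs binomial -2389
nematode: Nm=632 (planted 667), R2=0.955, within=83.0%, AIC neutral -5027 vs binomial -1756
...
Nm ordering recovered: True
```

Each group's fitted migration parameter *Nm* lands within a few percent of
the value the generator planted, the neutral fit beats the binomial null
for every group (lower AIC), and the across-group ordering of *Nm* is
reproduced exactly. The other scripts report the diversity partition
(`03`), ordination and PERMANOVA (`04`, e.g. weighted UniFrac
F₆,₄₁₃ = 102.2, P = 0.001), enterotype recovery (`05`, ARI = 1.0 for all
six groups), the trophic gradient (`07`, Shannon ~ δ¹⁵N with R² = 0.68,
P < 10⁻⁸⁹), exact recovery of every planted unique-taxon set (`08`), and
the dark-matter network comparison (`09`, removal of unknown taxa lowers
betweenness and degree relative to random removal, P < 10⁻⁶).

The same stages are scriptable via the `trophoweb` CLI
(`trophoweb simulate | partition | betadiv | permanova | enterotype | ncm |
trophic | unique | darknet | run`); `trophoweb run --config run.yaml`
executes the whole pipeline with manifests and byte-reproducible outputs.

## Layout

```
src/trophoweb/    io, simulate, diversity, beta, enterotype, neutral,
                  trophic, unique, network, pipeline, cli
analysis/         numbered narrative drivers writing tables to results/
tests/            pytest suite incl. property tests and acceptance checks
scripts/          acceptance.py
docs/methods.md   model assumptions, parameter choices, limitations
```
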