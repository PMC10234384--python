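# recmap

Recombination-landscape mapping for biparental RIL (recombinant inbred
line) populations: from SNP genotype matrices to Marey-map recombination
rate profiles, hotspot/coldspot calls, cross-population hotspot sharing,
genomic-feature association and motif flank enrichment — together with a
forward RIL simulator that provides ground-truth landscapes, so every stage
of the pipeline can be verified against known truth.

## Pipeline

| stage      | module              | what it does |
|------------|---------------------|--------------|
| simulate   | `recmap.simulate`   | F_k RILs by single seed descent over a piecewise recombination landscape (Poisson crossovers, inverse-transform placement); emits genotypes + crossover truth |
| qc         | `recmap.qc`         | marker filters: >10% missingness, segregation-distortion χ² (P < 0.01), duplicate-pattern collapse |
| map        | `recmap.linkmap`    | physical-order two-point genetic maps; exact finite-generation RIL correction (F5 default) or the Haldane–Waddington F∞ limit; Kosambi/Haldane distances |
| rates      | `recmap.marey`      | isotonic Marey map cleanup, cubic-spline rate profiles (cM/Mbp), fixed-window genetic/physical ratio |
| hotspots   | `recmap.hotspots`   | sliding-window peak calling against per-chromatin-class median background, Tukey size-outlier filter, coldspots, chromatin classification, set comparison |
| assoc      | `recmap.assoc`      | gene-region annotation from GFF3; windowed logistic regression of hotspot/coldspot status on feature coverage (Wald test) |
| motifs     | `recmap.motifs`     | poly-A run and CCN-like IUPAC scans of hotspot flanks, permutation enrichment vs length/chromatin-matched background |
| io / cli   | `recmap.io`, `recmap.cli`, `recmap.pipeline` | genotype TSV, BED, BedGraph, GFF3, FASTA, TOML landscapes; `recmap` CLI; `run_all` orchestrator |

Coordinates are 0-based half-open everywhere; GFF3 is converted at the
boundary. Rates are cM/Mbp throughout.

## CLI

```sh
# simulate a demo population over a TOML landscape spec
recmap simulate --landscape landscape.toml --n-lines 500 --marker-spacing 25000 \
    --seed 1 --out sim/

# stage by stage
recmap qc --genotypes sim/genotypes.tsv --out qc.tsv --report qc_report.json
recmap map --genotypes qc.tsv --function kosambi --out map.tsv
recmap rates --map map.tsv --method spline --grid 10000 --out rates.bedgraph
recmap hotspots --rates rates.bedgraph --chromatin chromatin.bed --out hotspots.bed
recmap coldspots --rates rates.bedgraph --out coldspots.bed
recmap compare --a we_hotspots.bed --b wp_hotspots.bed --out shared.tsv
recmap assoc --hotspots hotspots.bed --coldspots coldspots.bed --te te.bed \
    --map map.tsv --out assoc.tsv
recmap motifs --hotspots hotspots.bed --fasta genome.fa --seed 1 --out motifs.tsv

# or end to end
recmap all --genotypes sim/genotypes.tsv --chromatin chromatin.bed --out run/
```

`recmap all` writes every intermediate plus `manifest.json` (config, seed,
QC accounting, spline clamping diagnostics) and a summary table.

See `recmap.io.read_landscape` for the TOML landscape format.

## Notes on methods

- Two-point recombination fractions from RILs are corrected for inbreeding
  generations. The classical fixation-limit inversion r = R/(2−2R) is
  provided (`correct_ril`), but at F5 it understates the map by ~26%, so
  `build_map` defaults to `correct_ril_finite`, which inverts the exact
  two-locus selfing Markov chain for the stated generation.
- Spline rate profiles default to an explicit roughness penalty in the
  pipeline (λ = 0.1, Mbp units). Cumulative-map noise is a random walk, so
  generalized cross-validation badly under-smooths; GCV and pure
  interpolation remain available via `--smoothing`.
- Negative spline derivatives are clamped at zero and the track is rescaled
  to conserve map length; the clamped fraction is logged as a fit
  diagnostic.
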