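# aeronit

Quantitative workflow for ammonia-oxidizing microorganisms (AOA, AOB and
comammox) in fine particulate matter (PM2.5): marker-gene community
characterization, qPCR-based absolute abundance per m³ of sampled air,
nitrification-potential kinetics, and model-based partitioning of
ammonia oxidation among guilds. A seeded synthetic-data module stands in
for field samples so every stage is testable offline with known ground
truth.

## Modules

| Module | Purpose |
| --- | --- |
| `aeronit.synthetic` | Seeded generators for every pipeline input: clustered clone-library sequences, 10-fold dilution qPCR plates, zero-order incubation series with paired blanks, environmental-factor tables with planted monotone links. |
| `aeronit.qpcr` | Standard-curve fitting (Cq vs log10 copies), inversion to copies, copies→cells via per-cell gene copy numbers (1 *amoA*/AOA and comammox, 2.5/AOB, 3.6 16S/prokaryote), normalization to cells m⁻³ air, guild ratio/proportion summaries. |
| `aeronit.community` | Pairwise p-distances (global alignment for unequal lengths), furthest-neighbor OTU clustering at 97% similarity (distance 0.03, boundary-inclusive), Shannon/Chao1 diversity, shared-OTU sample network. |
| `aeronit.phylo` | Jukes–Cantor correction, Saitou–Nei neighbor joining with deterministic tie-breaking and negative-branch clamping, column-bootstrap support, newick output. |
| `aeronit.kinetics` | Blank-corrected net concentrations, two-point maximum nitrification rate NNR_max = (net₀ − net_t)·Q1·1000/(t·Q2) in μg (NH₄⁺-N) m⁻³ air h⁻¹, nitrogen mass-balance report. |
| `aeronit.attribution` | Guild rates cells·r_in·Mr_N·10⁻⁹; relative contributions RC_AOA, RC_AOB with comammox as remainder; scenario grid over r_in ∈ {0.5, 208} × {1, 50} fmol cell⁻¹ h⁻¹. |
| `aeronit.stats` | Spearman rank correlation with exact-permutation p-values (all n! orderings for n ≤ 8), Monte Carlo and asymptotic fallbacks, heatmap-ready correlation matrix, optional Benjamini–Hochberg. |

## CLI

Every command works on plain-text formats (FASTA, CSV/TSV, newick; specs
as YAML):

```bash
aeronit simulate sequences community.yaml -o sim        # FASTA + truth CSV
aeronit simulate qpcr plate.yaml -o plate --target aoa
aeronit simulate incubation inc.yaml -o inc
aeronit simulate env env.yaml -o env

aeronit otu cluster sim.fasta -o otu --cutoff 0.03      # OTU table, reps, edges
aeronit otu diversity otu.otu_table.csv -o diversity.csv
aeronit tree sim.fasta -o tree.nwk --bootstrap 100 --seed 1
aeronit quantify plate.plate.csv -o abundance.csv --copies-per-cell 1 \
    --filter-fraction 0.25 --air-volume 144
aeronit kinetics rate inc.series.csv -o rates.csv --q1 0.25 --q2 48
aeronit kinetics balance inc.series.csv -o balance.csv
aeronit attribute --abundance abundance.csv --rates rates.csv -o contrib.csv
aeronit correlate env.factors.csv env.taxa.csv -o corr.csv
```

Example YAML specs appear in `tests/test_cli.py`.

## Notes and assumptions

- Replicate Cq values convert to copies individually, then average on
  the linear scale (geometric-mean alternative available).
- Efficiency/R² gates on standard curves warn rather than fail.
- The comammox contribution is defined as the remainder
  1 − RC_AOA − RC_AOB (no comammox cell-specific rate is available); a
  direct-rate mode exists for sensitivity analysis. Raw AOA+AOB sums
  above 1 are proportionally rescaled and flagged.
- Heterotrophic ammonia assimilation is ignored by default (documented
  assumption) with an optional fractional discount.
- Distances use pairwise deletion for ambiguous/gapped sites; the
  reaction→extract scale-up factor is explicit config because elution
  and template volumes are lab-specific.
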