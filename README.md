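# vampscan

A pipeline for variant-abundance sort-seq (VAMP-seq) deep mutational
scans: from barcode–variant subassembly and FACS-bin read counting to
normalized abundance scores, degron-tile stability indices, and
variant-effect-map analysis — with a synthetic sort-seq generator so
every stage runs, and is tested, without external data.

**Who it is for.** Groups running (or reanalyzing) multiplexed
variant-abundance assays: a site-saturation library of protein variants
fused to GFP is sorted by GFP:mCherry ratio into four equal-occupancy
bins, and barcode sequencing of each bin quantifies where each variant
sits in the abundance distribution. The same machinery scores short
peptide tiles to map degradation signals (degrons).

## The score

For barcode *b* with read frequency *f<sub>b,g</sub>* in FACS gate *g*
(gate 1 = lowest GFP:mCherry ratio, gate 4 = highest; per-gate
frequencies, no pseudocounts):

```
PSI_b = Σ_g g·f_{b,g} / Σ_g f_{b,g}
```

Barcode PSIs are averaged per variant and per replicate, replicates are
averaged, and scores are anchored so the wild type scores 1 and the
median nonsense variant 0:

```
abundance = (PSI_i − PSI_stop) / (PSI_WT − PSI_stop)
```

Peptide tiles get the analogous tile stability index (TSI), and
separately sorted tile sub-libraries (Odds / Evens / C-terminal) are
placed on a common scale by an affine fit through shared control
peptides. Downstream analyses include per-position missense medians, a
low-abundance classification, ROC/AUC against clinical labels (low
abundance predicting pathogenicity), and correlations with external
per-variant scores (ΔΔG, conservation).

## Worked example

Simulate a small saturation scan with known ground truth and score it:

```python
import vampscan as vs
from scipy.stats import spearmanr

seq = vs.ProteinSequence("demo", "MCDEFGHIKL")
design = vs.enumerate_design_space(seq, include_synonymous=True)
# {'missense': 190, 'nonsense': 9, 'wild-type': 1, 'synonymous-wild-type': 1}

exp = vs.simulate_experiment(design, mean_barcodes_per_variant=10,
                             cells_per_barcode=100, n_biological=2,
                             n_technical=2, seed=7)
result = vs.score_counts(exp.counts, exp.barcode_map)
print(f"PSI_WT = {result.psi_wt:.3f}   PSI_stop = {result.psi_stop:.3f}")

merged = result.scores.merge(exp.true_scores, on="variant")
print(f"Spearman(true, estimated) = "
      f"{spearmanr(merged.true_score, merged.score).statistic:.3f}")
```

prints

```
PSI_WT = 3.423   PSI_stop = 1.279
Spearman(true, estimated) = 0.998
```

and the score table contains rows such as

```
variant  category     score       sd  n_barcodes
    C2*  nonsense -0.051770 0.000665           9
    D3A  missense  0.870905 0.011554           9
    M1C  missense  0.951364 0.011485           8
     WT wild-type  1.000000 0.000000          11
```

The wild type sits at 1.000 by construction, the nonsense variant near
0 (slightly below, since the anchor is the nonsense *median*), and the
two missense variants near their simulated WT-like abundances; `sd` is
the spread over per-replicate scores and `n_barcodes` the number of
independent barcodes averaged per variant.

The same flow is available from the shell:

```bash
vampscan run --config config.yaml --outdir run/ --seed 7
```

with subcommands `design`, `simulate`, `subassemble`, `score`, `tiles`
and `analyze`, a YAML config validated before anything runs, and a
`manifest.json` recording a content digest of every output.

## Layout

| Module | Role |
|---|---|
| `vampscan.library_design` | design-space enumeration, peptide tiling, sub-library partition, oligo design |
| `vampscan.synthetic_data` | ground-truth generators: abundances, barcode libraries, long reads, FACS sorting, sequencing, tile pools |
| `vampscan.subassembly` | barcode→variant map from long reads, with rejection and conflict rules |
| `vampscan.abundance_scoring` | counts → frequencies → PSI → normalized abundance scores, replicate QC |
| `vampscan.degron_scoring` | TSI, contaminant removal, control-anchor renormalization, per-residue profiles |
| `vampscan.atlas_analysis` | effect-map matrix, position medians, low-abundance classes, ROC/AUC, external correlations |
| `vampscan.pipeline` / `vampscan.cli` | stage orchestration, config validation, run manifests |

See `docs/methods.md` for the model, the simulator's assumptions, and
numerical conventions.
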