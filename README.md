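# ccfdna

Quantification of colon-derived cell-free DNA (c-cfDNA) from targeted
bisulfite amplicon sequencing, with the downstream statistics used to relate
c-cfDNA levels and dynamics to treatment response in locally advanced rectal
cancer (LARC) under neoadjuvant chemoradiation (nCRT).

## The problem

Plasma cfDNA is a mixture of fragments released by dying cells of many
tissues. Colon epithelium can be recognized in that mixture by a small panel
of marker loci whose CpG sites are unmethylated specifically in colon and
methylated in the blood-cell background. After bisulfite conversion,
unmethylated cytosines read as T and methylated cytosines stay C, so each
sequenced molecule carries a CG/TG pattern across the marker's CpGs. The
colon-derived signal at a marker is the fraction of molecules in which
*every* CpG reads TG:

```
fraction_m = (# molecules with all CpGs unmethylated) / (# accepted molecules at marker m)
c-cfDNA [GE/ml] = mean_m ( fraction_m × total cfDNA [ng/ml] × 303 )
```

where 303 converts ng/ml to haploid genome equivalents per ml (3.3 pg per
haploid genome). Clinically, low c-cfDNA at the start of the second
treatment week (W2D1) marks patients heading for pathologic complete
response (pathCR, TRG 0), and a strict W1D1→W2D1 increase is associated with
disease recurrence.

Because the patient plasma and cohort data behind these analyses are not
publicly deposited, the package ships a first-class synthetic layer: a
plasma mixture read simulator with known per-molecule ground truth, and a
longitudinal cohort simulator with pathCR structure, relapse-coupled
c-cfDNA dynamics, and right-censored follow-up. Every statistical routine is
validated against independent enumeration oracles.

## What is in the box

| module | contents |
|---|---|
| `ccfdna.panel` | marker/panel types, validation (CpG map, primer CH rule), bisulfite conversion, panel TSV and FASTA I/O, the deterministic 8-marker fixture panel |
| `ccfdna.readsim` | plasma mixture model → multiplexed FASTQ with ground truth |
| `ccfdna.quant` | demultiplexing, bisulfite-aware alignment (score ≥ −0.2×length acceptance), CG/TG calling, molecule classification, fractions, GE/ml conversion |
| `ccfdna.cohort` | longitudinal cohort simulator, CSV round-trip, summaries |
| `ccfdna.stats` | Mann-Whitney U (exact/asymptotic), Fisher's exact, ROC AUC with DeLong or bootstrap CI, Kaplan-Meier + log-rank, W1D1→W2D1 dynamics calls, full response-analysis report |
| `ccfdna.cli` | `ccfdna panel-validate / simulate-reads / quantify / simulate-cohort / analyze / end-to-end` |

## Worked example

```python
import ccfdna as c

panel = c.default_panel()                      # 8 colorectal markers
cfg = c.PlasmaMixtureConfig(colon_fraction=0.05, n_molecules_per_marker=5000, seed=1)
reads, truth = c.simulate_sample_reads(panel, cfg)
quant, qc = c.quantify_sample(None, panel, reads=reads,
                              sample_id="S1", cfdna_ng_per_ml=20.0)
print(quant.to_frame().to_string(index=False))
print(f"combined c-cfDNA score: {quant.combined_score:.1f} copies/ml")
```

prints

```
sample_id     marker  total_molecules  unmethylated_molecules  fraction  copies_per_ml
       S1     FGFRL1             5000                     255   0.05100     309.060000
       S1       Col1             5000                     242   0.04840     293.304000
       S1       ECH1             5000                     221   0.04420     267.852000
       S1 cg10900049             5000                     214   0.04280     259.368000
       S1 cg23460250             5000                     219   0.04380     265.428000
       S1 cg12462916             5000                     259   0.05180     313.908000
       S1 cg09094964             4999                     246   0.04921     298.211642
       S1 cg15139063             5000                     226   0.04520     273.912000
combined c-cfDNA score: 285.1 copies/ml
```

A 5% colon spike into a 20 ng/ml sample is recovered marker by marker
(fractions ≈ 0.05, slightly attenuated by the default 99.5% conversion
efficiency) and combines to ≈ 0.05 × 20 × 303 ≈ 303 copies/ml.

On the cohort side:

```python
res = c.fisher_exact([[7, 0], [7, 10]])   # increase × relapse counts
print(f"Fisher p = {res.p_value:.4f}")    # -> Fisher p = 0.0188
```

i.e. the association between a week-2 c-cfDNA increase and later recurrence
(7/7 relapsers vs 7/17 non-relapsers with an increase) is significant at
p ≈ .019.

The whole chain runs from the shell, too:

```sh
ccfdna end-to-end --seed 7 --out-dir runs/demo
```

which simulates reads, quantifies them, simulates a 37-patient cohort,
runs the analyses, and writes a manifest making the run reproducible;
repeating the command with the same seed reproduces every file byte for
byte.

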