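# thermosleep

Analysis pipeline for paired two-night thermal-intervention sleep studies, in
which every subject sleeps one night on a cooling high-heat-capacity mattress
(condition `HM`) and one night on a regular mattress (condition `LM`), with
polysomnographic sleep staging and continuous temperature / heart-rate
recording over 450 min after lights-off.

The package covers the full chain from raw per-epoch inputs to the final
statistical results:

| module              | purpose |
| ------------------- | ------- |
| `synthetic_cohort`  | generates paired-night cohorts (hypnograms + CBT/PBT/MAT/HR series) with a configurable ~110-min NREM-REM cycle, night trends, conductive-cooling kinetics and between-subject heterogeneity of the cooling response |
| `preprocess`        | CSV readers, 10-min binning (45 bins, W+N1 pooled), sensor-averaged physiology, CBT−PBT gradient, nocturnal summaries, per-subject HM−LM deltas and night-part means (boundary 190 min) |
| `interval_stats`    | per-bin paired t tests with Benjamini-Hochberg FDR, cumulative-sum timecourses, paired Cohen's d, repeated-measures condition ANOVA with η², F/χ² tail probabilities, Pearson correlations and the night-part correlation table |
| `cycle_spectral`    | detrended periodogram over bins 1–44 (frequencies k/440 min⁻¹), group spectra with peak/period estimation, folding into 4 × 11-bin cycles |
| `cosinor`           | fixed-period cosinor fits, population-mean layer, Hotelling zero-amplitude rhythmicity test, wrapped acrophase differences |
| `mediation`         | single-mediator linear mediation (ACME/ADE/total) with percentile bootstrap CIs |
| `heterogeneity`     | median split by the gradient response, study-balance G-test, subgroup folded-cycle and cosinor analyses |
| `cli_report`        | one-config orchestration of the whole pipeline plus the `thermosleep` CLI |

## CLI

```sh
# write a synthetic cohort as CSV (hypnogram.csv, physio.csv, manifest.json)
thermosleep simulate --config cohort.yaml --out data/ --seed 1

# run every analysis stage; writes table1.csv, table2.csv, timecourses.csv,
# spectra.csv, peak.json, folded_cycles.csv, cosinor.json, mediation.json,
# heterogeneity.json, report.json and run.log
thermosleep analyze --config run.yaml --out results/ --seed 1

# simulate in memory and analyze in one step / print a finished report
thermosleep all --out results/ --seed 1
thermosleep report --out results/
```

The YAML config mirrors `cli_report.RunConfig`; every analysis constant
(190-min night-part boundary, FDR q = 0.05, data-derived vs fixed 110-min
folding period, 1000 bootstrap resamples, CI level) is a config key, and the
defaults reproduce the reference settings.  `mode: csv` with `hypnogram_csv`
and `physio_csv` paths analyzes externally supplied data in the same formats.

## Conventions

* Time is measured from lights-off; bins and epochs are 0-based and
  half-open (`bin b` covers minutes `[10b, 10(b+1))`).
* Stage minutes per bin always sum to 10 (W and N1 pooled).
* Δ quantities are HM − LM within subject; the night-part boundary bin
  (minutes 190–200) belongs to the second part.
* Phase differences are wrapped to (−55, +55] min at the 110-min period.
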