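# blastula

Multi-level statistical and biomechanical modelling of digital blastula-stage
embryo cohorts.

Starting from per-cell lineage tables (one row per cell per time step, with
filiation, positions, cell type, volume and surface), the package provides:

- **`blastula.lineage`** — lineage data model, tab-separated file I/O,
  structural validation, per-cell feature extraction (cycle length, division
  time, cycle-mean volume/surface, daughter/mother ratios), embryo-level
  N/W/Z curves and contact degrees.
- **`blastula.synthetic`** — synthetic digital-embryo cohorts with known
  group laws, per-embryo time/space distortions and observation windows;
  ground truth saved for recovery tests.
- **`blastula.rescaling`** — per-embryo affine temporal and linear spatial
  rescaling onto the cohort baseline, fitted on the cell-number and
  total-volume curves.
- **`blastula.group_stats`** — per-(generation, type) feature distributions:
  normal / log-normal fits, chi-square goodness of fit, mother-daughter and
  sister-sister independence reports.
- **`blastula.model`** — recursive probabilistic model across generations
  (division times add, volumes/surfaces multiply), closed-form propagation,
  Kullback-Leibler model evaluation, and the cohort prototype as the KL
  centroid of the member laws.
- **`blastula.simulator`** — stochastic artificial cell lineages from a group
  model (32-cell start: 16 Mes, 8 Mac, 4 LMic, 4 SMic), ensemble summaries
  (mean/sd of N, W, Z over seeded realisations) and comparison with measured
  curves.
- **`blastula.mechanics`** — spatial embedding as overdamped particle
  dynamics: attraction-repulsion pair forces with homotypic/heterotypic
  adhesion, planarity-conservation forces, turgor pressure, and tangential
  oriented divisions.
- **`blastula.sweep`** — objective functions (sphericity, planarity, border
  similarity) and the 2-D sweep over the adhesion-coefficient plane with
  phase labels and a best-fit mask.

## CLI

```sh
blastula synth --seed 7 -o cohort/                 # synthetic cohort + ground truth
blastula io validate cohort/embryo_0.tsv
blastula features cohort/embryo_0.tsv -o features.tsv
blastula curves cohort/embryo_0.tsv -o curves.tsv
blastula rescale cohort/ -o rescaled/ --report rescale.tsv
blastula stats rescaled/ -o stats.tsv --independence indep.tsv \
    --per-embryo-dir stats_dir/
blastula model evaluate stats_dir/ -o eval.tsv
blastula model prototype stats_dir/ -o prototype.yaml
blastula simulate prototype.yaml --n 300 --seed 1 -o ensemble.tsv
blastula embed prototype.yaml --seed 3 -o run_dir/
blastula sweep --lineage prototype.yaml --replicates 3 --seed 11 -o sweep_dir/
```

## Lineage file format

Tab-separated with header
`cell_id  mother_id  t  x  y  z  type  volume  surface`; one row per
(cell, time step); `mother_id` empty for first-frame cells; division encoded
by two cells sharing a mother and starting strictly after her last frame.
Optional directives: `# time_unit: min|hpf` and
`# roots_born_at_start: true` (first-frame cells born exactly at window
start, as in synthetic data).
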