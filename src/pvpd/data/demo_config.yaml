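# Demo end-to-end run: synthetic study-condition data, shipped termset
# and pharmacology tables. Load with pvpd.pipeline.load_run_config or
# `pvpd run --config <this file>`.
seed: 0
drugs:
  - aripiprazole
  - asenapine
  - brexpiprazole
  - cariprazine
  - clozapine
  - iloperidone
  - lurasidone
  - olanzapine
  - paliperidone
  - quetiapine
  - risperidone
  - ziprasidone
generator:
  study_defaults: true
  n_reports: 150000
  surge: true
exclude_drugs:
  - iloperidone
median_over: included
out_dir: results/demo_run
make_figures: true
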