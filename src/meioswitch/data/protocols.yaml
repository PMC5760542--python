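fig2a:
  genotype: wild type
  horizon: 700.0
  model: meiosis
  observables:
  - ste11_t
  - phes
  - mat1pm
  - mei3_t
  - mei2
  - pat1_active
  schedule:
  - phes_enabled: true
    pka: 1.0
    t: 0.0
    tor2: 1.0
  - phes_enabled: true
    pka: 0.75
    t: 50.0
    tor2: 0.0
fig2b:
  genotype: mei3D
  horizon: 700.0
  model: meiosis
  observables:
  - ste11_t
  - phes
  - mat1pm
  - mei3_t
  - mei2
  - pat1_active
  schedule:
  - phes_enabled: true
    pka: 1.0
    t: 0.0
    tor2: 1.0
  - phes_enabled: true
    pka: 0.75
    t: 50.0
    tor2: 0.0
fig2c:
  genotype: pat1-114 (34C)
  horizon: 700.0
  model: meiosis
  observables:
  - ste11_t
  - phes
  - mat1pm
  - mei3_t
  - mei2
  - pat1_active
  schedule:
  - phes_enabled: true
    pka: 1.0
    t: 0.0
    tor2: 1.0
fig2d:
  genotype: pat1-114 (30C)
  horizon: 700.0
  model: meiosis
  observables:
  - ste11_t
  - phes
  - mat1pm
  - mei3_t
  - mei2
  - pat1_active
  schedule:
  - phes_enabled: true
    pka: 1.0
    t: 0.0
    tor2: 1.0
fig4a:
  genotype: wild type
  horizon: 800.0
  model: meiosis
  observables:
  - ste11_t
  - phes
  - mat1pm
  - mei3_t
  - mei2
  - pat1_active
  schedule:
  - phes_enabled: true
    pka: 0.75
    t: 0.0
    tor2: 0.0
  - phes_enabled: false
    pka: 1.0
    t: 135.0
    tor2: 1.0
fig4b:
  genotype: wild type
  horizon: 800.0
  model: meiosis
  observables:
  - ste11_t
  - phes
  - mat1pm
  - mei3_t
  - mei2
  - pat1_active
  schedule:
  - phes_enabled: true
    pka: 0.75
    t: 0.0
    tor2: 0.0
  - phes_enabled: false
    pka: 1.0
    t: 150.0
    tor2: 1.0
fig5a:
  genotype: wild type
  horizon: 400.0
  model: integrated
  observables:
  - mpf
  - rum1
  - mass
  - ste11_t
  - phes
  - mei2
  - pat1_active
  schedule:
  - phes_enabled: true
    pka: 1.0
    t: 0.0
    tor2: 1.0
fig5b:
  genotype: ste11-T82A
  horizon: 400.0
  model: integrated
  observables:
  - mpf
  - rum1
  - mass
  - ste11_t
  - phes
  - mei2
  - pat1_active
  schedule:
  - phes_enabled: true
    pka: 1.0
    t: 0.0
    tor2: 1.0
fig6a:
  genotype: wild type
  horizon: 900.0
  model: integrated
  observables:
  - mpf
  - rum1
  - mass
  - ste11_t
  - phes
  - mei2
  - pat1_active
  schedule:
  - phes_enabled: true
    pka: 1.0
    t: 0.0
    tor2: 1.0
  - phes_enabled: true
    pka: 0.75
    t: 150.0
    tor2: 0.0
fig6b:
  genotype: wild type
  horizon: 900.0
  model: integrated
  observables:
  - mpf
  - rum1
  - mass
  - ste11_t
  - phes
  - mei2
  - pat1_active
  schedule:
  - phes_enabled: true
    pka: 1.0
    t: 0.0
    tor2: 1.0
  - phes_enabled: true
    pka: 0.75
    t: 135.0
    tor2: 0.0
fig7a:
  condition: rich
  kind: cellmass_diagram
  mass_range:
  - 0.25
  - 3.2
  phes: 0.0
fig7b_green:
  condition: starved
  kind: cellmass_diagram
  mass_range:
  - 0.25
  - 3.2
  phes: 2.0
fig7b_red:
  condition: starved
  kind: cellmass_diagram
  mass_range:
  - 0.25
  - 3.2
  phes: 0.0
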