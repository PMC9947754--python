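# Example run configuration for `geoprobit run-all --config examples/config.yml`.
# Generate the inputs first:
#   geoprobit simulate --scenario full_geoadditive --seed 1 --outdir sim/
data: sim/data.csv
graph: sim/map.gra
outdir: out/
schema:
  region: region
  y1: stunted
  y2: wasted
  categorical:
    wealth: poorest
    mother_edu: none
    mother_bmi: normal
    toilet: unimproved
  continuous: [child_age_months, mother_age_years]
alpha: 0.05
screen: true
smooth: [child_age_months, mother_age_years]
spatial: true
sampler:
  iterations: 12000
  burnin: 2000
  thin: 10
  seed: 1
  ig_a: 0.001
  ig_b: 0.001
plots: true
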