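# Five-configuration crossover-redistribution experiment on a 100 Mb
# chromosome with a 10 Mb measured interval at [45, 55] Mb.
seed: 1
stages: [simulate, compare]
simulate:
  chrom_length: 100000000
  uniform_rate: 1.5            # cM/Mb
  interval: [45000000, 55000000]
  design: backcross
  plants_per_config: 12
  progeny_per_plant: 400
  model:
    strength: 2.0              # max multiplicative stimulation at a boundary
    decay_cm: 20.0             # exponential decay scale (genetic distance)
    activity_threshold: 0.5    # cM/Mb below which HOM windows cannot donate
    conserve: true
  # configurations default to inbred / hybrid / juxtaposed /
  # reverse_juxtaposed / interrupted_juxtaposed when omitted
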