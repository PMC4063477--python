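# Per-species thermal performance curves for foraging propensity.
# Synthetic Gaussian stand-ins (relative propensity = exp(-0.5((T-t_opt)/width)^2))
# for unpublished per-species foraging--temperature data; parameters were
# chosen to reproduce the qualitative warming behaviors reported for the
# community (cool-weather P. imparis shifts its spring activity earlier
# under warming, heat-susceptible A. rudis loses summer foraging, broadly
# warm-tolerant N. faisonensis loses intensity without a timing shift).
# Fully user-replaceable.
n_faisonensis:
  t_opt: 25.0
  width: 8.0
a_rudis:
  t_opt: 22.0
  width: 6.0
p_imparis:
  t_opt: 10.0
  width: 7.0
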