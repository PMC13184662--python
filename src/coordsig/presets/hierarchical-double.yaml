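# Hierarchical double embedding: Girshites are a zealous sect of the
# Lagashites, who are in turn Sumerian.  Girshites prefer Girsu > Lagash >
# generic Sumerian > Akkadian greetings; Lagashites prefer Lagash > Sumerian
# > Akkadian; generic Sumerians value only the Sumerian and (grudgingly)
# Akkadian greetings.  Akkadians are 55% of the population.  One real signal
# in each of three dimensions gives three degrees of identity specificity.
name: hierarchical-double
family: hierarchical-double
actions: [sumerian, lagash, girsu, akkad]
signal_alphabet: [1, 1, 1]
signal_cost: 0.02
free_parameters:
  V: 4.0
types:
  - label: Sumerian
    proportion: 0.15
    payoffs: [V, 0, 0, 1]
  - label: Lagashite
    proportion: 0.15
    payoffs: [2, V, 0, 1]
  - label: Girshite
    proportion: 0.15
    payoffs: [2, 3, V, 1]
  - label: Akkadian
    proportion: 0.55
    payoffs: [0, 0, 0, V]
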