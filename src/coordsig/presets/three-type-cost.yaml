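# Three-type scenario with attention costs.  Akkadians (one third of the
# population) benefit only from their own greeting; the two Sumerian types
# earn V for their preferred greeting, 1 for the other Sumerian greeting and
# a smaller tolerance payoff w for the Akkadian greeting.  Ummians make up a
# share d of the Sumerian remainder.  One signalling dimension, two real
# signals, attention cost c per attended dimension.
name: three-type-cost
family: three-type-cost
actions: [umma, kish, akkad]
signal_alphabet: [2]
signal_cost: 0.02
free_parameters:
  V: 2.0
  d: 0.5
  w: 0.5
  a: 0.3333333333333333
types:
  - label: Ummian
    proportion: d * (1 - a)
    payoffs: [V, 1, w]
  - label: Kishu
    proportion: (1 - d) * (1 - a)
    payoffs: [1, V, w]
  - label: Akkadian
    proportion: a
    payoffs: [0, 0, V]
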