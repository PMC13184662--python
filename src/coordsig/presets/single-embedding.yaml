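# Single embedding: Girshites are a zealous subgroup of the Lagashites.
# Girshites most prefer the Girsu greeting, then the Lagash greeting, and
# grudgingly accept the Akkadian greeting; Lagashites value only the Lagash
# and (grudgingly) Akkadian greetings; Akkadians only their own.  Default is
# two signalling dimensions with one real signal each; override
# signal_alphabet to [2] for the one-dimension comparison.
name: single-embedding
family: single-embedding
actions: [girsu, lagash, akkad]
signal_alphabet: [1, 1]
signal_cost: 0.02
free_parameters:
  V: 4.0
types:
  - label: Girshite
    proportion: 0.2
    payoffs: [V, 2, 1]
  - label: Lagashite
    proportion: 0.4
    payoffs: [0, V, 1]
  - label: Akkadian
    proportion: 0.4
    payoffs: [0, 0, V]
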