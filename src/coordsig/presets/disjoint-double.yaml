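# Disjoint double embedding: Ummians and Lagashites are both Sumerian and
# prefer a generic Sumerian greeting over the Akkadian one, but get nothing
# from each other's city greeting.  Akkadians are 55% of the population.
# Agents have one real signal in the first dimension (the shared Sumerian
# marker) and two in the second (the city markers).
name: disjoint-double
family: disjoint-double
actions: [sumerian, umma, lagash, akkad]
signal_alphabet: [1, 2]
signal_cost: 0.02
free_parameters:
  V: 4.0
types:
  - label: Sumerian
    proportion: 0.15
    payoffs: [V, 0, 0, 1]
  - label: Ummian
    proportion: 0.15
    payoffs: [2, V, 0, 1]
  - label: Lagashite
    proportion: 0.15
    payoffs: [2, 0, V, 1]
  - label: Akkadian
    proportion: 0.55
    payoffs: [0, 0, 0, V]
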