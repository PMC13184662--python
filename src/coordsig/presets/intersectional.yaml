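# Intersectional scenario: Ummians and Lagashites hate each other's greeting;
# Kishus are happy with either (payoff kp, above the Akkadian-greeting
# tolerance but below the parents' own preference) and, in the intersectional
# variant, prefer a distinct Kish greeting above all (VK = V).  Setting
# VK = 0 gives the mere-conjunction variant in which Kishus have no distinct
# greeting.  Kishus are a share r of the population, Ummians and Lagashites
# each (0.6 - r)/2, Akkadians the remaining 40%.  Two signalling dimensions
# with one real signal each.
name: intersectional
family: intersectional
actions: [umma, lagash, kish, akkad]
signal_alphabet: [1, 1]
signal_cost: 0.02
free_parameters:
  V: 4.0
  VK: 4.0
  r: 0.2
  kp: 2.0
types:
  - label: Ummian
    proportion: (0.6 - r) / 2
    payoffs: [V, 0, 0, 1]
  - label: Lagashite
    proportion: (0.6 - r) / 2
    payoffs: [0, V, 0, 1]
  - label: Kishu
    proportion: r
    payoffs: [kp, kp, VK, 1]
  - label: Akkadian
    proportion: 0.4
    payoffs: [0, 0, 0, V]
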