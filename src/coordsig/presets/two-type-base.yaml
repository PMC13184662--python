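# Baseline two-type scenario: Ummians (majority share d) and Kishus.
# Each type earns V for coordinating on its preferred greeting, 1 for the
# non-preferred greeting, 0 for miscoordination.  One signalling dimension
# with two real signals and the null signal; set signal_alphabet to [] for
# the signal-free baseline game.  Signalling is costless here.
name: two-type-base
family: two-type-base
actions: [umma, kish]
signal_alphabet: [2]
signal_cost: 0.0
free_parameters:
  V: 2.0
  d: 0.5
types:
  - label: Ummian
    proportion: d
    payoffs: [V, 1]
  - label: Kishu
    proportion: 1 - d
    payoffs: [1, V]
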