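# Default evolutionary regimes for the synthetic family generator.
#
# Disordered segments are enriched in polar/charged/small residues
# (P, E, S, Q, K, R, G, A, D, N) and substitute fast; ordered segments are
# enriched in bulky hydrophobics (W, C, F, I, Y, V, L, M) and substitute
# slowly. subs_rate is expected substitutions per site per branch of the
# star phylogeny.
disordered:
  subs_rate: 0.5
  composition:
    P: 0.075
    E: 0.075
    S: 0.075
    Q: 0.075
    K: 0.075
    R: 0.075
    G: 0.075
    A: 0.075
    D: 0.075
    N: 0.075
    W: 0.025
    C: 0.025
    F: 0.025
    I: 0.025
    Y: 0.025
    V: 0.025
    L: 0.025
    M: 0.025
    H: 0.025
    T: 0.025
ordered:
  subs_rate: 0.1
  composition:
    W: 0.075
    C: 0.075
    F: 0.075
    I: 0.075
    Y: 0.075
    V: 0.075
    L: 0.075
    M: 0.075
    P: 0.033333333333333333
    E: 0.033333333333333333
    S: 0.033333333333333333
    Q: 0.033333333333333333
    K: 0.033333333333333333
    R: 0.033333333333333333
    G: 0.033333333333333333
    A: 0.033333333333333333
    D: 0.033333333333333333
    N: 0.033333333333333333
    H: 0.033333333333333333
    T: 0.033333333333333334
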