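provenance: 'SYNTHETIC reconstruction of the flank-effect classification and combination
  rules from published arrest-peptide hierarchies: strong triplets PPP, D/PP/D, PPW,
  APP, G/PP/G, PPN; weak L/PP/L, CPP, HPP; X(-2) in {H,K,Q,R,W} pronounces and in
  {C,G,L,S,T} attenuates the arrest; all other contexts default to weak arrest. Not
  a transcription of any single published dataset.'
flank_effect:
  x_m2:
    A: MEDIUM_EFF
    C: WEAK_EFF
    D: MEDIUM_EFF
    E: MEDIUM_EFF
    F: MEDIUM_EFF
    G: WEAK_EFF
    H: STRONG_EFF
    I: MEDIUM_EFF
    K: STRONG_EFF
    L: WEAK_EFF
    M: MEDIUM_EFF
    N: MEDIUM_EFF
    P: MEDIUM_EFF
    Q: STRONG_EFF
    R: STRONG_EFF
    S: WEAK_EFF
    T: WEAK_EFF
    V: MEDIUM_EFF
    W: STRONG_EFF
    Y: MEDIUM_EFF
  x_m1:
    A: STRONG_EFF
    C: WEAK_EFF
    D: STRONG_EFF
    E: MEDIUM_EFF
    F: WEAK_EFF
    G: STRONG_EFF
    H: WEAK_EFF
    I: WEAK_EFF
    K: WEAK_EFF
    L: WEAK_EFF
    M: WEAK_EFF
    N: MEDIUM_EFF
    P: STRONG_EFF
    Q: MEDIUM_EFF
    R: WEAK_EFF
    S: MEDIUM_EFF
    T: MEDIUM_EFF
    V: WEAK_EFF
    W: WEAK_EFF
    Y: WEAK_EFF
  x_p1:
    A: MEDIUM_EFF
    C: WEAK_EFF
    D: STRONG_EFF
    E: MEDIUM_EFF
    F: WEAK_EFF
    G: STRONG_EFF
    H: WEAK_EFF
    I: WEAK_EFF
    K: MEDIUM_EFF
    L: WEAK_EFF
    M: WEAK_EFF
    N: STRONG_EFF
    P: STRONG_EFF
    Q: WEAK_EFF
    R: WEAK_EFF
    S: MEDIUM_EFF
    T: WEAK_EFF
    V: WEAK_EFF
    W: STRONG_EFF
    Y: WEAK_EFF
combination_rules:
- n: '2'
  x_m2: WEAK_EFF
  x_m1: WEAK_EFF
  x_p1: WEAK_EFF
  strength: WEAK
- n: '2'
  x_m2: WEAK_EFF
  x_m1: WEAK_EFF
  x_p1: MEDIUM_EFF
  strength: WEAK
- n: '2'
  x_m2: WEAK_EFF
  x_m1: WEAK_EFF
  x_p1: STRONG_EFF
  strength: MEDIUM
- n: '2'
  x_m2: WEAK_EFF
  x_m1: MEDIUM_EFF
  x_p1: WEAK_EFF
  strength: WEAK
- n: '2'
  x_m2: WEAK_EFF
  x_m1: MEDIUM_EFF
  x_p1: MEDIUM_EFF
  strength: WEAK
- n: '2'
  x_m2: WEAK_EFF
  x_m1: MEDIUM_EFF
  x_p1: STRONG_EFF
  strength: MEDIUM
- n: '2'
  x_m2: WEAK_EFF
  x_m1: STRONG_EFF
  x_p1: WEAK_EFF
  strength: MEDIUM
- n: '2'
  x_m2: WEAK_EFF
  x_m1: STRONG_EFF
  x_p1: MEDIUM_EFF
  strength: MEDIUM
- n: '2'
  x_m2: WEAK_EFF
  x_m1: STRONG_EFF
  x_p1: STRONG_EFF
  strength: MEDIUM
- n: '2'
  x_m2: MEDIUM_EFF
  x_m1: WEAK_EFF
  x_p1: WEAK_EFF
  strength: WEAK
- n: '2'
  x_m2: MEDIUM_EFF
  x_m1: WEAK_EFF
  x_p1: MEDIUM_EFF
  strength: MEDIUM
- n: '2'
  x_m2: MEDIUM_EFF
  x_m1: WEAK_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: '2'
  x_m2: MEDIUM_EFF
  x_m1: MEDIUM_EFF
  x_p1: WEAK_EFF
  strength: MEDIUM
- n: '2'
  x_m2: MEDIUM_EFF
  x_m1: MEDIUM_EFF
  x_p1: MEDIUM_EFF
  strength: MEDIUM
- n: '2'
  x_m2: MEDIUM_EFF
  x_m1: MEDIUM_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: '2'
  x_m2: MEDIUM_EFF
  x_m1: STRONG_EFF
  x_p1: WEAK_EFF
  strength: STRONG
- n: '2'
  x_m2: MEDIUM_EFF
  x_m1: STRONG_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: '2'
  x_m2: MEDIUM_EFF
  x_m1: STRONG_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: '2'
  x_m2: STRONG_EFF
  x_m1: WEAK_EFF
  x_p1: WEAK_EFF
  strength: MEDIUM
- n: '2'
  x_m2: STRONG_EFF
  x_m1: WEAK_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: '2'
  x_m2: STRONG_EFF
  x_m1: WEAK_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: '2'
  x_m2: STRONG_EFF
  x_m1: MEDIUM_EFF
  x_p1: WEAK_EFF
  strength: STRONG
- n: '2'
  x_m2: STRONG_EFF
  x_m1: MEDIUM_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: '2'
  x_m2: STRONG_EFF
  x_m1: MEDIUM_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: '2'
  x_m2: STRONG_EFF
  x_m1: STRONG_EFF
  x_p1: WEAK_EFF
  strength: STRONG
- n: '2'
  x_m2: STRONG_EFF
  x_m1: STRONG_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: '2'
  x_m2: STRONG_EFF
  x_m1: STRONG_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: 3+
  x_m2: WEAK_EFF
  x_m1: WEAK_EFF
  x_p1: WEAK_EFF
  strength: STRONG
- n: 3+
  x_m2: WEAK_EFF
  x_m1: WEAK_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: 3+
  x_m2: WEAK_EFF
  x_m1: WEAK_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: 3+
  x_m2: WEAK_EFF
  x_m1: MEDIUM_EFF
  x_p1: WEAK_EFF
  strength: STRONG
- n: 3+
  x_m2: WEAK_EFF
  x_m1: MEDIUM_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: 3+
  x_m2: WEAK_EFF
  x_m1: MEDIUM_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: 3+
  x_m2: WEAK_EFF
  x_m1: STRONG_EFF
  x_p1: WEAK_EFF
  strength: STRONG
- n: 3+
  x_m2: WEAK_EFF
  x_m1: STRONG_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: 3+
  x_m2: WEAK_EFF
  x_m1: STRONG_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: 3+
  x_m2: MEDIUM_EFF
  x_m1: WEAK_EFF
  x_p1: WEAK_EFF
  strength: STRONG
- n: 3+
  x_m2: MEDIUM_EFF
  x_m1: WEAK_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: 3+
  x_m2: MEDIUM_EFF
  x_m1: WEAK_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: 3+
  x_m2: MEDIUM_EFF
  x_m1: MEDIUM_EFF
  x_p1: WEAK_EFF
  strength: STRONG
- n: 3+
  x_m2: MEDIUM_EFF
  x_m1: MEDIUM_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: 3+
  x_m2: MEDIUM_EFF
  x_m1: MEDIUM_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: 3+
  x_m2: MEDIUM_EFF
  x_m1: STRONG_EFF
  x_p1: WEAK_EFF
  strength: STRONG
- n: 3+
  x_m2: MEDIUM_EFF
  x_m1: STRONG_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: 3+
  x_m2: MEDIUM_EFF
  x_m1: STRONG_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: 3+
  x_m2: STRONG_EFF
  x_m1: WEAK_EFF
  x_p1: WEAK_EFF
  strength: STRONG
- n: 3+
  x_m2: STRONG_EFF
  x_m1: WEAK_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: 3+
  x_m2: STRONG_EFF
  x_m1: WEAK_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: 3+
  x_m2: STRONG_EFF
  x_m1: MEDIUM_EFF
  x_p1: WEAK_EFF
  strength: STRONG
- n: 3+
  x_m2: STRONG_EFF
  x_m1: MEDIUM_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: 3+
  x_m2: STRONG_EFF
  x_m1: MEDIUM_EFF
  x_p1: STRONG_EFF
  strength: STRONG
- n: 3+
  x_m2: STRONG_EFF
  x_m1: STRONG_EFF
  x_p1: WEAK_EFF
  strength: STRONG
- n: 3+
  x_m2: STRONG_EFF
  x_m1: STRONG_EFF
  x_p1: MEDIUM_EFF
  strength: STRONG
- n: 3+
  x_m2: STRONG_EFF
  x_m1: STRONG_EFF
  x_p1: STRONG_EFF
  strength: STRONG
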