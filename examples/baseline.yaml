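network:
  shared_resistances:
    R0: 1.0
    R1: 1.0
    R2: 2.0
    R3: 1.0
  topology:
    n1:
      resistance: R0
      children:
      - A
      - n2
    n2:
      resistance: R1
      children:
      - B
      - n3
    n3:
      resistance: R2
      children:
      - C
      - n4
    n4:
      resistance: R3
      children:
      - D
      - E
  compartments:
    A:
      R: 1.0
      C: 0.08
      V_rest: 1.0
    B:
      R: 15.0
      C: 0.06
      V_rest: 1.0
    C:
      R: 11.0
      C: 0.05
      V_rest: 1.0
    D:
      R: 15.0
      C: 0.02
      V_rest: 1.0
    E:
      R: 7.0
      C: 0.02
      V_rest: 1.0
ventilator:
  mode: CF
  peep: 2.0
  ti: 1.0
  ttot: 3.0
  q_aw: 1.7
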