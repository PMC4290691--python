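# 30-node ER-Golgi stress network.
#
# Reconstruction notes (changelog):
#   - ATF6f uses the joint_min rule: it requires BOTH its precursor ATF6
#     and the Golgi proteases S1/2P.
#   - basal production on IKK, IkB and NFkB plus the canonical
#     IKK -> NFkB activation close the IKK -| IkB -| NFkB -> A20 -| IKK
#     negative feedback into a self-contained oscillator that saturates
#     (NFkB locked at 2) under full IRE1 stress.
#   - eIF2a -> BACE1 lets sustained PERK stress drive amyloid production.
#   - JNK -> P53 makes full P53 induction reachable from IRE1 alone.
#   - GADD34 -| ATF4 closes the translational-recovery negative
#     feedback loop responsible for the ATF4/GADD34 oscillation.
name: er_golgi
nodes:
  - {name: ATF6, kind: input, levels: 3}
  - {name: PERK, kind: input, levels: 3}
  - {name: IRE1, kind: input, levels: 3}
  - {name: S1_2P, kind: input, levels: 3}
  - {name: ATF6f, kind: internal, levels: 3, rule: joint_min}
  - {name: XBP1, kind: internal, levels: 3}
  - {name: cMYC, kind: internal, levels: 3}
  - {name: Bcl2, kind: internal, levels: 3}
  - {name: Survival, kind: internal, levels: 3}
  - {name: eIF2a, kind: internal, levels: 3}
  - {name: ATF4, kind: internal, levels: 3}
  - {name: CHOP, kind: internal, levels: 3}
  - {name: GADD34, kind: internal, levels: 3}
  - {name: P53, kind: internal, levels: 3}
  - {name: TRAF2, kind: internal, levels: 3}
  - {name: ASK1, kind: internal, levels: 3}
  - {name: JNK, kind: internal, levels: 3}
  - {name: BACE1, kind: internal, levels: 3}
  - {name: Abeta, kind: internal, levels: 3}
  - {name: IKK, kind: internal, levels: 3, basal: 2}
  - {name: IkB, kind: internal, levels: 3, basal: 2}
  - {name: NFkB, kind: internal, levels: 3, basal: 2}
  - {name: CyclinD, kind: internal, levels: 3}
  - {name: A20, kind: internal, levels: 3}
  - {name: BAX, kind: internal, levels: 3}
  - {name: Cytoc, kind: internal, levels: 3}
  - {name: Caspase9, kind: internal, levels: 3}
  - {name: Cancer, kind: output, levels: 2}
  - {name: Apoptosis, kind: output, levels: 2}
  - {name: Alzheimer, kind: output, levels: 2}
edges:
  # ATF6 arm: ATF6 + S1/2P -> ATF6f -> XBP1 -> {cMYC, Bcl2} -> Survival
  - {from: ATF6, to: ATF6f, sign: "+"}
  - {from: S1_2P, to: ATF6f, sign: "+"}
  - {from: ATF6f, to: XBP1, sign: "+"}
  - {from: XBP1, to: cMYC, sign: "+"}
  - {from: XBP1, to: Bcl2, sign: "+"}
  - {from: cMYC, to: Survival, sign: "+"}
  - {from: Bcl2, to: Survival, sign: "+"}
  # PERK arm: PERK -> eIF2a -> ATF4 -> CHOP -> GADD34 -> P53
  - {from: PERK, to: eIF2a, sign: "+"}
  - {from: GADD34, to: ATF4, sign: "-"}
  - {from: eIF2a, to: ATF4, sign: "+"}
  - {from: ATF4, to: CHOP, sign: "+"}
  - {from: NFkB, to: CHOP, sign: "-"}
  - {from: CHOP, to: GADD34, sign: "+"}
  - {from: GADD34, to: P53, sign: "+"}
  - {from: JNK, to: P53, sign: "+"}
  # IRE1 arm A: IRE1 -> TRAF2 -> ASK1 -> JNK -> BACE1 -> Abeta
  - {from: IRE1, to: TRAF2, sign: "+"}
  - {from: TRAF2, to: ASK1, sign: "+"}
  - {from: ASK1, to: JNK, sign: "+"}
  - {from: JNK, to: BACE1, sign: "+"}
  - {from: eIF2a, to: BACE1, sign: "+"}
  - {from: NFkB, to: BACE1, sign: "+"}
  - {from: BACE1, to: Abeta, sign: "+"}
  # IRE1 arm B: TRAF2 -> IKK -| IkB -| NFkB -> {CyclinD, BACE1, A20}
  - {from: TRAF2, to: IKK, sign: "+"}
  - {from: A20, to: IKK, sign: "-"}
  - {from: IKK, to: IkB, sign: "-"}
  - {from: IkB, to: NFkB, sign: "-"}
  - {from: IKK, to: NFkB, sign: "+"}
  - {from: NFkB, to: CyclinD, sign: "+"}
  - {from: NFkB, to: A20, sign: "+"}
  # IRE1 arm C: JNK -> BAX -> Cytoc -> Caspase9
  - {from: JNK, to: BAX, sign: "+"}
  - {from: BAX, to: Cytoc, sign: "+"}
  - {from: Cytoc, to: Caspase9, sign: "+"}
  # cell fates
  - {from: Survival, to: Cancer, sign: "+"}
  - {from: CyclinD, to: Cancer, sign: "+"}
  - {from: P53, to: Apoptosis, sign: "+"}
  - {from: Caspase9, to: Apoptosis, sign: "+"}
  - {from: Survival, to: Apoptosis, sign: "-"}
  - {from: Abeta, to: Alzheimer, sign: "+"}
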