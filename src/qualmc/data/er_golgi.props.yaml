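# CTL property suite with expected verdicts (sync; async with fairness).
# Scenario blocks fix input-node initial values; unmentioned inputs stay
# free over their full domain.
- id: P1
  formula: "IRE1 = 2 -> AF (Abeta >= 1 & Alzheimer = True)"
  expect_sync: true
  expect_async: true
- id: P2
  formula: "PERK = 2 -> AF (Abeta >= 1 & Alzheimer = True)"
  expect_sync: true
  expect_async: true
- id: P3j1
  formula: "IRE1 = 1 -> AF (Caspase9 >= 1 & Apoptosis = True)"
  expect_sync: false
  expect_async: false
- id: P3j2
  formula: "IRE1 = 2 -> AF (Caspase9 >= 1 & Apoptosis = True)"
  expect_sync: true
  expect_async: true
- id: P4
  formula: "IRE1 = 2 -> AF (Abeta >= 1 & Alzheimer = True & Caspase9 >= 1 & Apoptosis = True)"
  expect_sync: true
  expect_async: true
- id: P5
  tier: calibration
  formula: "AG (TRAF2 = 2 -> AF (Abeta >= 1 & Alzheimer = True))"
  expect_sync: true
  expect_async: false
- id: P5p
  formula: "AG (TRAF2 = 2 -> EF (Abeta >= 1 & Alzheimer = True))"
  expect_sync: true
  expect_async: true
- id: P6
  formula: "AG (NFkB = 2 -> AF (Abeta >= 1 & Alzheimer = True))"
  expect_sync: true
  expect_async: false
- id: P6p
  formula: "AG (NFkB = 2 -> EF (Abeta >= 1 & Alzheimer = True))"
  expect_sync: true
  expect_async: true
- id: P7
  tier: calibration
  formula: "AG (ASK1 = 2 -> AF (Abeta >= 1 & Alzheimer = True))"
  expect_sync: true
  expect_async: false
- id: P7p
  formula: "AG (ASK1 = 2 -> EF (Abeta >= 1 & Alzheimer = True))"
  expect_sync: true
  expect_async: true
- id: P8
  formula: "ATF6 >= 1 -> AF (cMYC >= 1 & Cancer = True & Apoptosis = False)"
  expect_sync: false
  expect_async: false
- id: P9
  tier: calibration
  formula: "(ATF6 >= 1 & S1_2P >= 1) -> AF (cMYC >= 1 & Cancer = True & Apoptosis = False)"
  scenario: {fix: {IRE1: 0}}
  expect_sync: true
  expect_async: false
- id: P9p
  formula: "(ATF6 >= 1 & S1_2P >= 1) -> EF (cMYC >= 1 & Cancer = True & Apoptosis = False)"
  scenario: {fix: {IRE1: 0}}
  expect_sync: true
  expect_async: true
- id: P10
  formula: "IRE1 = 2 -> AF (CyclinD = 2 & Cancer = True & P53 = 2 & Apoptosis = True)"
  expect_sync: true
  expect_async: true
- id: P11
  formula: "AG (IKK = 2 -> AF (P53 = 0 & Cancer = True))"
  scenario: {fix: {PERK: 0, IRE1: 0}}
  expect_sync: true
  expect_async: false
- id: P11p
  formula: "AG (IKK = 2 -> EF (P53 = 0 & Cancer = True))"
  scenario: {fix: {PERK: 0, IRE1: 0}}
  expect_sync: true
  expect_async: true
- id: P12
  formula: "AG (NFkB = 2 -> AF (P53 = 0 & Cancer = True))"
  scenario: {fix: {PERK: 0, IRE1: 0}}
  expect_sync: true
  expect_async: false
- id: P12p
  formula: "AG (NFkB = 2 -> EF (P53 = 0 & Cancer = True))"
  scenario: {fix: {PERK: 0, IRE1: 0}}
  expect_sync: true
  expect_async: true
- id: P13
  formula: "AG (ATF4 = 2 -> AF (P53 >= 1 & Apoptosis = True & Cancer = False))"
  scenario: {fix: {ATF6: 0, S1_2P: 0, IRE1: 0}}
  expect_sync: true
  expect_async: false
- id: P13p
  formula: "AG (ATF4 = 2 -> EF (P53 >= 1 & Apoptosis = True & Cancer = False))"
  scenario: {fix: {ATF6: 0, S1_2P: 0, IRE1: 0}}
  expect_sync: true
  expect_async: true
- id: P14
  formula: "AG (NFkB = 2 -> AF (P53 = 0 & Cancer = True & Abeta >= 1 & Alzheimer = True))"
  scenario: {fix: {PERK: 0, IRE1: 0}}
  expect_sync: true
  expect_async: false
- id: P15
  formula: "PERK >= 1 -> AG ((NFkB >= 1 -> AF (NFkB = 0)) & (NFkB = 0 -> AF (NFkB >= 1)))"
  scenario: {fix: {IRE1: 0}}
  expect_sync: true
  expect_async: false
- id: P15p
  formula: "PERK >= 1 -> AG ((NFkB >= 1 -> EF (NFkB = 0)) & (NFkB = 0 -> EF (NFkB >= 1)))"
  scenario: {fix: {IRE1: 0}}
  expect_sync: true
  expect_async: true
- id: P16
  formula: "PERK >= 1 -> AG ((NFkB >= 1 -> AF (A20 >= 1)) & (A20 >= 1 -> AF (NFkB = 0)))"
  scenario: {fix: {IRE1: 0}}
  expect_sync: true
  expect_async: false
- id: P16p
  formula: "PERK >= 1 -> AG ((NFkB >= 1 -> EF (A20 >= 1)) & (A20 >= 1 -> EF (NFkB = 0)))"
  scenario: {fix: {IRE1: 0}}
  expect_sync: true
  expect_async: true
- id: P17
  formula: "AG ((NFkB >= 1 -> AF (NFkB = 0)) & (NFkB = 0 -> AF (NFkB >= 1)))"
  scenario: {fix: {ATF6: 0, PERK: 0, IRE1: 0, S1_2P: 0}}
  expect_sync: true
  expect_async: false
- id: P17p
  formula: "AG ((NFkB >= 1 -> EF (NFkB = 0)) & (NFkB = 0 -> EF (NFkB >= 1)))"
  scenario: {fix: {ATF6: 0, PERK: 0, IRE1: 0, S1_2P: 0}}
  expect_sync: true
  expect_async: true
- id: P18
  formula: "AG ((NFkB >= 1 -> AF (A20 >= 1)) & (A20 >= 1 -> AF (NFkB = 0)))"
  scenario: {fix: {ATF6: 0, PERK: 0, IRE1: 0, S1_2P: 0}}
  expect_sync: true
  expect_async: false
- id: P18p
  formula: "AG ((NFkB >= 1 -> EF (A20 >= 1)) & (A20 >= 1 -> EF (NFkB = 0)))"
  scenario: {fix: {ATF6: 0, PERK: 0, IRE1: 0, S1_2P: 0}}
  expect_sync: true
  expect_async: true
- id: P19
  formula: "AG ((GADD34 = 2 -> AF (ATF4 = 0)) & (ATF4 = 0 -> AF (GADD34 = 0)))"
  expect_sync: true
  expect_async: false
- id: P19p
  formula: "AG ((GADD34 = 2 -> EF (ATF4 = 0)) & (ATF4 = 0 -> EF (GADD34 = 0)))"
  expect_sync: true
  expect_async: true
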