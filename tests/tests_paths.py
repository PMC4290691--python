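"""Shared inline fixtures for CLI tests."""

TOY_MODEL = """
name: toy
nodes:
  - {name: A, kind: input, levels: 3}
  - {name: B, kind: internal, levels: 3}
  - {name: C, kind: internal, levels: 3}
  - {name: Out, kind: output, levels: 2}
edges:
  - {from: A, to: B, sign: "+"}
  - {from: B, to: C, sign: "+"}
  - {from: C, to: Out, sign: "+"}
"""

TOY_PROPS = """
- id: reach2
  formula: "A = 2 -> AF (C = 2)"
  scenario: {}
  expect_sync: true
  expect_async: true
- id: decay
  formula: "A = 0 -> AF (C = 0)"
  expect_sync: true
  expect_async: true
- id: witnessed
  formula: "EF (Out = 1)"
  scenario: {fix: {A: 2}}
  expect_sync: true
  expect_async: true
"""
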