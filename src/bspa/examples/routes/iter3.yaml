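# Iteration 3: two-step route — amide coupling then reductive amination on
# the methylpiperazine core (racemic).
id: iter3
adducts: ["[M+H]+"]
steps:
  - id: amide
    rule: "[NX3;H2,H1;!$(NC=O);!$(NS=O):1].[CX3:2](=[OX1:3])[OX2H]>>[N:1][C:2]=[O:3]"
    input_roles: [amine, acid]
    leaving_formula: H2O
  - id: red_amination
    rule: "[NX3;H2,H1;!$(NC=O);!$(NS=O):1].[CX3;H1:2]=[OX1]>>[N:1][CH2:2]"
    input_roles: [amine, aldehyde]
    leaving_formula: O
stages:
  - step: amide
    inputs: {amine: core_diamine, acid: acid}
  - step: red_amination
    inputs: {amine: product, aldehyde: aldehyde}
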