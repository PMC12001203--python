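# Iteration 2: one-step amide coupling on the urea-retaining core.
id: iter2
adducts: ["[M+H]+"]
steps:
  - id: amide
    rule: "[NX3;H2,H1;!$(NC=O);!$(NS=O):1].[CX3:2](=[OX1:3])[OX2H]>>[N:1][C:2]=[O:3]"
    input_roles: [amine, acid]
    leaving_formula: H2O
stages:
  - step: amide
    inputs: {amine: core_amine, acid: acid}
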