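# Iteration 3.5: two-step route — amide coupling then urea formation on the
# racemic methylpiperazine core (16 acids x 64 isocyanates = 1024 targets).
id: iter3_5
adducts: ["[M+H]+"]
steps:
  - id: amide
    rule: "[NX3;H2,H1;!$(NC=O);!$(NS=O):1].[CX3:2](=[OX1:3])[OX2H]>>[N:1][C:2]=[O:3]"
    input_roles: [amine, acid]
    leaving_formula: H2O
  - id: urea
    rule: "[NX3;H2,H1;!$(NC=O);!$(NS=O):1].[NX2:2]=[CX2:3]=[OX1:4]>>[N:1][C:3](=[O:4])[N:2]"
    input_roles: [amine, isocyanate]
    leaving_formula: ""
stages:
  - step: amide
    inputs: {amine: core_diamine, acid: acid}
  - step: urea
    inputs: {amine: product, isocyanate: isocyanate}
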