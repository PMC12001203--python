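# Iteration 1.1: urea vector without the furan ring.
id: iter1_1
adducts: ["[M+H]+"]
steps:
  - id: urea
    rule: "[NX3;H2,H1;!$(NC=O);!$(NS=O):1].[NX2:2]=[CX2:3]=[OX1:4]>>[N:1][C:3](=[O:4])[N:2]"
    input_roles: [amine, isocyanate]
    leaving_formula: ""
stages:
  - step: urea
    inputs: {amine: core_amine, isocyanate: isocyanate}
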