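# Iteration 4.2: two parallel two-step routes whose products are combined by
# a final esterification (8 x 20 = 160 targets).
id: iter4_2
adducts: ["[M+H]+"]
steps:
  - id: red_amination
    rule: "[NX3;H2,H1;!$(NC=O);!$(NS=O):1].[CX3;H1:2]=[OX1]>>[N:1][CH2:2]"
    input_roles: [amine, aldehyde]
    leaving_formula: O
  - id: amide
    rule: "[NX3;H1;!$(NC=O);!$(NS=O):1].[CX3:2](=[OX1:3])[OX2H]>>[N:1][C:2]=[O:3]"
    input_roles: [amine, acid]
    leaving_formula: H2O
  - id: urea
    rule: "[NX3;H1;!$(NC=O);!$(NS=O):1].[NX2:2]=[CX2:3]=[OX1:4]>>[N:1][C:3](=[O:4])[N:2]"
    input_roles: [amine, isocyanate]
    leaving_formula: ""
  - id: ester
    rule: "[OX2H;!$(OC=O):1].[CX3:2](=[OX1:3])[OX2H]>>[O:1][C:2]=[O:3]"
    input_roles: [alcohol, acid]
    leaving_formula: H2O
branches:
  - id: branchA
    stages:
      - step: red_amination
        inputs: {amine: amino_alcohol, aldehyde: aldehyde_a}
      - step: amide
        inputs: {amine: product, acid: cap_acid}
  - id: branchB
    stages:
      - step: red_amination
        inputs: {amine: amino_acid, aldehyde: aldehyde_b}
      - step: urea
        inputs: {amine: product, isocyanate: isocyanate_b}
merge:
  step: ester
  inputs: {alcohol: "product:branchA", acid: "product:branchB"}
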