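# Nine simulated trait architectures: mean effect sizes for the additive,
# dominant and epistatic (AA / AD / DD) components. Shared simulation
# parameters: QTN = 1000 causal markers, broad-sense heritability H2 = 0.7,
# coefficient of variation of effects cv = 0.1.
S1: {mu_A: 100, mu_D: 0,   mu_AA: 0,    mu_AD: 0,    mu_DD: 0,    description: "Fully additive phenotype"}
S2: {mu_A: 75,  mu_D: 25,  mu_AA: 0,    mu_AD: 0,    mu_DD: 0,    description: "Mixture of additive and dominant effects"}
S3: {mu_A: 50,  mu_D: 50,  mu_AA: 0,    mu_AD: 0,    mu_DD: 0,    description: "Mixture of additive and dominant effects"}
S4: {mu_A: 25,  mu_D: 75,  mu_AA: 0,    mu_AD: 0,    mu_DD: 0,    description: "Mixture of additive and dominant effects"}
S5: {mu_A: 0,   mu_D: 100, mu_AA: 0,    mu_AD: 0,    mu_DD: 0,    description: "Fully dominant phenotype"}
S6: {mu_A: 33,  mu_D: 33,  mu_AA: 34,   mu_AD: 0,    mu_DD: 0,    description: "Additive and dominant effects, plus a single epistatic effect"}
S7: {mu_A: 33,  mu_D: 33,  mu_AA: 0,    mu_AD: 34,   mu_DD: 0,    description: "Additive and dominant effects, plus a single epistatic effect"}
S8: {mu_A: 33,  mu_D: 33,  mu_AA: 0,    mu_AD: 0,    mu_DD: 34,   description: "Additive and dominant effects, plus a single epistatic effect"}
S9: {mu_A: 33,  mu_D: 33,  mu_AA: 11.3, mu_AD: 11.3, mu_DD: 11.3, description: "Additive and dominant effects, plus three different epistatic effects"}
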