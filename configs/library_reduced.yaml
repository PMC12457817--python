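# Reduced Super Learner library: non-adaptive and data-adaptive
# parametric learners only.
- family: glm
- family: glm-pairwise-interactions
- family: ridge-bayes-glm
- family: gam
- family: lasso-elasticnet
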