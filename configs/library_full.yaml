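# Full Super Learner library: the reduced set plus flexible
# non-parametric learners (more prone to biased standard errors when
# cross-fitting is not used).
- family: glm
- family: glm-pairwise-interactions
- family: ridge-bayes-glm
- family: gam
- family: lasso-elasticnet
- family: random-forest
- family: gradient-boosting
- family: neural-net
- family: mars-like
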