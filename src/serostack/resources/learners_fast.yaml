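# Desk-scale search ranges: same families, lighter ensembles, for quick runs
# and continuous testing.  Study-scale ranges live in learners.yaml.
c50:
  n_estimators: {type: int, low: 10, high: 30}
  max_depth: {type: int, low: 1, high: 3}
  learning_rate: {type: loguniform, low: 0.1, high: 1.0}
svm_rbf:
  C: {type: loguniform, low: 0.1, high: 10.0}
  gamma: {type: loguniform, low: 0.001, high: 1.0}
rrf:
  n_estimators: {type: int, low: 30, high: 60}
  max_features: {type: uniform, low: 0.2, high: 1.0}
  min_samples_leaf: {type: int, low: 2, high: 8}
nnet_pca:
  n_components: {type: uniform, low: 0.4, high: 0.9}
  hidden: {type: int, low: 2, high: 8}
  alpha: {type: loguniform, low: 0.001, high: 1.0}
gausspr:
  length_scale: {type: loguniform, low: 1.0, high: 10.0}
glmnet:
  C: {type: loguniform, low: 0.01, high: 10.0}
  l1_ratio: {type: uniform, low: 0.0, high: 1.0}
adabag:
  n_bags: {type: int, low: 3, high: 5}
  n_estimators: {type: int, low: 5, high: 15}
xgboost:
  n_estimators: {type: int, low: 30, high: 80}
  max_depth: {type: int, low: 1, high: 3}
  learning_rate: {type: loguniform, low: 0.05, high: 0.3}
  subsample: {type: uniform, low: 0.6, high: 1.0}
glm_stepaic: {}
naive_bayes: {}
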