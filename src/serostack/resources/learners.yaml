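# Random-search hyperparameter ranges for the 10 base-learner families.
# Ranges follow commonly published practice for each family; they are data,
# not code, so a study can version its own copy.
c50:
  n_estimators: {type: int, low: 20, high: 100}
  max_depth: {type: int, low: 1, high: 4}
  learning_rate: {type: loguniform, low: 0.05, high: 1.0}
svm_rbf:
  C: {type: loguniform, low: 0.01, high: 100.0}
  gamma: {type: loguniform, low: 0.0001, high: 10.0}
rrf:
  n_estimators: {type: int, low: 50, high: 250}
  max_features: {type: uniform, low: 0.1, high: 1.0}
  min_samples_leaf: {type: int, low: 1, high: 10}
nnet_pca:
  n_components: {type: uniform, low: 0.3, high: 0.95}
  hidden: {type: int, low: 2, high: 12}
  alpha: {type: loguniform, low: 0.0001, high: 1.0}
gausspr:
  length_scale: {type: loguniform, low: 0.3, high: 30.0}
glmnet:
  C: {type: loguniform, low: 0.001, high: 100.0}
  l1_ratio: {type: uniform, low: 0.0, high: 1.0}
adabag:
  n_bags: {type: int, low: 5, high: 15}
  n_estimators: {type: int, low: 10, high: 50}
xgboost:
  n_estimators: {type: int, low: 30, high: 200}
  max_depth: {type: int, low: 1, high: 5}
  learning_rate: {type: loguniform, low: 0.01, high: 0.5}
  subsample: {type: uniform, low: 0.5, high: 1.0}
glm_stepaic: {}
naive_bayes: {}
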