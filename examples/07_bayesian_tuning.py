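"""Bayesian hyperparameter search with a Gaussian-process surrogate.

The tuner proposes points inside the box (hidden units 32-64, learning
rate 0.001-0.01, batch size 64-128, dropout 0.3-0.7) by maximizing the
upper confidence bound mu + kappa*sigma of a GP fitted to past trials, and
returns the best configuration observed.
"""

from lesiongraph import (ModelConfig, build_feature_table, build_graph,
                         generate_cohort, tune_bayesian)

cohort = generate_cohort(n_benign=20, n_malignant=20, seed=0)
graph = build_graph(build_feature_table(cohort), tau=0.9)

best, trials = tune_bayesian(graph=graph, budget=8, seed=0,
                             base_config=ModelConfig(epochs=40, seed=0))
print(trials.to_string(index=False,
                       float_format=lambda v: f"{v:.4g}"))
print(f"\nbest configuration: hidden={best.hidden_units} "
      f"lr={best.learning_rate:.4g} batch={best.batch_size} "
      f"dropout={best.model_dropout:.2f}")
print("'score' is validation accuracy (%); every proposed point stays "
      "inside the search box.")
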