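"""Train the elastic-net germ-line age clock, with and without BMI.

Features are the 51 clock regions' methylation means; the penalty is
chosen by 10-fold cross-validation along a log-spaced path. The with-BMI
clock adds the participant's BMI as a 52nd feature.
"""

import germclock as g

cohort = g.generate_cohort(seed=1)
beta, region_map, truth = g.simulate_methylome(cohort, g.SimulationParams(), seed=1)
region_m = g.aggregate_regions(beta, region_map)
ages = cohort.set_index("id")["age"]

for include_bmi in (False, True):
    feats = g.clock_features(region_m, truth.clock_region_ids, cohort=cohort,
                             include_bmi=include_bmi)
    model = g.train_clock(feats, ages.reindex(feats.index).to_numpy(),
                          include_bmi=include_bmi, alpha=0.5, k_folds=10, seed=1)
    pred = g.predict_age(model, feats, ages=ages.reindex(feats.index).to_numpy())
    r2 = g.r_squared(pred["actual_age"], pred["predicted_age"])
    mae = g.mae(pred["actual_age"], pred["predicted_age"])
    active = int((model.coef != 0).sum())
    label = "with BMI   " if include_bmi else "without BMI"
    print(f"{label}: {model.n_features} features, lambda={model.lam:.4f}, "
          f"{active} active, r^2={r2:.4f}, MAE={mae:.4f} y")
# r^2 is the squared correlation of actual vs predicted age over the 96
# training samples; MAE is the mean absolute prediction error in years.
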