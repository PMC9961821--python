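"""Compare the response-surface fit with a Levenberg-Marquardt neural net.

Trains the 3-6-4 tangent-sigmoid MLP twenty times from seeded restarts
(70/15/15 train/validation/test split, early stopping on validation
error), keeps the restart with the best validation error, and tabulates
R2 / RMSE / AAD / SEP for both predictors on all 20 runs. The RSM
numbers are in-sample for a 10-parameter linear-in-coefficients model;
the ANN numbers include the 6 points it never trained on.
"""

import extractopt as eo

design, responses = eo.load_fixture("table1")

mlp, history, _ = eo.train_best_of(
    design, responses, eo.TrainConfig(seed=0), n_restarts=20
)
ann_pred = eo.forward(mlp, design.natural)

print(f"selected restart stopped by {history.stop_reason} at epoch {history.best_epoch}")
print(f"{'response':8s} {'model':4s} {'R2':>8s} {'RMSE':>8s} {'AAD%':>8s} {'SEP%':>8s}")
for j, name in enumerate(responses.names):
    y = responses.column(name)
    rsm_model = eo.fit_quadratic(design, y, name)
    for label, pred in (
        ("RSM", eo.predict(rsm_model, design.coded, coded=True)),
        ("ANN", ann_pred[:, j]),
    ):
        m = eo.comparison_metrics(pred, y)
        print(f"{name:8s} {label:4s} {m.r2:8.4f} {m.rmse:8.4f} "
              f"{m.aad_percent:8.3f} {m.sep_percent:8.4f}")
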