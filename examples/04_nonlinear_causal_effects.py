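"""Nonlinear causal-effect estimation: functional network versus linear.

The outcome follows a cosine causal form Y = 2 cos(G) + confounding +
noise.  The second stage fits the fitted exposure with (a) the B-spline
functional network and (b) a linear model; the functional network should
achieve a clearly lower test error because the linear model cannot bend.
"""


from ganiv import (
    DfnnConfig, fit_second_stage, fit_first_stage_ols,
    make_simulation2_dataset, outcome_metrics, split_dataset, SplitSpec,
)

ds = make_simulation2_dataset(n=1000, causal_form="cos", seed=5)
idx1, tr, te = split_dataset(ds.n, SplitSpec(seed=5))

fit = fit_first_stage_ols(ds.Z[idx1], ds.G[idx1])
ghat = fit.predict(ds.Z)

cfg = DfnnConfig(lr_grid=(1e-2, 1e-3), l2_grid=(1e-3,), max_epochs=800)
dfnn = fit_second_stage(ghat[tr], ds.Y[tr], cfg, kind="dfnn")
lin = fit_second_stage(ghat[tr], ds.Y[tr], kind="linear")

for name, model in (("functional network", dfnn), ("linear second stage", lin)):
    m = outcome_metrics(model.predict(ghat[te]), ds.Y[te], ds.y0[te])
    print(f"{name:20s} test MSE={m['mse']:.3f}  bias={m['bias']:.3f}  "
          f"RV={m['rv']:.3f}")
print("(lower MSE/bias and higher RV for the functional network: the "
      "cosine effect is invisible to a straight line)")
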