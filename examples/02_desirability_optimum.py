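"""Locate the extraction condition that maximizes all four assays at once.

Fits one quadratic per response (total phenolics, total flavonoids,
DPPH inhibition, CUPRAC), converts each prediction to a 0-1 Derringer
desirability ramp anchored at the observed worst/best values, and
maximizes their geometric mean D over the coded factorial cube. The
printed optimum is the solvent/time/temperature setting a lab would
run; D near 1 means every response is simultaneously near its best.
"""

import extractopt as eo

design, responses = eo.load_fixture("table1")
models = [eo.fit_quadratic(design, responses.column(n), n) for n in responses.names]
spec = eo.DesirabilitySpec.maximize_observed(responses.names, responses.values)

result = eo.optimize_desirability(models, spec, region=(-1.0, 1.0))

names = [f.name for f in design.factors]
print("optimum (natural units):",
      ", ".join(f"{n} = {v:.2f}" for n, v in zip(names, result.point_natural)))
print("optimum (coded units):  ",
      ", ".join(f"{v:+.3f}" for v in result.point_coded))
print(f"overall desirability D = {result.D:.3f}")
for name in responses.names:
    print(f"  {name:7s} predicted {result.predicted[name]:6.3f}  "
          f"d = {result.individual[name]:.3f}")

# agreement between a validation experiment and the model at the optimum
rep = eo.validation_rsd(4.49, round(result.predicted["TPC"], 2), "TPC")
print(f"\nTPC validation: experimental 4.49 vs predicted {rep.predicted:.2f}"
      f" -> pair SD {rep.std:.3f}, RSD {rep.rsd_percent:.2f}%")
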