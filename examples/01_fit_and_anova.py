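"""Fit the quadratic response surface for one assay and print its ANOVA.

Loads the packaged 20-run central-composite extraction study, fits the
full 10-term second-order model for DPPH radical-scavenging activity in
coded units, and prints the diagnostic battery. The F/p columns say
which factors matter; the lack-of-fit test checks the quadratic is
adequate against pure replicate error; R2/adjusted/predicted R2 and
PRESS summarize fit and leave-one-out prediction quality.
"""

import extractopt as eo

design, responses = eo.load_fixture("table1")
y = responses.column("DPPH")
model = eo.fit_quadratic(design, y, "DPPH")
report = eo.anova(model, design, y)

print("term        coef       SS       F        p")
for row in report.terms:
    mark = "*" if row.significant else " "
    print(f"{row.term:6s} {row.coefficient:+9.4f} {row.ss:8.4f} {row.f:8.2f} {row.p:8.4f} {mark}")
print(f"\nlack-of-fit F = {report.lack_of_fit_f:.2f} (p = {report.lack_of_fit_p:.4f})"
      f"  -> quadratic is adequate if p > 0.05")
print(f"R2 = {report.r2:.4f}, adjusted = {report.adj_r2:.4f}, predicted = {report.pred_r2:.4f}")
print(f"PRESS = {report.press:.4f}, AICc = {report.aicc:.2f}, BIC = {report.bic:.2f}")
print(f"CV% = {report.cv_percent:.4f}, adequate precision = {report.adequate_precision:.4f}")
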