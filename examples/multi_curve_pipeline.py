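"""Run the full pipeline on a multi-curve dataset and export results.

Builds a four-compound panel (three monotonic, one biphasic), runs
fit -> select -> estimate -> assess per curve, writes the standard CSV/JSON
outputs and a plot with dashed lines at each in-range estimate.
"""

import tempfile
from pathlib import Path

import respcurve as rc
from respcurve.plotting import render_plot

records = []
for i, (name, mid, theta) in enumerate([
        ("cmpd_A", "LL.4", (1.5, 2.0, 100.0, 0.5)),
        ("cmpd_B", "LL.4", (1.5, 2.0, 100.0, 5.0)),
        ("cmpd_C", "LL.4", (-1.5, 2.0, 100.0, 3.0))]):
    recipe = rc.DRRecipe(mid, theta, noise_sd=3.0, seed=17 + i,
                         factors=(name,))
    records.extend(rc.simulate_dose_response(recipe).records)
ds = rc.DoseResponseDataset(records, shape="monotonic",
                            factor_names=("compound",))

config = rc.AnalysisConfig(ed_method="serra_greco", ed_basis="relative",
                           selection_criterion="AIC", seed=17)
result = rc.run_dr(ds, config)

table = result.estimates_table()
print(table[["curve", "phase", "estimate", "ci_low", "ci_high",
             "in_range"]].to_string(index=False))
# Lower ED50 = higher potency: cmpd_A (true e=0.5) beats cmpd_B (e=5);
# cmpd_C has a rising curve (negative slope parameter) and is handled the
# same way.

out = Path(tempfile.mkdtemp(prefix="respcurve_"))
paths = result.export(out)
plots = render_plot(result, ds, out / "panel", formats=("png",))
print("written:", *paths.values(), *plots, sep="\n  ")
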