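"""Sustained regional expression trends across N -> B -> T zones.

Simulates region-labelled single cells with planted monotone gradients
and classifies every gene as sustained-up, sustained-down or no-trend
within the epithelial compartment, in both relaxed and strict modes.
"""

import evosig as es

truth = es.make_truth(seed=7)
cells, _ = es.gen_regional_cells(200, truth, seed=7)

planted = truth.trend_direction()
for mode in ("relaxed", "strict"):
    calls = es.classify_regional_trend(cells, "EPI", mode=mode)
    counts = calls["direction"].value_counts().to_dict()
    trending = planted.index[planted != "none"]
    hit = (calls.loc[trending, "direction"] == planted[trending]).mean()
    print(f"{mode}: {counts}; planted gradients recovered {hit:.0%}")

# "up" means mean log-normalized expression rises monotonically from the
# non-tumor zone through the border into the core AND the change is
# DE-significant (N vs T in relaxed mode; both adjacent steps in strict).
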