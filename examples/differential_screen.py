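"""Screen a two-group metabolite table for discriminating features.

Simulates an elicitor-vs-control abundance table with 20 planted two-fold
increases and 20 decreases, then applies the screening rule:
fold change >= 2 or <= 0.5, PLS-DA VIP > 2, Welch P < 0.05 — plus the
milder "counted list" preset (VIP > 1, P < 0.05) and a ratio-based
pathway-enrichment test on the result.
"""

from camptomine import diffstats
from camptomine.synth import gen_metabolites

matrix, conditions, truth = gen_metabolites(
    n_features=300, n_up=20, n_down=20, effect_log2=1.0,
    n_per_group=6, seed=42)

for name, preset in (("discriminating (VIP>2, FC>=2)",
                      diffstats.DISCRIMINATING),
                     ("counted lists  (VIP>1)", diffstats.COUNTED_LISTS)):
    res = diffstats.metabolite_screen(matrix, conditions,
                                      "treated", "control",
                                      thresholds=preset)
    n_up = (res.direction == "up").sum()
    n_down = (res.direction == "down").sum()
    hits = (((res.direction == "up") & (truth == "up"))
            | ((res.direction == "down") & (truth == "down"))).sum()
    print(f"{name}: {n_up} up, {n_down} down "
          f"(recovers {hits}/40 planted effects)")

res = diffstats.metabolite_screen(matrix, conditions, "treated", "control",
                                  thresholds=diffstats.COUNTED_LISTS)
differential = res.index[res.direction != "ns"]
sets = {"planted_up": list(truth.index[truth == "up"]),
        "planted_down": list(truth.index[truth == "down"]),
        "random_100": list(truth.index[100:200])}
enrichment = diffstats.enrich(differential, res.index, sets)
print()
print(enrichment.to_string(index=False))

# A pathway is enriched when its share of the differential features
# exceeds its share of the background (N_MPDM/N_DM > N_MPBM/N_BM) and the
# one-sided hypergeometric P is < 0.05: the two planted sets pass, the
# random set does not.
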