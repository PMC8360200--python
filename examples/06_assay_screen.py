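"""Quantify a simulated NAD(P)H-depletion plate screen.

Active wells show an exponential 340 nm decay as the cofactor is oxidised;
flat wells are inactive. Beer-Lambert (epsilon 6220 /M/cm) converts the
endpoint drop to cofactor consumed, reported against both the substrate
(5 mM) and cofactor (1 mM) loadings.
"""

from sdrmine.assay import screen_matrix, simulate_trace

traces = []
k = 0
for enzyme in ("SDR_a", "SDR_b", "SDR_c"):
    for substrate in ("ketone_1", "ketone_2"):
        active = (enzyme, substrate) != ("SDR_c", "ketone_2") and enzyme != "SDR_b"
        for rep in range(3):  # triplicate wells
            traces.append(
                simulate_trace(f"W{k}", enzyme, substrate, active=active, seed=k)
            )
            k += 1

table = screen_matrix(traces, hit_threshold=10.0)
cols = ["enzyme_id", "substrate_id", "n_wells", "consumed_mM_mean",
        "conversion_substrate_pct_mean", "conversion_substrate_pct_sd",
        "conversion_cofactor_pct_mean", "hit"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))

print("\nWith 1 mM cofactor against 5 mM substrate the substrate-referenced"
      "\nconversion saturates at 20% (the stoichiometric ceiling) while the"
      "\ncofactor-referenced figure reaches 100%; both are always reported.")
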