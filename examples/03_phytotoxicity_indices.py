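"""Germination phytotoxicity indices and frass-composition metrics.

Computes GERIR/GERIS for a suppressive and a stimulating extract, applies
the 50/70/80% phytotoxicity thresholds, then derives C/N ratios, the
organic-matter conversion and the conductivity range from the packaged
frass composition tables.
"""

import pandas as pd

from rhizoquant import (
    GerminationRecord,
    classify_phytotoxicity,
    cn_ratio,
    field_range,
    geri_r,
    geri_s,
    load_composition_table,
    organic_matter_from_carbon,
)

# one suppressive and one stimulating dish versus a distilled-water control
dishes = {
    "whey-diet extract 100%": GerminationRecord(G1=2, G2=18, R1=3.1, R2=14.8,
                                                S1=2.5, S2=9.9),
    "gainesville extract 25%": GerminationRecord(G1=19, G2=18, R1=16.9, R2=14.8,
                                                 S1=10.4, S2=9.9),
}
for name, rec in dishes.items():
    gr, gs = geri_r(rec), geri_s(rec)
    verdict = classify_phytotoxicity(gr, threshold=50)
    print(f"{name}: GERIR {gr:6.1f}%  GERIS {gs:6.1f}%  "
          f"phytotoxic(<50%): {verdict.phytotoxic}")

# values far below 50% flag phytotoxicity; above 100% indicate stimulation

solid = load_composition_table("solid_frass")
print("\nC/N ratio per solid frass type (amendment-like when ~20-40):")
for sample, row in solid.iterrows():
    print(f"  {sample}: C/N = {cn_ratio(row.organic_c_pct, row.total_n_pct):.1f}, "
          f"OM from C = {organic_matter_from_carbon(row.organic_c_pct):.2f}% "
          f"(table: {row.organic_matter_pct}%)")

extracts = pd.concat([load_composition_table("as_extracts"),
                      load_composition_table("e_extracts")])
lo, hi = field_range(extracts, "conductivity_ms_cm")
print(f"\nextract electrical conductivity spans {lo} to {hi} mS/cm "
      "- high enough to inhibit germination of salt-sensitive species")
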