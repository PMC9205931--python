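"""Agreement statistics between two species tables (e.g. CNN vs baseline)."""

import pandas as pd

from ednacnn import (
    SampleTable,
    bray_curtis,
    cohen_kappa,
    kendall_tau_b,
    median_agreement,
    overlap_counts,
)

hierarchy = {"P1": ("F1", "R1"), "P2": ("F1", "R1"), "P3": ("F2", "R1")}


def table(rows):
    return SampleTable(
        pd.DataFrame(rows, columns=["sample_id", "species", "reads"]), hierarchy
    )


cnn = table([("P1", "bagre", 900), ("P1", "piraï", 120), ("P1", "acara", 30),
             ("P2", "bagre", 700), ("P2", "acara", 250),
             ("P3", "piraï", 400), ("P3", "acara", 60)])
baseline = table([("P1", "bagre", 850), ("P1", "piraï", 200),
                  ("P2", "bagre", 600), ("P2", "acara", 280), ("P2", "piraï", 10),
                  ("P3", "piraï", 350), ("P3", "acara", 40)])

print("per-vector statistics on sample P1 (universe = union of species):")
a, b = [900, 120, 30], [850, 200, 0]
print(f"  Kendall tau-b = {kendall_tau_b(a, b):.3f}")
print(f"  Cohen kappa   = {cohen_kappa([x > 0 for x in a], [x > 0 for x in b]):.3f}")
print(f"  Bray-Curtis   = {bray_curtis(a, b):.3f}")

report = median_agreement(cnn, baseline, level="replicate", min_reads_grid=[0, 25])
print("\nmedian agreement across replicates:")
print(report[["min_reads", "tau_median", "kappa_median"]].to_string(index=False))
# Higher min-read thresholds drop low-count species, typically raising the
# rank agreement between two pipelines.

venn = overlap_counts({"bagre", "piraï", "acara"}, {"bagre", "acara"},
                      {"bagre", "piraï", "doradid"})
print("\nthree-way species overlap (CNN / baseline / checklist):", venn)
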