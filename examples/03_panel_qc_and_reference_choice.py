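"""Screen a panel for outliers, then choose the two reference compounds.

A synthetic panel is generated with known contamination: one column whose
times were shuffled (e.g. a mislabelled export) and one compound offset by
+3 min on 40% of columns (an analyte whose retention chemistry departs from
the panel's shared linear behaviour).  The screen must exclude exactly
those, and the reference pair is then chosen among the clean compounds.
"""
import lctrs
from lctrs.simulate import PanelSpec, generate_panel

spec = PanelSpec(seed=7, shuffle_columns=1, offset_compound="compound B")
panel, truth = generate_panel(spec)
print("planted:", truth["shuffled_columns"], "+ compound B offset on",
      len(truth["offset_cells"]), "columns")

report = lctrs.detect_outliers(panel)
print("excluded columns  :", dict(report.excluded_columns))
print("excluded compounds:", dict(report.excluded_compounds))
print("final consensus over", report.final_strt.n, "columns:")
print(report.final_strt.values.round(3).to_string())

best, ranking = lctrs.select_reference_pair(
    panel, report.final_strt, candidates=report.final_strt.compounds,
    excluded=report.excluded_compounds,
)
print(f"\nreference pair: {best.first} + {best.second} (coverage {best.coverage:.2f})")
print(ranking.round(3).to_string(index=False))
# The pair bracketing the retention span (coverage near 1) with the smallest
# panel-mean two-point deviation wins; pairs containing the excluded
# compound are ineligible.
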