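"""Predict where two saponins elute on a column they were never calibrated on.

The bundled Paridis panel gives each compound a standard retention time
(St_R): its mean retention over 30 C_18 columns.  Injecting just the two
reference saponins (VII and I) on the target column fixes the affine map from
the St_R axis to that column's time axis; the two analytes (VI and II) are
then located in the sample chromatogram and vetted by a four-point refit.
"""
import lctrs
from lctrs.core import MatchConfig, PeakList

panel = lctrs.datasets.paridis_panel()
strt = lctrs.compute_strt(panel)
pair = lctrs.make_reference_pair(strt, "Chonglou saponin VII", "Chonglou saponin I")

# the target column: BDS Hypersil C18.  The two reference times would come
# from reference-substance injections; the sample peak list from the sample
# chromatogram.  Here both are the panel's own measurements of col4.
target = panel.times["col4"]
ref_times = (target[pair.first], target[pair.second])
peaks = PeakList(times=tuple(sorted(target)))

cfg = MatchConfig(t_r_window=0.6, t_r_limit=0.5)
result = lctrs.run_lctrs(strt, pair, ref_times, peaks, cfg)

two = result.previous
print(f"two-point line      : t = {two.line.slope:.4f}*St_R + {two.line.intercept:.4f}")
for m in two.matches:
    print(f"  {m.analyte:22s} predicted {m.predicted:7.3f} min -> peak {m.peak:7.3f} (dt {m.delta:.3f})")
print(f"multi-point refit   : t = {result.line.slope:.4f}*St_R + {result.line.intercept:.4f}")
for m in result.matches:
    print(f"  {m.analyte:22s} refined   {m.predicted:7.3f} min    dt {m.delta:.3f} (limit {cfg.limit_for(m.analyte)})")
print(f"success: {result.success}")
# Both deviations shrink after the refit and stay below the 0.5 min limit,
# so both analyte peaks are identified without their own reference substances.
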