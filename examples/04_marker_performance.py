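"""Age-stratified performance of a methylation marker, ER status and
their combination.

Marker levels at the candidate region are dichotomized at a calibration
cutoff (here 0.15 — a placeholder, not a clinically validated value), the
combined marker is methylation-high AND ER-negative, and performance
against the pCR outcome is tabulated overall and within age strata.
"""

from methmarker import (
    SimulationConfig,
    dichotomize,
    region_level,
    simulate_cohort,
    stratified_report,
)
from methmarker.performance import er_negative_calls

bundle = simulate_cohort(SimulationConfig(seed=1))
labelled = [s for s in bundle.samples if s.pcr is not None]

levels = region_level(bundle.beta, bundle.marker_probe_ids)
meth_calls = dichotomize({s.sample_id: levels[s.sample_id] for s in labelled}, 0.15)
er_calls = er_negative_calls(labelled)

report = stratified_report(labelled, meth_calls, er_calls)
print(f"{'stratum':8s} {'marker':12s} {'n':>4s} {'pos%':>6s} {'PPV%':>6s} "
      f"{'sens%':>6s} {'spec%':>6s}")
for res in (report.overall, *report.strata):
    for name, ct in res.markers.items():
        fmt = lambda v: "  -- " if v is None else f"{v:6.1f}"
        print(f"{res.stratum.label:8s} {name:12s} {ct.n:4d} "
              f"{fmt(ct.percent('positive_rate'))} {fmt(ct.percent('ppv'))} "
              f"{fmt(ct.percent('sensitivity'))} {fmt(ct.percent('specificity'))}")
# PPV is the pCR rate among marker-positive patients; the combined marker
# trades sensitivity for a higher PPV/specificity than either component.
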