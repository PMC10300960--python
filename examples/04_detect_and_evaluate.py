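"""Full pipeline: features, thresholds, confusion counts, ROC and AUC.

Runs all four detectors (ERD, ESD, ESED, CESED) on a synthetic recording
and evaluates them against the generator's truth labels under both
threshold rules (median of the feature series, and the ROC-optimal cutoff
closest to the perfect-detector corner (0,1)).
"""

from pamdetect.detection import LabelSeries
from pamdetect.pipeline import PipelineConfig, analyze_recording
from pamdetect.synth import generate

labelled = generate(seed=1)
truth = LabelSeries(labels=labelled.labels, zones=labelled.zone_of_segment)
result = analyze_recording(labelled.recording, PipelineConfig(), truth=truth)

print(f"competent IMFs by average energy ratio: {result.cimf}; analysing IMF{result.imf_used}")
print(f"main domain: {result.main_domain} Hz\n")
print(f"{'detector':8s} {'rule':12s} {'cutoff':>8s} {'TPR%':>7s} {'FPR%':>7s} "
      f"{'AUC':>7s} {'F1%':>7s}")
for ev in result.evaluations:
    print(f"{ev.algorithm:8s} {ev.threshold_method:12s} {ev.cutoff:8.3f} "
          f"{100 * ev.tpr:7.2f} {100 * ev.fpr:7.2f} {ev.report.auc:7.4f} "
          f"{100 * ev.report.f1:7.2f}")

# Higher AUC = better ranking of call vs noise windows irrespective of the
# cutoff; the concentrated entropy detector (CESED) should lead, with the
# ROC-optimal rule trading a little recall for far fewer false alarms than
# the median rule.
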