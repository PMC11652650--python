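#!/usr/bin/env python
"""Account for habitat areas and score the map against the known truth.

Bins the HSI surface into 0.1-wide classes, totals each class's area in
km² (cos-latitude corrected), sums the suitable range (HSI 0.6–0.9),
reports the binary map's presence/absence areas and percentages, and —
because the landscape is synthetic with known truth — computes the
thematic accuracy (overall / producer's / user's accuracy, Cohen's
kappa with its agreement category) of the majority-vote map against
the thresholded true suitability.
"""

import sys

from _common import STUDY_DIR, build_pipeline

def main() -> None:
    pipe = build_pipeline()
    areas = pipe.areas()
    print(f"total mapped area      {areas['total_km2']:12.1f} km^2")
    print(f"suitable (HSI 0.6-0.9) {areas['suitable_km2']:12.1f} km^2")
    print(f"presence               {areas['presence_km2']:12.1f} km^2 ({areas['presence_pct']:.1f}%)")
    print(f"absence                {areas['absence_km2']:12.1f} km^2 ({areas['absence_pct']:.1f}%)")
    report = pipe.accuracy()
    print(f"truth agreement: overall {report.overall_pct:.2f}%, "
          f"kappa {report.kappa:.3f} ({report.agreement})")
    print(f"written to {STUDY_DIR / 'class_areas.csv'}, {STUDY_DIR / 'area_summary.json'}, "
          f"{STUDY_DIR / 'accuracy.csv'}")

if __name__ == "__main__":
    sys.exit(main())
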