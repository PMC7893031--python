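#!/usr/bin/env python
"""Beat-rate time course: baseline -> 24 h hypoxia -> 24 h reoxygenation.

Simulates the full recording protocol for 41 electrodes (1 min segments:
hourly during the 20 h baseline, every 30 min afterwards, desk profile),
detects beats, normalizes each electrode to its own baseline median BPM and
aggregates the analysis periods.  Writes the period summary and the
exclusion report under results/ and prints the recovered period means next
to the programmed study targets.
"""

import argparse
from pathlib import Path

from cardiomea.scenarios import run_beat_rate_study

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    study = run_beat_rate_study(seed=args.seed)
    study.period_summary.to_csv(RESULTS / "beat_rate_period_summary.csv", index=False)
    study.exclusions.to_csv(RESULTS / "beat_rate_exclusions.csv", index=False)

    n_in = int(study.exclusions["included"].sum())
    print(f"electrodes analyzed: {n_in} of {len(study.exclusions)}")
    print(f"{'period':10s} {'recovered':>9s} {'target':>7s}")
    for period, target in study.targets.items():
        print(f"{period:10s} {study.recovered[period]:9.3f} {target:7.3f}")
    print("\nThe rate collapses to about a third of baseline during 7-15 h of "
          "hypoxia, partially adapts by 15-24 h, overshoots in the first 6 h "
          "of reoxygenation and settles back near baseline -- the programmed "
          "phase response is recovered through the full detection chain.")


if __name__ == "__main__":
    main()
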