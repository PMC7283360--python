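#!/usr/bin/env python
"""Reconstruct the pH × NaCl phase diagram from the simulated curves.

Classifies every scenario profile written by 01_simulate_scenarios.py
(low-q power-law exponent + diffraction-peak hunt) and tabulates the
call against the registered ground truth. The output is the computed
phase diagram: bundled lamellar phases at acidic pH and low-to-
physiological salt, filaments at higher pH or salt, aggregates for the
charge-reversed E34K mutant at acidic pH.
"""

import csv
from pathlib import Path

from husaxs.phase import classify_phase
from husaxs.profiles import read_profile

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    index = list(csv.DictReader(open(OUT / "scenario_index.csv")))
    rows, correct = [], 0
    for entry in index:
        prof = read_profile(OUT / "profiles" / entry["file"])
        call = classify_phase(prof)
        d1 = f"{call.peaks[0][1]:.1f}" if call.peaks else ""
        ok = call.label == entry["expected_label"]
        correct += ok
        rows.append({"scenario": entry["scenario"], "label": call.label,
                     "expected": entry["expected_label"], "match": ok,
                     "exponent": f"{call.exponent:.2f}",
                     "first_spacing_A": d1, "true_d_A": entry["true_d_A"]})
        print(f"{entry['scenario']:14s} {call.label:9s} slope={call.exponent:6.2f} "
              f"d1={d1 or '-':>6s}  truth={entry['expected_label']}"
              f"{' d=' + entry['true_d_A'] if entry['true_d_A'] else ''}")
    with open(OUT / "phase_diagram.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(rows[0]))
        w.writeheader()
        w.writerows(rows)
    print(f"\n{correct}/{len(rows)} conditions match their expected phase; "
          "table in results/phase_diagram.csv")


if __name__ == "__main__":
    main()
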