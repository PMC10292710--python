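#!/usr/bin/env python
"""Summarise the embedded study data and the event/count disagreement."""

import json
from pathlib import Path

from rarecast.data import (
    consistency_report,
    load_annual_fixture,
    load_event_fixture,
    write_counts_csv,
    write_events_csv,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "01_data_overview"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = load_annual_fixture(include_2020=True)
    events = load_event_fixture()
    write_counts_csv(counts, OUT / "annual_counts.csv")
    write_events_csv(events, OUT / "event_times.csv")
    report = consistency_report()
    (OUT / "consistency_report.json").write_text(json.dumps(report, indent=2))
    print(f"annual counts {counts.start_year}-{counts.end_year}, "
          f"total {int(counts.counts.sum())}")
    print(f"event table: {report['n_events']} events, last on "
          f"{report['last_event_date']}")
    print(f"{len(report['mismatched_years'])} years disagree between the "
          f"two representations -> {OUT}")


if __name__ == "__main__":
    main()
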