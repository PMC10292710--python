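#!/usr/bin/env python
"""Rolling-origin comparison of all six model variants, T = 2003..2014."""

from pathlib import Path

from rarecast.data import load_annual_fixture, load_event_fixture
from rarecast.evaluation import VARIANT_NAMES, report, rolling_evaluation

OUT = Path(__file__).resolve().parent.parent / "results" / "05_rolling_evaluation"
SEED = 0


def main() -> None:
    counts = load_annual_fixture(include_2020=True)
    events = load_event_fixture()
    table = rolling_evaluation(
        counts, events, variants=VARIANT_NAMES, seed=SEED, snc_restarts=3
    )
    report(table, None, OUT,
           manifest={"seed": SEED, "variants": list(VARIANT_NAMES),
                     "snc_restarts": 3},
           plots=True)
    print(table.pivot(index="T", columns="variant",
                      values="train_rmse").round(3).to_string())
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
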