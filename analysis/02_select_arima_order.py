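#!/usr/bin/env python
"""ARIMA order selection on every rolling training window 1966-T."""

import json
from pathlib import Path

import pandas as pd

from rarecast.arima import grid_search, stepwise_search
from rarecast.data import load_annual_fixture, split_by_year

OUT = Path(__file__).resolve().parent.parent / "results" / "02_arima_order"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = load_annual_fixture()
    rows = []
    for T in range(2003, 2015):
        train = split_by_year(counts, T).train.values()
        step_order, step_fit, _ = stepwise_search(train)
        grid_order, grid_fit, _ = grid_search(train)
        rows.append({
            "T": T,
            "stepwise_order": step_order.as_tuple(),
            "stepwise_aic": round(step_fit.aic, 2),
            "exhaustive_order": grid_order.as_tuple(),
            "exhaustive_aic": round(grid_fit.aic, 2),
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "order_by_window.csv", index=False)
    print(table.to_string(index=False))

    # full AIC surface on the longest window, for reference
    _, _, info = grid_search(split_by_year(counts, 2014).train.values())
    surface = {str(k): v for k, v in info["aic"].items()}
    (OUT / "aic_surface_1966_2014.json").write_text(json.dumps(surface, indent=2))
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
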