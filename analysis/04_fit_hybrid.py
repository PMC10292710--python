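#!/usr/bin/env python
"""SNC architecture selection for each lag cap on the full study series."""

import json
from pathlib import Path

from rarecast.arima import ArimaOrder, fit_arima
from rarecast.data import load_annual_fixture
from rarecast.hybrid import (
    TrainingConfig,
    extract_residuals,
    normalize,
    snc_select,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "04_hybrid_snc"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = load_annual_fixture()
    fit = fit_arima(counts.values(), ArimaOrder(0, 1, 1))
    scaled, _ = normalize(extract_residuals(counts.values(), fit).values)
    config = TrainingConfig(seed=SEED)
    payload = {}
    for n_max in (3, 5, 7, 10):
        arch, report = snc_select(scaled, n_max=n_max, config=config,
                                  restarts=3)
        payload[f"n_max={n_max}"] = {
            "selected": {"n": arch.n_inputs, "m": arch.m_hidden},
            "step1": report["step1"],
            "step2": report["step2"],
        }
        print(f"n_max={n_max}: selected n={arch.n_inputs}, m={arch.m_hidden}")
    (OUT / "snc_selection.json").write_text(json.dumps(payload, indent=2))
    print(f"-> {OUT}")


if __name__ == "__main__":
    main()
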