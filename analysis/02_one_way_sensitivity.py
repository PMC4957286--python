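#!/usr/bin/env python
"""One-way sensitivity analysis with threshold search.

Sweeps every ranged input one at a time, records the ICER at the range
endpoints, and searches for the value at which the ICER crosses the
GBP 20,000/QALY willingness-to-pay threshold.  Writes
results/owsa_table.csv and prints the parameters whose range crosses the
threshold (the rows that decide the adoption question).
"""

from pathlib import Path

from pacea.lifetable import default_life_table
from pacea.params import load_default_parameters
from pacea.sensitivity import one_way_table

OUT = Path(__file__).resolve().parents[1] / "results"
WTP = 20000.0


def main() -> None:
    mp = load_default_parameters()
    lt = default_life_table()
    table = one_way_table(mp, lt, WTP)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "owsa_table.csv", index=False, float_format="%.6f")

    crossing = table[table["note"] == ""]
    print(f"{len(crossing)} of {len(table)} ranged parameters cross "
          f"GBP {WTP:,.0f}/QALY within their range:\n")
    cols = ["parameter", "base_value", "threshold", "icer_at_lower", "icer_at_upper"]
    print(crossing[cols].round(4).to_string(index=False))
    print(f"\nWrote {OUT / 'owsa_table.csv'}")


if __name__ == "__main__":
    main()
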