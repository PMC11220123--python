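"""Spatial autocorrelation of the yearly stage-3 efficiency surface.

Prints global Moran's I per year with permutation p-values, and the
quadrant census of the local statistics for the last year.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    moran = pd.read_csv(BASE / "three_stage" / "table7_moran.csv")
    print(moran.to_string(index=False))
    last = moran["year"].max()
    lisa = pd.read_csv(BASE / "three_stage" / f"lisa_{last}.csv")
    print(f"\nlocal Moran quadrants, {last}:")
    print(lisa["quadrant"].value_counts().to_string())
    sig = lisa[lisa["p_perm"] <= 0.05]
    print(f"{len(sig)} units significant at 5% (conditional permutation)")


if __name__ == "__main__":
    main()
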