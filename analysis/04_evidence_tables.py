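"""Build the threshold-probability / Bayes-factor evidence spectrum.

Re-reads the posterior draws exported by 03_bayesian_refit.py (no refit),
evaluates P(effect < t) for t = 1.0 down to 0.5 with Bayes factors and
Jeffreys evidence labels, and writes one CSV and one markdown grid per
endpoint.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from bayesrct.evidence import evidence_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    for endpoint in ("24h", "30d"):
        draws_path = args.outdir / f"draws_{endpoint}.csv"
        if not draws_path.exists():
            raise SystemExit(f"{draws_path} missing: run 03_bayesian_refit.py first")
        beta = pd.read_csv(draws_path)["beta"].to_numpy()
        table = evidence_table(np.exp(beta), endpoint=endpoint)
        table.to_csv(args.outdir / f"evidence_{endpoint}.csv")
        print(table.to_markdown())
        print()
    print(f"wrote evidence tables under {args.outdir}")


if __name__ == "__main__":
    main()
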