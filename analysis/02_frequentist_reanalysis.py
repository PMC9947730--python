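"""Reproduce the trial's frequentist results from its printed aggregates.

Reconstructs death counts from the published rates, computes risk ratio,
risk difference (both count- and rate-based paths), odds ratio, and the
two-sided Mantel-Haenszel test, and writes one row per endpoint.
"""

import argparse
from pathlib import Path

import pandas as pd

from bayesrct.frequentist import analyze_counts, rates_based_comparison
from bayesrct.trial_data import PROPPR_ARM_SIZES, PROPPR_RATES, proppr_counts


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for endpoint in ("24h", "30d"):
        a, n1, c, n2 = proppr_counts(endpoint)
        res = analyze_counts(endpoint, a, n1, c, n2)
        rate_t, rate_c = PROPPR_RATES[endpoint]
        rd_rates, rr_rates = rates_based_comparison(
            rate_t, PROPPR_ARM_SIZES[0], rate_c, PROPPR_ARM_SIZES[1]
        )
        rows.append(
            {
                "endpoint": endpoint,
                "deaths_t": a, "n_t": n1, "deaths_c": c, "n_c": n2,
                "risk_ratio": res.risk_ratio.estimate,
                "rr_lower": res.risk_ratio.lower, "rr_upper": res.risk_ratio.upper,
                "risk_diff": res.risk_difference.estimate,
                "rd_lower": res.risk_difference.lower,
                "rd_upper": res.risk_difference.upper,
                "odds_ratio": res.odds_ratio.estimate,
                "mh_chi2": res.mh_chi2, "p_value": res.p_value,
                "risk_diff_from_rates": rd_rates.estimate,
                "risk_ratio_from_rates": rr_rates.estimate,
            }
        )
        print(
            f"{endpoint}: RR {res.risk_ratio.estimate:.2f} "
            f"[{res.risk_ratio.lower:.2f}, {res.risk_ratio.upper:.2f}]; "
            f"difference {100 * res.risk_difference.estimate:.1f}% "
            f"[{100 * res.risk_difference.lower:.1f}%, "
            f"{100 * res.risk_difference.upper:.1f}%]; "
            f"P = {res.p_value:.2f} "
            f"(rate-based difference {100 * rd_rates.estimate:.1f}%, "
            f"RR {rr_rates.estimate:.2f})"
        )
    out = args.outdir / "frequentist.csv"
    pd.DataFrame(rows).to_csv(out, index=False, lineterminator="\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
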