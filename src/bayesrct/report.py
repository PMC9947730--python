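"""End-to-end pipeline: paired frequentist and Bayesian results per endpoint.

``run_reanalysis`` accepts either a patient-level dataset (stratified by its
real sites) or an aggregate block of printed rates and arm sizes (counts
reconstructed, pooled single stratum), runs the classical estimators and
the hierarchical Bayesian fit for both endpoints, and assembles a
side-by-side comparison report with full provenance.  All displayed rounded
values are derived from stored full-precision values at render time.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

import bayesrct
from bayesrct.evidence import (
    DEFAULT_THRESHOLDS,
    EvidenceRow,
    EvidenceTable,
    LevelOfEvidence,
    bayes_factor,
    credible_interval,
    evidence_table,
    format_bayes_factor,
    jeffreys_level,
    threshold_probability,
)
from bayesrct.frequentist import (
    EstimateCI,
    FrequentistResult,
    analyze_counts,
    rates_based_comparison,
)
from bayesrct.hierarchical import (
    McmcSettings,
    PosteriorDraws,
    PriorSpec,
    effect_draws,
    fit_model,
)
from bayesrct.trial_data import (
    ENDPOINTS,
    PROPPR_ARM_SIZES,
    PROPPR_RATES,
    StratifiedTable,
    TrialDataset,
    reconstruct_counts,
    stratified_from_counts,
    summarize,
)


class ReportError(ValueError):
    """Invalid report inputs."""


#: Aggregate preset: endpoint -> (treatment rate, n_t, control rate, n_c).
PROPPR_AGGREGATES: dict[str, tuple[float, int, float, int]] = {
    ep: (PROPPR_RATES[ep][0], PROPPR_ARM_SIZES[0], PROPPR_RATES[ep][1], PROPPR_ARM_SIZES[1])
    for ep in ENDPOINTS
}


@dataclass(frozen=True)
class BayesianSummary:
    """Posterior summaries for one endpoint on the effect-ratio scale exp(beta)."""

    median: float
    cri_lower: float
    cri_upper: float
    prob_superiority: float
    mc_se: float
    bayes_factor: float
    loe: LevelOfEvidence
    evidence: EvidenceTable
    max_rhat: float
    min_ess: float


@dataclass(frozen=True)
class EndpointComparison:
    endpoint: str
    frequentist: FrequentistResult
    bayesian: BayesianSummary
    # rate-based classical point estimates (the published 30-day path);
    # populated only when the input is an aggregate block
    rates_risk_difference: EstimateCI | None = None
    rates_risk_ratio: EstimateCI | None = None


@dataclass
class ComparisonReport:
    endpoints: dict[str, EndpointComparison]
    provenance: dict = field(default_factory=dict)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "endpoints": {k: asdict(v) for k, v in self.endpoints.items()},
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ComparisonReport":
        endpoints = {}
        for ep, block in data["endpoints"].items():
            fr = dict(block["frequentist"])
            for key in ("risk_difference", "risk_ratio", "odds_ratio"):
                fr[key] = EstimateCI(*fr[key])
            bay = dict(block["bayesian"])
            bay["loe"] = LevelOfEvidence(*bay["loe"])
            ev = bay["evidence"]
            bay["evidence"] = EvidenceTable(
                ev["endpoint"],
                [
                    EvidenceRow(
                        r["threshold"], r["probability"], r["mc_se"],
                        r["bayes_factor"], LevelOfEvidence(*r["loe"]),
                    )
                    for r in ev["rows"]
                ],
            )
            endpoints[ep] = EndpointComparison(
                endpoint=block["endpoint"],
                frequentist=FrequentistResult(**fr),
                bayesian=BayesianSummary(**bay),
                rates_risk_difference=(
                    EstimateCI(*block["rates_risk_difference"])
                    if block.get("rates_risk_difference") else None
                ),
                rates_risk_ratio=(
                    EstimateCI(*block["rates_risk_ratio"])
                    if block.get("rates_risk_ratio") else None
                ),
            )
        return cls(endpoints, dict(data.get("provenance", {})))


def summaries_from_draws(
    draws: PosteriorDraws,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    level: float = 0.95,
) -> BayesianSummary:
    """Evidence summaries from stored draws; no refit involved."""
    effect = effect_draws(draws, "odds-ratio")
    lo, med, hi = credible_interval(effect, level)
    p_sup, mc_se = threshold_probability(effect, 1.0)
    bf = bayes_factor(p_sup)
    diag = draws.diagnostics
    return BayesianSummary(
        median=med,
        cri_lower=lo,
        cri_upper=hi,
        prob_superiority=p_sup,
        mc_se=mc_se,
        bayes_factor=bf,
        loe=jeffreys_level(bf),
        evidence=evidence_table(effect, thresholds, endpoint=draws.endpoint),
        max_rhat=diag.max_rhat if diag else float("nan"),
        min_ess=min(diag.ess.values()) if diag else float("nan"),
    )


def _dataset_checksum(dataset: TrialDataset) -> str:
    csv = dataset.to_frame().to_csv(index=False, lineterminator="\n")
    return hashlib.sha256(csv.encode()).hexdigest()


def run_reanalysis(
    dataset: TrialDataset | None = None,
    aggregates: Mapping[str, tuple[float, int, float, int]] | None = None,
    priors: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    level: float = 0.95,
    endpoints: Sequence[str] = ENDPOINTS,
) -> ComparisonReport:
    """Full side-by-side reanalysis for the requested endpoints.

    Exactly one of ``dataset`` (patient-level records, stratified by site)
    or ``aggregates`` (endpoint -> (rate_t, n_t, rate_c, n_c); counts
    reconstructed, pooled single stratum) must be given.  Deterministic for
    a fixed ``mcmc.seed``; each endpoint's fit uses a seed offset derived
    from it.
    """
    if (dataset is None) == (aggregates is None):
        raise ReportError("provide exactly one of dataset or aggregates")
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcSettings()
    comparisons: dict[str, EndpointComparison] = {}
    for k, ep in enumerate(endpoints):
        ep_seed = (mcmc.seed + k) % 2**31
        ep_mcmc = replace(mcmc, seed=ep_seed)
        rates_rd = rates_rr = None
        if dataset is not None:
            treatment, control, table = summarize(dataset, ep)
            a, n1 = treatment.deaths, treatment.n
            c, n2 = control.deaths, control.n
        else:
            if ep not in aggregates:
                raise ReportError(f"aggregates missing endpoint {ep!r}")
            rate_t, n1, rate_c, n2 = aggregates[ep]
            a = reconstruct_counts(rate_t, n1)
            c = reconstruct_counts(rate_c, n2)
            table = stratified_from_counts(ep, a, n1, c, n2, n_sites=1)
            rates_rd, rates_rr = rates_based_comparison(rate_t, n1, rate_c, n2, level)
        freq = analyze_counts(ep, a, n1, c, n2, level, table=table)
        draws = fit_model(table, priors, ep_mcmc)
        bayes = summaries_from_draws(draws, thresholds, level)
        comparisons[ep] = EndpointComparison(
            endpoint=ep,
            frequentist=freq,
            bayesian=bayes,
            rates_risk_difference=rates_rd,
            rates_risk_ratio=rates_rr,
        )
    provenance = {
        "package": "bayesrct",
        "version": bayesrct.__version__,
        "numpy": np.__version__,
        "seed": mcmc.seed,
        "chains": mcmc.chains,
        "burn_in": mcmc.burn_in,
        "saved_per_chain": mcmc.saved_per_chain,
        "priors": repr(priors),
        "thresholds": list(thresholds),
        "level": level,
        "input": (
            {"kind": "dataset", "sha256": _dataset_checksum(dataset)}
            if dataset is not None
            else {"kind": "aggregates", "values": {k: list(v) for k, v in aggregates.items()}}
        ),
    }
    return ComparisonReport(comparisons, provenance)


# ---------------------------------------------------------------------------
# Rendering


def _fmt_pct(x: float) -> str:
    return f"{100 * x:.1f}%"


def _fmt_ci(ci: EstimateCI, pct: bool = False) -> str:
    f = _fmt_pct if pct else (lambda v: f"{v:.2f}")
    return f"{f(ci.estimate)} [{f(ci.lower)}, {f(ci.upper)}]"


def report_markdown(report: ComparisonReport) -> str:
    lines = ["# Frequentist vs Bayesian side-by-side comparison", ""]
    lines.append("| Endpoint | Frequentist | Bayesian |")
    lines.append("|---|---|---|")
    for ep, cmp_ in report.endpoints.items():
        fr, ba = cmp_.frequentist, cmp_.bayesian
        freq_txt = (
            f"{_fmt_pct(fr.rate_treatment)} vs {_fmt_pct(fr.rate_control)}; "
            f"RR {_fmt_ci(fr.risk_ratio)}; "
            f"difference {_fmt_ci(fr.risk_difference, pct=True)}; "
            f"P = {fr.p_value:.2f}"
        )
        bayes_txt = (
            f"{round(100 * ba.prob_superiority):d}% probability that 1:1:1 is "
            f"superior to 1:1:2; effect ratio {ba.median:.2f} "
            f"[95% CrI, {ba.cri_lower:.2f}-{ba.cri_upper:.2f}]; "
            f"BF {format_bayes_factor(ba.bayes_factor)} ({ba.loe})"
        )
        lines.append(f"| {ep} mortality | {freq_txt} | {bayes_txt} |")
    lines.append("")
    lines.append("## Evidence spectrum")
    for ep, cmp_ in report.endpoints.items():
        lines.append("")
        lines.append(cmp_.bayesian.evidence.to_markdown())
    lines.append("")
    lines.append("## Provenance")
    for key, value in report.provenance.items():
        lines.append(f"- {key}: {value}")
    lines.append("")
    return "\n".join(lines)


RENDER_FORMATS = ("markdown", "json", "csv")


def render_report(
    report: ComparisonReport, format: str, out_dir: str | Path
) -> list[Path]:
    """Write the report in the requested format; returns the files written.

    ``markdown``: the side-by-side table plus evidence grids; ``json``:
    full precision, round-trippable through ``ComparisonReport.from_dict``;
    ``csv``: one evidence table per endpoint.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "markdown":
        path = out_dir / "report.md"
        path.write_text(report_markdown(report))
        written.append(path)
    elif format == "json":
        path = out_dir / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2))
        written.append(path)
    elif format == "csv":
        for ep, cmp_ in report.endpoints.items():
            path = out_dir / f"evidence_{ep}.csv"
            cmp_.bayesian.evidence.to_csv(path)
            written.append(path)
    else:
        raise ReportError(f"unknown format {format!r}; expected one of {RENDER_FORMATS}")
    return written


def plot_effect_histogram(
    effect: Sequence[float], path: str | Path, endpoint: str = ""
) -> Path:
    """Basic histogram of posterior effect-ratio draws (no styling)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.hist(np.asarray(effect), bins=80, density=True)
    ax.axvline(1.0, linestyle="--")
    ax.set_xlabel("effect ratio exp(beta)")
    ax.set_ylabel("posterior density")
    if endpoint:
        ax.set_title(f"{endpoint} mortality")
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
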