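"""Per-gene survival association of qualifying-variant carriage.

Cox proportional-hazards models of carrier status against time to first
treatment (TTFT) and overall survival (OS), restricted to genes carried by
more than 1% of CLL cases.  TTFT models adjust for IGHV mutation status and
tumor stage at diagnosis; OS models for IGHV status and age at diagnosis
(an alternative age + CLL/MBL adjustment set is selectable).  Ties are
handled with the Efron approximation; carrier Wald p-values are BH-corrected
across genes within each outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from lymphgerm.burden import fdr_adjust

logger = logging.getLogger(__name__)

OUTCOMES = ("TTFT", "OS")

#: Default covariate sets per outcome.
DEFAULT_COVARIATES: dict[str, tuple[str, ...]] = {
    "TTFT": ("ighv_unmutated", "stage"),
    "OS": ("ighv_unmutated", "age_dx"),
}

#: Alternative adjustment set (age + CLL/MBL precursor status).
ALT_COVARIATES: tuple[str, ...] = ("age_dx", "is_mbl")


@dataclass(frozen=True)
class CoxResult:
    gene: str
    outcome: str
    n_carriers: int
    n_used: int
    hr: float
    ci95: tuple[float, float]
    p: float
    q: float | None = None
    covariates: tuple[str, ...] = ()
    converged: bool = True


def eligible_genes(
    carriers: Mapping[str, set[str]] | Mapping[str, Sequence[str]],
    n_cll: int,
    min_frequency: float = 0.01,
) -> set[str]:
    """Genes carried by strictly more than ``min_frequency`` of CLL cases."""
    if n_cll <= 0:
        raise ValueError("n_cll must be positive")
    return {
        gene
        for gene, pts in carriers.items()
        if len(set(pts)) / n_cll > min_frequency
    }


def _outcome_columns(outcome: str) -> tuple[str, str]:
    if outcome == "TTFT":
        return "ttft_time", "ttft_event"
    if outcome == "OS":
        return "os_time", "os_event"
    raise ValueError(f"unknown outcome {outcome!r}")


def cox_association(
    records: pd.DataFrame,
    carrier_patients: set[str],
    outcome: str,
    gene: str = "",
    covariates: Sequence[str] | None = None,
) -> CoxResult:
    """Cox PH fit of carrier status on one outcome with covariate adjustment.

    ``records`` needs columns ``patient``, the outcome's time/event pair, and
    the covariates.  Patients with missing covariates or times are dropped
    per model (logged).  Raises ``ValueError`` on a degenerate design (all or
    no patients carriers, or < 2 events); non-convergence returns a result
    flagged ``converged=False`` so callers can exclude it from FDR.
    """
    time_col, event_col = _outcome_columns(outcome)
    covariates = tuple(
        covariates if covariates is not None else DEFAULT_COVARIATES[outcome]
    )
    needed = ["patient", time_col, event_col, *covariates]
    df = records.loc[:, needed].copy()
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.info(
            "%s/%s: dropped %d patients with missing covariates",
            gene, outcome, n_before - len(df),
        )
    df["carrier"] = df["patient"].isin(carrier_patients).astype(float)
    n_carriers = int(df["carrier"].sum())
    if n_carriers == 0 or n_carriers == len(df):
        raise ValueError(
            f"{gene}/{outcome}: carrier indicator has no contrast "
            f"({n_carriers}/{len(df)} carriers)"
        )
    if df[event_col].sum() < 2:
        raise ValueError(f"{gene}/{outcome}: fewer than 2 events")
    model_df = df[["carrier", *covariates, time_col, event_col]].astype(float)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(model_df, duration_col=time_col, event_col=event_col)
    except (ConvergenceError, ValueError) as exc:
        logger.warning("%s/%s: Cox fit failed (%s)", gene, outcome, exc)
        return CoxResult(
            gene=gene, outcome=outcome, n_carriers=n_carriers, n_used=len(df),
            hr=float("nan"), ci95=(float("nan"), float("nan")), p=float("nan"),
            covariates=covariates, converged=False,
        )
    coef = float(cph.params_["carrier"])
    se = float(cph.standard_errors_["carrier"])
    hr = float(np.exp(coef))
    with np.errstate(over="ignore"):
        ci = (float(np.exp(coef - 1.959963984540054 * se)),
              float(np.exp(coef + 1.959963984540054 * se)))
    p = float(cph.summary.loc["carrier", "p"])
    return CoxResult(
        gene=gene, outcome=outcome, n_carriers=n_carriers, n_used=len(df),
        hr=hr, ci95=ci, p=p, covariates=covariates,
    )


def screen_genes(
    records: pd.DataFrame,
    carriers: Mapping[str, set[str]],
    outcome: str,
    covariates: Sequence[str] | None = None,
    min_frequency: float = 0.01,
    n_cll: int | None = None,
) -> list[CoxResult]:
    """One Cox model per eligible gene with BH q-values within outcome.

    Genes failing eligibility, degenerate designs, and non-converged fits are
    excluded from the FDR set (the latter are still returned, flagged).
    """
    n_cll = n_cll if n_cll is not None else len(records)
    eligible = eligible_genes(carriers, n_cll, min_frequency)
    results: list[CoxResult] = []
    for gene in sorted(eligible):
        try:
            res = cox_association(
                records, set(carriers[gene]), outcome, gene=gene, covariates=covariates
            )
        except ValueError as exc:
            logger.warning("skipping %s: %s", gene, exc)
            continue
        results.append(res)
    ok = [r for r in results if r.converged and np.isfinite(r.p)]
    if ok:
        qs = fdr_adjust([r.p for r in ok])
        q_by_gene = {r.gene: float(q) for r, q in zip(ok, qs)}
        results = [
            CoxResult(
                gene=r.gene, outcome=r.outcome, n_carriers=r.n_carriers,
                n_used=r.n_used, hr=r.hr, ci95=r.ci95, p=r.p,
                q=q_by_gene.get(r.gene), covariates=r.covariates,
                converged=r.converged,
            )
            for r in results
        ]
    results.sort(key=lambda r: (not r.converged, r.p if np.isfinite(r.p) else np.inf))
    return results


def results_to_frame(results: Sequence[CoxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "outcome": r.outcome,
                "n_carriers": r.n_carriers,
                "n_used": r.n_used,
                "hr": r.hr,
                "ci95_low": r.ci95[0],
                "ci95_high": r.ci95[1],
                "p": r.p,
                "q": r.q,
                "covariates": "+".join(r.covariates),
                "converged": r.converged,
            }
            for r in results
        ],
        columns=[
            "gene", "outcome", "n_carriers", "n_used", "hr",
            "ci95_low", "ci95_high", "p", "q", "covariates", "converged",
        ],
    )
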