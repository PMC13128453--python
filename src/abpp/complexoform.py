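"""Complexoform-restricted liganding: discordance model and comparisons.

A covalent probe that only reacts with one complexation state of its target
produces discordant readouts between the two ABPP tracks: protein-directed
competition reports engagement of the probe-reactive complexoform
(``c_protein = e``), while cysteine-directed competition reports engagement
of the whole scout-probe-reactive pool (``c_site = f * e``, with ``f`` the
fraction of that pool residing in the reactive complexoform).  The
discordance ``D = c_protein - c_site`` flags complex-restricted targets and
``f_hat = c_site / c_protein`` estimates ``f``.

The comparative operation regresses per-protein stereoselective enrichment
between two cell states (e.g. parental vs. partner-knockout) on log scale
and flags targets whose enrichment collapses in one state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

F_TOL = 1e-9


# ---------------------------------------------------------------------------
# discordance and fraction estimation
# ---------------------------------------------------------------------------


def discordance(
    protein_calls: pd.DataFrame,
    site_calls: pd.DataFrame,
    protein_floor: float = 0.5,
    discordance_min: float = 0.3,
) -> pd.DataFrame:
    """Per matched (protein, site): discordance and complexoform-fraction
    estimate.

    Competition percentages from both tracks enter as fractions in [0, 1].
    Each protein is matched to its best-competing quantified site (the
    presumptive probe-modified cysteine); flat sibling sites of the same
    protein are not candidate complexoform signatures.  A pair is ``flagged``
    when ``c_protein >= protein_floor`` and ``D >= discordance_min``.
    Proteins without a matched quantified site are reported with ``c_site``
    undefined and never flagged.  ``f_hat`` values above 1 (site competition
    exceeding protein competition, i.e. noise) are clamped with
    ``f_saturated`` set.
    """
    prot = protein_calls.set_index("protein_accession")
    rows = []
    site_by_prot = (
        site_calls.groupby("protein_accession") if len(site_calls) else None
    )
    for acc, pcall in prot.iterrows():
        c_protein = pcall["max_competition_pct"] / 100.0
        sites = (
            site_by_prot.get_group(acc)
            if site_by_prot is not None and acc in site_by_prot.groups
            else None
        )
        if sites is not None:
            sites = sites.dropna(subset=["max_competition_pct"])
            if len(sites):
                sites = sites.loc[[sites["max_competition_pct"].idxmax()]]
            else:
                sites = None
        if sites is None or not len(sites):
            rows.append(
                {
                    "protein_accession": acc,
                    "site_key": "",
                    "residue_index": np.nan,
                    "c_protein": c_protein,
                    "c_site": np.nan,
                    "discordance": np.nan,
                    "f_hat": np.nan,
                    "f_saturated": False,
                    "flagged": False,
                }
            )
            continue
        for _, s in sites.iterrows():
            c_site = s["max_competition_pct"] / 100.0
            d = c_protein - c_site
            if np.isfinite(c_protein) and c_protein > protein_floor:
                f_hat = c_site / c_protein
            else:
                f_hat = np.nan
            saturated = np.isfinite(f_hat) and f_hat > 1.0 + F_TOL
            if np.isfinite(f_hat):
                f_hat = float(np.clip(f_hat, 0.0, 1.0))
            flagged = (
                np.isfinite(c_protein)
                and np.isfinite(d)
                and c_protein >= protein_floor
                and d >= discordance_min
            )
            rows.append(
                {
                    "protein_accession": acc,
                    "site_key": s.get("site_key", ""),
                    "residue_index": s.get("residue_index", np.nan),
                    "c_protein": c_protein,
                    "c_site": c_site,
                    "discordance": d,
                    "f_hat": f_hat,
                    "f_saturated": bool(saturated),
                    "flagged": bool(flagged),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FractionEstimate:
    """Reactive-complexoform fraction with delta-method uncertainty."""

    f_hat: float
    se: float
    status: str  # "ok", "saturated" or "undefined"

    @property
    def defined(self) -> bool:
        return self.status != "undefined"


def estimate_fraction(
    c_total: float,
    c_complex: float,
    cv_total: float = 0.0,
    cv_complex: float = 0.0,
    floor: float = 0.25,
) -> FractionEstimate:
    """``f_hat = c_total / c_complex``: fraction of the scout-reactive pool in
    the probe-reactive complexoform.

    ``c_total`` is the whole-pool engagement readout, ``c_complex`` the
    complex-restricted readout; below ``floor`` the quotient is unstable and
    the estimate is reported as undefined.  Uncertainty propagates the input
    CVs to first order assuming the two readouts are independent.
    """
    if not np.isfinite(c_complex) or c_complex <= floor:
        return FractionEstimate(np.nan, np.nan, "undefined")
    f = c_total / c_complex
    se = abs(f) * float(np.hypot(cv_total, cv_complex))
    if f > 1.0 + F_TOL:
        return FractionEstimate(1.0, se, "saturated")
    return FractionEstimate(float(np.clip(f, 0.0, 1.0)), se, "ok")


# ---------------------------------------------------------------------------
# comparative cross-state regression
# ---------------------------------------------------------------------------


@dataclass
class ComparativeResult:
    """Two-pass log-scale OLS of state-2 vs state-1 enrichment."""

    slope: float
    intercept: float
    per_protein: pd.DataFrame  # log2 values, residuals, state ratio, outlier flag
    outliers: list[str]
    n_fit: int


def comparative_regression(
    state1: pd.DataFrame,
    state2: pd.DataFrame,
    prior_flags: tuple[str, ...] = (),
    resid_cut: float = 3.0,
) -> ComparativeResult:
    """Regress per-protein stereoselective enrichment across two cell states.

    Inputs carry ``protein_accession`` and ``enrichment_ratio`` (the
    probe-B/probe-A enrichment ratio in that state).  Fit is ordinary least
    squares on log2 scale, two-pass: fit all shared proteins, flag points
    with externally studentized residual beyond ``resid_cut`` or named in
    ``prior_flags``, then refit without them.  The reported per-protein
    ``state_ratio`` is state1/state2 enrichment.

    Raises ``ValueError`` with fewer than 3 shared proteins.
    """
    merged = state1.merge(
        state2, on="protein_accession", suffixes=("_1", "_2")
    ).dropna(subset=["enrichment_ratio_1", "enrichment_ratio_2"])
    merged = merged[
        (merged["enrichment_ratio_1"] > 0) & (merged["enrichment_ratio_2"] > 0)
    ].reset_index(drop=True)
    if len(merged) < 3:
        raise ValueError("comparative regression requires >=3 shared proteins")
    x = np.log2(merged["enrichment_ratio_1"].to_numpy(float))
    y = np.log2(merged["enrichment_ratio_2"].to_numpy(float))

    first = sm.OLS(y, sm.add_constant(x)).fit()
    if first.mse_resid < 1e-24:  # degenerate: perfectly colinear states
        student = np.zeros(len(x))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            student = first.get_influence().resid_studentized_external
        student = np.nan_to_num(student, nan=0.0, posinf=0.0, neginf=0.0)
    out_mask = np.abs(student) > resid_cut
    out_mask |= merged["protein_accession"].isin(prior_flags).to_numpy()
    if out_mask.sum() > len(merged) - 3:  # keep the refit solvable
        out_mask = merged["protein_accession"].isin(prior_flags).to_numpy()
    second = sm.OLS(y[~out_mask], sm.add_constant(x[~out_mask])).fit()
    intercept, slope = second.params

    per_protein = pd.DataFrame(
        {
            "protein_accession": merged["protein_accession"],
            "log2_enrichment_state1": x,
            "log2_enrichment_state2": y,
            "residual": y - (intercept + slope * x),
            "studentized_residual_pass1": student,
            "state_ratio": merged["enrichment_ratio_1"] / merged["enrichment_ratio_2"],
            "outlier": out_mask,
        }
    )
    return ComparativeResult(
        slope=float(slope),
        intercept=float(intercept),
        per_protein=per_protein,
        outliers=list(merged.loc[out_mask, "protein_accession"]),
        n_fit=int((~out_mask).sum()),
    )


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class ComplexoformDetector(BaseEstimator):
    """Flags complexoform-restricted liganding from paired track outputs.

    ``fit(protein_calls, site_calls)`` exposes ``estimates_`` (one row per
    matched protein/site with discordance, ``f_hat`` and the flag) and
    ``flagged_`` (the flagged subset).
    """

    def __init__(self, protein_floor: float = 0.5, discordance_min: float = 0.3):
        self.protein_floor = protein_floor
        self.discordance_min = discordance_min

    def fit(self, protein_calls: pd.DataFrame, site_calls: pd.DataFrame):
        self.estimates_ = discordance(
            protein_calls,
            site_calls,
            protein_floor=self.protein_floor,
            discordance_min=self.discordance_min,
        )
        self.flagged_ = self.estimates_[self.estimates_["flagged"]].reset_index(
            drop=True
        )
        return self

    def fit_predict(self, protein_calls, site_calls) -> pd.DataFrame:
        return self.fit(protein_calls, site_calls).estimates_
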