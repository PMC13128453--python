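"""Protein-directed competitive ABPP quantification and liganding calls.

Workflow (per TMT plex): each PSM's reporter intensities are converted to
fractional ratios (intensity / total over channels); PSMs failing the quality
cascade (summed intensity < 10,000, signal-to-noise < 1.0 or isolation
purity < 0.5) are excluded with a logged reason; surviving PSM fractions are
summed per protein and normalized to 100 across channels (an excluded plex
channel is temporarily replaced by a duplicate of its replicate partner so
the plex stays balanced, then removed); proteins supported by fewer than two
distinct peptides are excluded; proteins whose most enriched DMSO+alkyne
condition has a replicate CV >= 0.2 are excluded.

A protein is called liganded when, for at least one alkyne stereoprobe, its
enantioselective enrichment (ratio of DMSO+alkyne condition means between
enantiomers) exceeds 2-fold and competitive blockade of that enrichment by
the stereomatched non-alkyne competitor exceeds 50% — in the protein track
itself or, optionally, in matched cysteine-track evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import ExperimentDesign, PSMTable, PairingReport, validate_pairing


# ---------------------------------------------------------------------------
# PSM-level operations
# ---------------------------------------------------------------------------


def psm_fractional_ratios(
    table: PSMTable, design: ExperimentDesign | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-PSM channel fractions (intensity / total over included channels).

    Missing cells (NaN) do not contribute to the total.  PSMs whose total is
    zero are dropped and reported in the returned log.  Returns
    ``(fractions, dropped_log)``; fractions carry one ``frac_<label>`` column
    per included channel and sum to 1 per row.
    """
    design = design or table.design
    labels = design.included_labels
    inten = table.intensity_matrix(labels)
    totals = np.nansum(inten, axis=1)
    zero = totals == 0
    frac = np.full_like(inten, np.nan)
    frac[~zero] = inten[~zero] / totals[~zero, None]
    out = table.df.loc[~zero, ["psm_id", "protein_accession", "peptide_sequence"]].copy()
    for j, lab in enumerate(labels):
        out[f"frac_{lab}"] = frac[~zero, j]
    dropped = pd.DataFrame(
        {"psm_id": table.df.loc[zero, "psm_id"], "reason": "zero_total_intensity"}
    )
    return out.reset_index(drop=True), dropped.reset_index(drop=True)


def filter_psms(
    table: PSMTable,
    min_intensity: float = 10_000.0,
    min_s2n: float = 1.0,
    min_purity: float = 0.5,
    strict_metadata: bool = False,
) -> tuple[PSMTable, pd.DataFrame]:
    """Apply the PSM quality cascade; thresholds are strict ``<`` rules.

    A PSM is excluded when its summed reporter intensity is < ``min_intensity``,
    its signal-to-noise < ``min_s2n`` or its isolation purity < ``min_purity``.
    Missing purity/S-N metadata passes with a warning unless
    ``strict_metadata`` is set.  Returns ``(retained, exclusion_log)``; the
    log names every rule that fired for each dropped PSM.
    """
    df = table.df
    totals = np.nansum(table.intensity_matrix(), axis=1)
    s2n = pd.to_numeric(df["signal_to_noise"], errors="coerce")
    purity = pd.to_numeric(df["isolation_purity"], errors="coerce")

    rules = {
        "low_summed_intensity": totals < min_intensity,
        "low_signal_to_noise": np.where(s2n.isna(), strict_metadata, s2n < min_s2n),
        "low_isolation_purity": np.where(purity.isna(), strict_metadata, purity < min_purity),
    }
    fired = pd.DataFrame(rules, index=df.index)
    drop = fired.any(axis=1)
    log = pd.DataFrame(
        {
            "psm_id": df.loc[drop, "psm_id"],
            "rules": fired.loc[drop].apply(
                lambda r: ",".join(k for k, v in r.items() if v), axis=1
            ),
        }
    ).reset_index(drop=True)
    return PSMTable(df.loc[~drop], table.design), log


# ---------------------------------------------------------------------------
# protein roll-up and normalization
# ---------------------------------------------------------------------------


def rollup_normalize(
    table: PSMTable,
    design: ExperimentDesign | None = None,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Sum PSM fractions per protein and normalize channel signals to 100.

    For every excluded design channel, its replicate partner's signal is
    temporarily duplicated during the sum-to-100 normalization (keeping the
    plex balanced) and the duplicate is then removed, so the output carries
    one ``norm_<label>`` column per *included* channel and its row sum equals
    100 minus the duplicated partners' normalized values.

    Proteins with fewer than ``min_peptides`` distinct peptides are flagged
    ``excluded_low_evidence`` (kept in the table, excluded downstream).
    """
    design = design or table.design
    labels = design.included_labels
    fracs, _ = psm_fractional_ratios(table, design)
    frac_cols = [f"frac_{l}" for l in labels]
    grouped = fracs.groupby("protein_accession")
    signal = grouped[frac_cols].sum(min_count=1)
    signal = signal.fillna(0.0)
    n_psms = grouped.size()
    n_peptides = grouped["peptide_sequence"].nunique()

    sig = signal.to_numpy(dtype=float)
    dup_idx = [
        labels.index(design.replicate_partner(c.label).label)
        for c in design.channels
        if c.excluded
    ]
    totals = sig.sum(axis=1) + (sig[:, dup_idx].sum(axis=1) if dup_idx else 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = 100.0 * sig / totals[:, None]

    out = pd.DataFrame(
        {"n_psms": n_psms, "n_peptides": n_peptides}, index=signal.index
    )
    for j, lab in enumerate(labels):
        out[f"norm_{lab}"] = norm[:, j]
    out["excluded_low_evidence"] = out["n_peptides"] < min_peptides
    out.index.name = "protein_accession"
    return out.reset_index()


def condition_statistics(
    profiles: pd.DataFrame, design: ExperimentDesign
) -> pd.DataFrame:
    """Replicate mean and CV per (protein, role, compound) condition.

    CV = sample s.d. / mean; undefined (NaN) for single-replicate conditions.
    """
    rows = []
    for (role, compound), chans in design.conditions().items():
        cols = [f"norm_{c.label}" for c in chans]
        vals = profiles[cols].to_numpy(dtype=float)
        mean = vals.mean(axis=1)
        if vals.shape[1] > 1:
            sd = vals.std(axis=1, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cv = np.where(mean > 0, sd / mean, np.nan)
        else:
            cv = np.full(len(profiles), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "protein_accession": profiles["protein_accession"],
                    "role": role,
                    "compound_id": compound,
                    "mean": mean,
                    "cv": cv,
                    "n_replicates": vals.shape[1],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def replicate_screen(
    profiles: pd.DataFrame,
    design: ExperimentDesign,
    max_cv: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude proteins with CV >= ``max_cv`` in their most enriched
    DMSO+alkyne condition (most enriched chosen per protein by replicate
    mean; ties broken by declaration order).  Single-replicate conditions
    have undefined CV and are retained with ``cv_warning`` set.

    Returns ``(profiles with flags, condition_stats)``.
    """
    stats = condition_statistics(profiles, design)
    alk = stats[stats["role"] == "dmso_plus_alkyne"]
    # declaration order for tie-breaks
    order = {
        (r, c): i for i, (r, c) in enumerate(design.conditions())
    }
    alk = alk.assign(_ord=[order[("dmso_plus_alkyne", c)] for c in alk["compound_id"]])
    alk = alk.sort_values(
        ["protein_accession", "mean", "_ord"], ascending=[True, False, True]
    )
    top = alk.groupby("protein_accession", sort=False).first()
    prof = profiles.set_index("protein_accession")
    top = top.reindex(prof.index)
    prof["top_alkyne_condition"] = top["compound_id"]
    prof["top_alkyne_cv"] = top["cv"]
    prof["cv_warning"] = top["cv"].isna()
    prof["excluded_high_cv"] = top["cv"] >= max_cv
    return prof.reset_index(), stats


# ---------------------------------------------------------------------------
# selectivity and classification
# ---------------------------------------------------------------------------


@dataclass
class ClassificationThresholds:
    min_enantioselectivity: float = 2.0  # strict: "more than twofold"
    min_competition_pct: float = 50.0  # strict: ">50% blockade"
    es_cap: float = 100.0  # ceiling for ratios over zero enrichment
    max_cv: float = 0.2  # sets variability_flag, never auto-excludes


def selectivity_and_classify(
    profiles: pd.DataFrame,
    design: ExperimentDesign,
    pairing: PairingReport | None = None,
    thresholds: ClassificationThresholds | None = None,
    site_competitions: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-stereoprobe selectivity statistics and liganding calls.

    Enrichment of a stereoprobe is the replicate-mean normalized signal of
    its DMSO+alkyne condition.  Enantioselectivity is the enrichment ratio
    between enantiomers (capped, with a saturation flag, when the enantiomer
    enrichment is zero); diastereoselectivity divides by the arithmetic mean
    of the two diastereomers' enrichments.  Competition (%) is
    ``100 * (1 - competitor-condition mean / matched DMSO+alkyne mean)``,
    floored at 0 and capped at 100 for reporting (raw value retained).

    ``site_competitions`` may carry cysteine-track evidence (columns
    ``protein_accession``, ``compound_id`` (the competitor),
    ``competition_pct``); the competition criterion is then satisfied by
    either track, as recorded in ``evidence_route``.

    Proteins flagged ``excluded_low_evidence`` or ``excluded_high_cv`` do not
    reach classification.  Returns ``(selectivity, calls)``.
    """
    thresholds = thresholds or ClassificationThresholds()
    pairing = pairing or validate_pairing(design)
    stats = condition_statistics(profiles, design)
    mask = pd.Series(True, index=profiles.index)
    for col in ("excluded_low_evidence", "excluded_high_cv"):
        if col in profiles.columns:
            mask &= ~(profiles[col] == True)  # noqa: E712 (NaN counts as not excluded)
    eligible = profiles.loc[mask, "protein_accession"]
    stats = stats[stats["protein_accession"].isin(set(eligible))]

    mean_w = stats.pivot_table(
        index="protein_accession", columns=["role", "compound_id"], values="mean"
    )
    cv_w = stats.pivot_table(
        index="protein_accession", columns=["role", "compound_id"], values="cv",
        dropna=False,
    )

    alkynes = sorted(
        {c.compound_id for c in design.included_channels if c.role == "dmso_plus_alkyne"}
    )
    competitor_for = {
        alk: comp for comp, alk in design.stereochemistry.competitor_of.items()
    }
    site_idx: dict[tuple[str, str], float] = {}
    if site_competitions is not None and len(site_competitions):
        best = site_competitions.groupby(["protein_accession", "compound_id"])[
            "competition_pct"
        ].max()
        site_idx = best.to_dict()

    sel_rows, call_rows = [], []
    for acc in mean_w.index:
        def _get(wide: pd.DataFrame, key: tuple[str, str]) -> float:
            v = wide.loc[acc].get(key, np.nan)
            return float(v) if v is not None else np.nan

        enrich = {a: _get(mean_w, ("dmso_plus_alkyne", a)) for a in alkynes}
        per_probe = {}
        for a in alkynes:
            e_a = enrich[a]
            partner = pairing.enantiomer.get(a)
            es, es_sat = np.nan, False
            if partner is not None and partner in enrich and np.isfinite(e_a):
                e_b = enrich[partner]
                if np.isfinite(e_b):
                    if e_b == 0:
                        es, es_sat = (thresholds.es_cap if e_a > 0 else np.nan), e_a > 0
                    else:
                        es = e_a / e_b
                        if es > thresholds.es_cap:
                            es, es_sat = thresholds.es_cap, True
            ds = np.nan
            dias = pairing.diastereomers.get(a)
            if dias is not None and all(d in enrich for d in dias):
                dmean = np.nanmean([enrich[d] for d in dias])
                if dmean > 0 and np.isfinite(e_a):
                    ds = e_a / dmean
            comp_raw, comp_pct = np.nan, np.nan
            competitor = competitor_for.get(a)
            comp_cv = np.nan
            if competitor is not None:
                c_mean = _get(mean_w, ("competitor_plus_alkyne", competitor))
                if np.isfinite(c_mean) and np.isfinite(e_a) and e_a > 0:
                    comp_raw = 100.0 * (1.0 - c_mean / e_a)
                    comp_pct = float(np.clip(comp_raw, 0.0, 100.0))
                comp_cv = _get(cv_w, ("competitor_plus_alkyne", competitor))
            site_pct = site_idx.get((acc, competitor), np.nan) if competitor else np.nan
            alk_cv = _get(cv_w, ("dmso_plus_alkyne", a))
            per_probe[a] = dict(
                enrichment=e_a,
                enantioselectivity=es,
                es_saturated=es_sat,
                diastereoselectivity=ds,
                competition_raw=comp_raw,
                competition_pct=comp_pct,
                site_competition_pct=site_pct,
                alk_cv=alk_cv,
                comp_cv=comp_cv,
                competitor_id=competitor or "",
            )
            sel_rows.append(
                {
                    "protein_accession": acc,
                    "compound_id": a,
                    **{
                        k: per_probe[a][k]
                        for k in (
                            "enrichment",
                            "enantioselectivity",
                            "es_saturated",
                            "diastereoselectivity",
                            "competition_raw",
                            "competition_pct",
                            "site_competition_pct",
                            "competitor_id",
                        )
                    },
                }
            )
        active, routes = [], []
        for a, d in per_probe.items():
            es_ok = np.isfinite(d["enantioselectivity"]) and (
                d["enantioselectivity"] > thresholds.min_enantioselectivity
            )
            prot_comp_ok = np.isfinite(d["competition_pct"]) and (
                d["competition_pct"] > thresholds.min_competition_pct
            )
            site_comp_ok = np.isfinite(d["site_competition_pct"]) and (
                d["site_competition_pct"] > thresholds.min_competition_pct
            )
            if es_ok and (prot_comp_ok or site_comp_ok):
                active.append(a)
                routes.append("protein_track" if prot_comp_ok else "cysteine_track")
        comp_vals = [
            d["competition_pct"] for d in per_probe.values() if np.isfinite(d["competition_pct"])
        ]
        es_vals = [
            d["enantioselectivity"]
            for d in per_probe.values()
            if np.isfinite(d["enantioselectivity"])
        ]
        contributing_cvs = [
            v
            for d in per_probe.values()
            for v in (d["alk_cv"], d["comp_cv"])
            if np.isfinite(v)
        ]
        call_rows.append(
            {
                "protein_accession": acc,
                "liganded": bool(active),
                "active_stereoprobes": ",".join(active),
                "evidence_route": ",".join(sorted(set(routes))),
                "max_competition_pct": max(comp_vals) if comp_vals else np.nan,
                "max_enantioselectivity": max(es_vals) if es_vals else np.nan,
                "variability_flag": bool(
                    any(v >= thresholds.max_cv for v in contributing_cvs)
                ),
            }
        )
    selectivity = pd.DataFrame(sel_rows)
    calls = pd.DataFrame(call_rows)
    return selectivity, calls


def quadrant_table(selectivity: pd.DataFrame) -> pd.DataFrame:
    """Quadrant-plot export: per (protein, stereoprobe) enantioselectivity
    (x) and diastereoselectivity (y)."""
    return selectivity[
        ["protein_accession", "compound_id", "enantioselectivity", "diastereoselectivity"]
    ].rename(
        columns={
            "enantioselectivity": "enantioselectivity_x",
            "diastereoselectivity": "diastereoselectivity_y",
        }
    )


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class ProteinDirectedPipeline(BaseEstimator):
    """End-to-end protein-directed ABPP analysis of one PSM table.

    Parameters mirror the published filter cascade; fitted attributes are
    ``exclusion_log_`` (PSM-level), ``profiles_`` (normalized per-protein
    signals with evidence/CV flags), ``condition_stats_``, ``selectivity_``,
    ``calls_`` and ``quadrant_``.
    """

    def __init__(
        self,
        min_intensity: float = 10_000.0,
        min_s2n: float = 1.0,
        min_purity: float = 0.5,
        min_peptides: int = 2,
        max_cv: float = 0.2,
        min_enantioselectivity: float = 2.0,
        min_competition_pct: float = 50.0,
        es_cap: float = 100.0,
        strict_metadata: bool = False,
    ):
        self.min_intensity = min_intensity
        self.min_s2n = min_s2n
        self.min_purity = min_purity
        self.min_peptides = min_peptides
        self.max_cv = max_cv
        self.min_enantioselectivity = min_enantioselectivity
        self.min_competition_pct = min_competition_pct
        self.es_cap = es_cap
        self.strict_metadata = strict_metadata

    def fit(self, table: PSMTable, site_competitions: pd.DataFrame | None = None):
        design = table.design
        retained, self.exclusion_log_ = filter_psms(
            table,
            min_intensity=self.min_intensity,
            min_s2n=self.min_s2n,
            min_purity=self.min_purity,
            strict_metadata=self.strict_metadata,
        )
        profiles = rollup_normalize(retained, design, min_peptides=self.min_peptides)
        profiles, self.condition_stats_ = replicate_screen(
            profiles, design, max_cv=self.max_cv
        )
        self.profiles_ = profiles
        thresholds = ClassificationThresholds(
            min_enantioselectivity=self.min_enantioselectivity,
            min_competition_pct=self.min_competition_pct,
            es_cap=self.es_cap,
            max_cv=self.max_cv,
        )
        self.selectivity_, self.calls_ = selectivity_and_classify(
            profiles,
            design,
            thresholds=thresholds,
            site_competitions=site_competitions,
        )
        self.quadrant_ = quadrant_table(self.selectivity_)
        return self

    def fit_predict(self, table: PSMTable, **kw) -> pd.DataFrame:
        """Fit and return the liganding calls table."""
        return self.fit(table, **kw).calls_
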