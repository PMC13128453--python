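"""Cysteine-directed ABPP: DMSO-referenced engagement ratios and site calls.

Each PSM's reporter intensities are divided by the mean of its DMSO-control
channels, so a compound channel's ratio directly reads the fraction of
IA-DTB-reactive cysteine remaining after competitor treatment
(competition % = 100 x (1 - ratio)).  PSMs are grouped by (protein, labeled
residue); the DMSO-channel filters (summed DMSO intensity < 10,000 excluded,
DMSO CV > 0.5 excluded) and a replicate-dispersion screen are applied before
site-level liganding classification.

A site is called liganded when its competition exceeds 50%, its
enantioselectivity (ratio of the enantiomers' competition complements)
exceeds 2-fold, the peptide is unique, and either the protein already passed
the protein-directed liganding criteria or a sibling quantified peptide of
the same protein shows no liganding (distinguishing engagement from protein
abundance changes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import ExperimentDesign, PSMTable, ensure_site_positions

EPS_COMPLEMENT = 0.01  # guard for the enantiomer's competition complement


# ---------------------------------------------------------------------------
# PSM-level ratios
# ---------------------------------------------------------------------------


def engagement_ratios(
    table: PSMTable, design: ExperimentDesign | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-PSM ratio vectors: intensity / mean of the DMSO-control channels.

    PSMs whose DMSO mean is zero (or entirely missing) are dropped with a
    logged reason.  Returns ``(ratios, dropped_log)`` with one
    ``ratio_<label>`` column per included channel; by construction the mean
    of each retained PSM's DMSO-channel ratios equals 1.
    """
    design = design or table.design
    labels = design.included_labels
    dmso_labels = [c.label for c in design.included_channels if c.role == "dmso_control"]
    if len(dmso_labels) < 2:
        raise ValueError("cysteine-directed analysis requires >=2 DMSO channels")
    inten = table.intensity_matrix(labels)
    dmso = table.intensity_matrix(dmso_labels)
    with np.errstate(invalid="ignore"):
        dmso_mean = np.nanmean(dmso, axis=1)
    bad = ~np.isfinite(dmso_mean) | (dmso_mean == 0)
    ratios = np.full_like(inten, np.nan)
    ratios[~bad] = inten[~bad] / dmso_mean[~bad, None]
    keep_cols = ["psm_id", "protein_accession", "peptide_sequence", "unique_peptide"]
    out = table.df.loc[~bad, keep_cols].copy()
    for j, lab in enumerate(labels):
        out[f"ratio_{lab}"] = ratios[~bad, j]
    dropped = pd.DataFrame(
        {"psm_id": table.df.loc[bad, "psm_id"], "reason": "zero_dmso_mean"}
    )
    return out.reset_index(drop=True), dropped.reset_index(drop=True)


# ---------------------------------------------------------------------------
# site roll-up
# ---------------------------------------------------------------------------


@dataclass
class SiteFilterThresholds:
    min_dmso_intensity: float = 10_000.0  # strict "<" exclusion
    max_dmso_cv: float = 0.5  # strict ">" exclusion
    max_dispersion: float = 0.2
    max_probe_mods: int = 2
    literal_mean_rule: bool = False  # literal "mean > 0.2" reading of the screen


def rollup_sites(
    table: PSMTable,
    design: ExperimentDesign | None = None,
    thresholds: SiteFilterThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group PSM ratios by (protein, probe-labeled residue) into SiteProfiles.

    PSM-level exclusions (logged): no IA-DTB-labeled residue; more than
    ``max_probe_mods`` labeled residues on one peptide; summed DMSO intensity
    < ``min_dmso_intensity``; DMSO-channel CV > ``max_dmso_cv``.  Peptides
    carrying two labeled cysteines are reported jointly under a combined site
    key.  The site-level dispersion screen excludes (flags) a site whose
    DMSO-condition ratios have mean absolute deviation > ``max_dispersion``
    (or, under ``literal_mean_rule``, whose mean ratio exceeds it).

    Returns ``(site_profiles, exclusion_log)``; compound-condition replicate
    means appear as ``ratio_<compound>`` columns.
    """
    design = design or table.design
    thresholds = thresholds or SiteFilterThresholds()
    labels = design.included_labels
    dmso_labels = [c.label for c in design.included_channels if c.role == "dmso_control"]
    compounds = sorted(
        {
            c.compound_id
            for c in design.included_channels
            if c.role != "dmso_control" and c.compound_id
        }
    )

    df = ensure_site_positions(table.df).reset_index(drop=True)
    table = PSMTable(df, design)
    site_lists = [
        tuple(int(x) for x in str(s).split(",") if x) for s in df["site_positions"]
    ]
    dmso = table.intensity_matrix(dmso_labels)
    dmso_sum = np.nansum(dmso, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dmso_mean = np.nanmean(dmso, axis=1)
        dmso_sd = np.nanstd(dmso, axis=1, ddof=1)
        dmso_cv = np.where(dmso_mean > 0, dmso_sd / dmso_mean, np.nan)

    reasons = []
    for i in range(len(df)):
        r = []
        if len(site_lists[i]) == 0:
            r.append("no_probe_modification")
        elif len(site_lists[i]) > thresholds.max_probe_mods:
            r.append("too_many_probe_modifications")
        if dmso_sum[i] < thresholds.min_dmso_intensity:
            r.append("low_dmso_intensity")
        if np.isfinite(dmso_cv[i]) and dmso_cv[i] > thresholds.max_dmso_cv:
            r.append("high_dmso_cv")
        reasons.append(",".join(r))
    reasons = np.array(reasons, dtype=object)
    drop = reasons != ""
    log = pd.DataFrame(
        {"psm_id": df.loc[drop, "psm_id"], "rules": reasons[drop]}
    ).reset_index(drop=True)

    keep_df = df.loc[~drop].reset_index(drop=True)
    retained = PSMTable(keep_df, design)
    if len(retained) == 0:
        return (
            pd.DataFrame(
                columns=[
                    "protein_accession", "site_key", "residue_index", "n_psms",
                    "unique_peptide", "dmso_sum", "dmso_cv", "dispersion",
                    "excluded_dispersion",
                ]
                + [f"ratio_{c}" for c in compounds]
            ),
            log,
        )
    ratios, dropped0 = engagement_ratios(retained, design)
    if len(dropped0):
        log = pd.concat(
            [log, dropped0.rename(columns={"reason": "rules"})], ignore_index=True
        )
    kept_sites = [s for s, d in zip(site_lists, ~drop) if d]
    site_map = dict(zip(keep_df["psm_id"], kept_sites))
    dmso_sum_map = dict(
        zip(keep_df["psm_id"], np.nansum(retained.intensity_matrix(dmso_labels), axis=1))
    )
    ratios = ratios.reset_index(drop=True)
    ratios["site_key"] = [
        "C" + "_C".join(map(str, site_map[p])) for p in ratios["psm_id"]
    ]
    ratios["residue_index"] = [site_map[p][0] for p in ratios["psm_id"]]
    ratios["dmso_sum"] = [dmso_sum_map[p] for p in ratios["psm_id"]]

    cond_cols: dict[str, list[str]] = {}
    for cmpd in compounds:
        cond_cols[cmpd] = [
            f"ratio_{c.label}"
            for c in design.included_channels
            if c.compound_id == cmpd and c.role != "dmso_control"
        ]
    dmso_cols = [f"ratio_{l}" for l in dmso_labels]

    rows = []
    for (acc, key), grp in ratios.groupby(["protein_accession", "site_key"]):
        dvals = grp[dmso_cols].to_numpy(dtype=float).ravel()
        dvals = dvals[np.isfinite(dvals)]
        mad = float(np.mean(np.abs(dvals - dvals.mean()))) if len(dvals) else np.nan
        all_vals = grp[[c for cc in cond_cols.values() for c in cc]].to_numpy(float)
        site_mean = float(np.nanmean(all_vals)) if all_vals.size else np.nan
        if thresholds.literal_mean_rule:
            excluded = np.isfinite(site_mean) and site_mean > thresholds.max_dispersion
        else:
            excluded = np.isfinite(mad) and mad > thresholds.max_dispersion
        row = {
            "protein_accession": acc,
            "site_key": key,
            "residue_index": int(grp["residue_index"].iloc[0]),
            "n_psms": len(grp),
            "peptides": ";".join(sorted(set(grp["peptide_sequence"]))),
            "unique_peptide": bool(grp["unique_peptide"].all()),
            "dmso_sum": float(grp["dmso_sum"].mean()),
            "dispersion": mad,
            "excluded_dispersion": bool(excluded),
        }
        for cmpd, cols in cond_cols.items():
            vals = grp[cols].to_numpy(dtype=float)
            row[f"ratio_{cmpd}"] = float(np.nanmean(vals)) if vals.size else np.nan
        rows.append(row)
    profiles = pd.DataFrame(rows)
    return profiles, log


# ---------------------------------------------------------------------------
# site classification
# ---------------------------------------------------------------------------


def site_competitions(profiles: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    """Tidy per-(site, compound) competition table (percent, clipped to
    [0, 100]; raw value retained)."""
    compounds = sorted(
        {
            c.compound_id
            for c in design.included_channels
            if c.role != "dmso_control" and c.compound_id
        }
    )
    rows = []
    for _, p in profiles.iterrows():
        for cmpd in compounds:
            r = p.get(f"ratio_{cmpd}", np.nan)
            raw = 100.0 * (1.0 - r) if np.isfinite(r) else np.nan
            rows.append(
                {
                    "protein_accession": p["protein_accession"],
                    "site_key": p["site_key"],
                    "residue_index": p["residue_index"],
                    "compound_id": cmpd,
                    "competition_raw": raw,
                    "competition_pct": float(np.clip(raw, 0, 100))
                    if np.isfinite(raw)
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def classify_sites(
    profiles: pd.DataFrame,
    design: ExperimentDesign,
    protein_calls: pd.DataFrame | None = None,
    min_competition_pct: float = 50.0,
    min_enantioselectivity: float = 2.0,
    es_cap: float = 100.0,
) -> pd.DataFrame:
    """Apply the two-track site liganding criteria.

    Site enantioselectivity for compound X with enantiomer Y is
    ``(1 - ratio_X) / max(1 - ratio_Y, 0.01)`` capped at ``es_cap``.
    ``supporting_route`` records which additional criterion carried the call:
    ``protein_track_support`` (the protein passed protein-directed liganding),
    ``sibling_peptide_support`` (another quantified peptide of the protein
    shows no liganding) or ``insufficient``.
    """
    compounds = sorted(
        {
            c.compound_id
            for c in design.included_channels
            if c.role != "dmso_control" and c.compound_id
        }
    )
    enant = {}
    for a, b in design.stereochemistry.enantiomer_pairs:
        enant[a] = b
        enant[b] = a
    liganded_proteins: set[str] = set()
    if protein_calls is not None and len(protein_calls):
        liganded_proteins = set(
            protein_calls.loc[protein_calls["liganded"], "protein_accession"]
        )

    eligible = profiles[~profiles["excluded_dispersion"]].copy()

    # per-site per-compound metrics
    def _metrics(p) -> dict[str, dict[str, float]]:
        out = {}
        for cmpd in compounds:
            r = p.get(f"ratio_{cmpd}", np.nan)
            comp = 100.0 * (1.0 - r) if np.isfinite(r) else np.nan
            es = np.nan
            partner = enant.get(cmpd)
            if partner is not None:
                rp = p.get(f"ratio_{partner}", np.nan)
                if np.isfinite(r) and np.isfinite(rp):
                    es = (1.0 - r) / max(1.0 - rp, EPS_COMPLEMENT)
                    es = float(np.clip(es, 0.0, es_cap))
            out[cmpd] = {"competition": comp, "enantioselectivity": es}
        return out

    metrics = {i: _metrics(p) for i, p in eligible.iterrows()}

    def _shows_liganding(i) -> bool:
        return any(
            np.isfinite(m["competition"])
            and m["competition"] > min_competition_pct
            and np.isfinite(m["enantioselectivity"])
            and m["enantioselectivity"] > min_enantioselectivity
            for m in metrics[i].values()
        )

    shows = {i: _shows_liganding(i) for i in eligible.index}
    by_protein: dict[str, list[int]] = {}
    for i, p in eligible.iterrows():
        by_protein.setdefault(p["protein_accession"], []).append(i)

    rows = []
    for i, p in eligible.iterrows():
        acc = p["protein_accession"]
        active = [
            c
            for c, m in metrics[i].items()
            if np.isfinite(m["competition"])
            and m["competition"] > min_competition_pct
            and np.isfinite(m["enantioselectivity"])
            and m["enantioselectivity"] > min_enantioselectivity
        ]
        if acc in liganded_proteins:
            route = "protein_track_support"
        elif any(j != i and not shows[j] for j in by_protein[acc]):
            route = "sibling_peptide_support"
        else:
            route = "insufficient"
        liganded = bool(active) and p["unique_peptide"] and route != "insufficient"
        comps = [m["competition"] for m in metrics[i].values() if np.isfinite(m["competition"])]
        ess = [
            m["enantioselectivity"]
            for m in metrics[i].values()
            if np.isfinite(m["enantioselectivity"])
        ]
        row = {
            "protein_accession": acc,
            "site_key": p["site_key"],
            "residue_index": p["residue_index"],
            "liganded": liganded,
            "active_compounds": ",".join(active) if liganded else "",
            "supporting_route": route,
            "unique_peptide": bool(p["unique_peptide"]),
            "max_competition_pct": float(np.clip(max(comps), 0, 100)) if comps else np.nan,
            "max_enantioselectivity": max(ess) if ess else np.nan,
        }
        for cmpd in compounds:
            row[f"competition_pct_{cmpd}"] = (
                float(np.clip(metrics[i][cmpd]["competition"], 0, 100))
                if np.isfinite(metrics[i][cmpd]["competition"])
                else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class CysteineDirectedPipeline(BaseEstimator):
    """End-to-end cysteine-directed ABPP analysis of one PSM table.

    Fitted attributes: ``exclusion_log_``, ``site_profiles_``,
    ``site_competitions_`` and ``site_calls_``.
    """

    def __init__(
        self,
        min_dmso_intensity: float = 10_000.0,
        max_dmso_cv: float = 0.5,
        max_dispersion: float = 0.2,
        max_probe_mods: int = 2,
        literal_mean_rule: bool = False,
        min_competition_pct: float = 50.0,
        min_enantioselectivity: float = 2.0,
        es_cap: float = 100.0,
    ):
        self.min_dmso_intensity = min_dmso_intensity
        self.max_dmso_cv = max_dmso_cv
        self.max_dispersion = max_dispersion
        self.max_probe_mods = max_probe_mods
        self.literal_mean_rule = literal_mean_rule
        self.min_competition_pct = min_competition_pct
        self.min_enantioselectivity = min_enantioselectivity
        self.es_cap = es_cap

    def fit(self, table: PSMTable, protein_calls: pd.DataFrame | None = None):
        design = table.design
        thresholds = SiteFilterThresholds(
            min_dmso_intensity=self.min_dmso_intensity,
            max_dmso_cv=self.max_dmso_cv,
            max_dispersion=self.max_dispersion,
            max_probe_mods=self.max_probe_mods,
            literal_mean_rule=self.literal_mean_rule,
        )
        self.site_profiles_, self.exclusion_log_ = rollup_sites(
            table, design, thresholds
        )
        self.site_competitions_ = site_competitions(self.site_profiles_, design)
        self.site_calls_ = classify_sites(
            self.site_profiles_,
            design,
            protein_calls=protein_calls,
            min_competition_pct=self.min_competition_pct,
            min_enantioselectivity=self.min_enantioselectivity,
            es_cap=self.es_cap,
        )
        return self

    def fit_predict(self, table: PSMTable, **kw) -> pd.DataFrame:
        """Fit and return the site liganding calls table."""
        return self.fit(table, **kw).site_calls_
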