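"""Seeded synthetic PSM tables and kinetic traces with planted ground truth.

The generators are forward models of the two competitive ABPP tracks:

* **protein-directed** — cells pretreated with a non-alkyne competitor (or
  DMSO), then labeled with a stereomatched alkyne probe; enrichment of a
  liganded protein by its active alkyne exceeds the enantiomer's by the
  planted enantioselectivity, and the competitor attenuates that enrichment
  by the planted competition fraction.
* **cysteine-directed** — cells pretreated with the competitor, then lysates
  labeled with the broad-spectrum IA-DTB scout probe; a compound channel's
  expected reporter intensity at an engaged cysteine is the DMSO expectation
  times ``1 - engagement``.

Noise is multiplicative log-normal at three levels: protein (or site)
abundance, a per-(protein, channel) replicate effect, and per-(PSM, channel)
measurement noise.  Co-isolation interference is convex mixing of a PSM's
channel vector with a flat background profile; the mixing weight is recorded
as ``1 - isolation_purity`` so the purity filter removes exactly the
distorted PSMs.  With all noise parameters at zero the downstream pipeline
reproduces every planted quantity to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    ChannelDesign,
    ExperimentDesign,
    PSMTable,
    Stereochemistry,
    format_modifications,
    IA_DTB_MASS,
)

_TMT16_LABELS = [
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
]
_TMT10_LABELS = [
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131",
]

_AA = np.array(list("ADEFGHILMNPQSTVWY"))  # no C/K/R: placed explicitly


# ---------------------------------------------------------------------------
# default study designs
# ---------------------------------------------------------------------------


def default_protein_design() -> ExperimentDesign:
    """16-plex protein-directed layout: one enantiomeric alkyne pair.

    2 DMSO controls, 3+3 DMSO+alkyne replicates (FWG-3A/FWG-3B) and 4+4
    competitor+alkyne replicates (FWG-1A/FWG-1B pretreatment before the
    stereomatched alkyne).
    """
    chans: list[ChannelDesign] = []
    spec = (
        [("dmso_control", "", "none")] * 2
        + [("dmso_plus_alkyne", "FWG-3A", "A")] * 3
        + [("dmso_plus_alkyne", "FWG-3B", "B")] * 3
        + [("competitor_plus_alkyne", "FWG-1A", "A")] * 4
        + [("competitor_plus_alkyne", "FWG-1B", "B")] * 4
    )
    counts: dict[tuple[str, str], int] = {}
    for label, (role, cmpd, stereo) in zip(_TMT16_LABELS, spec):
        rep = counts.get((role, cmpd), 0) + 1
        counts[(role, cmpd)] = rep
        chans.append(ChannelDesign(label, role, cmpd, stereo, rep))
    stereo_chem = Stereochemistry(
        enantiomer_pairs=(("FWG-3A", "FWG-3B"), ("FWG-1A", "FWG-1B")),
        families=(("FWG-3A", "FWG-3B"),),
        competitor_of={"FWG-1A": "FWG-3A", "FWG-1B": "FWG-3B"},
    )
    return ExperimentDesign(16, "protein_directed", chans, "trypsin", stereo_chem)


def default_cysteine_design() -> ExperimentDesign:
    """10-plex cysteine-directed layout: 2 DMSO + 4+4 competitor channels."""
    chans: list[ChannelDesign] = []
    spec = (
        [("dmso_control", "", "none")] * 2
        + [("compound_only", "FWG-1A", "A")] * 4
        + [("compound_only", "FWG-1B", "B")] * 4
    )
    counts: dict[tuple[str, str], int] = {}
    for label, (role, cmpd, stereo) in zip(_TMT10_LABELS, spec):
        rep = counts.get((role, cmpd), 0) + 1
        counts[(role, cmpd)] = rep
        chans.append(ChannelDesign(label, role, cmpd, stereo, rep))
    stereo_chem = Stereochemistry(
        enantiomer_pairs=(("FWG-1A", "FWG-1B"),),
        families=(("FWG-1A", "FWG-1B"),),
    )
    return ExperimentDesign(10, "cysteine_directed", chans, "trypsin", stereo_chem)


# ---------------------------------------------------------------------------
# parameters and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimulationParams:
    """Planted study conditions for the synthetic PSM generators.

    Defaults mirror the competitive-ABPP regime the pipeline targets:
    200 proteins, ~8 PSMs each, 10% liganded with 80% competition and
    4-fold enantioselective enrichment, log-normal reporter noise and a
    co-isolation interference process tied to isolation purity.
    """

    n_proteins: int = 200
    psm_per_protein: float = 8.0
    base_intensity_log_mean: float = float(np.log(5.0e4))
    base_intensity_log_sd: float = 1.0
    n_cys_sites_per_protein: int = 2
    liganded_fraction: float = 0.1
    planted_competition: float = 0.8
    planted_enantioselectivity: float = 4.0
    complexoform_fraction: float = 1.0
    interference_level: float = 0.3
    interference_prob: float = 0.2
    replicate_cv: float = 0.1
    psm_noise_sd: float = 0.1
    missing_rate: float = 0.05
    background_binding: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "liganded_fraction",
            "complexoform_fraction",
            "missing_rate",
            "interference_prob",
            "planted_competition",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.interference_level < 1.0:
            raise ValueError("interference_level must be in [0, 1)")
        if self.planted_enantioselectivity < 1.0:
            raise ValueError("planted_enantioselectivity must be >= 1")
        if self.replicate_cv < 0 or self.psm_noise_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.n_proteins < 1 or self.psm_per_protein <= 0:
            raise ValueError("need at least one protein and a positive PSM rate")


def _lognoise(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    z = rng.standard_normal(shape)
    return np.exp(sigma * z)


def _peptides(rng: np.random.Generator, n: int, terminal: str) -> list[str]:
    """Random peptides with protease-consistent C-termini (no internal C)."""
    lengths = rng.integers(8, 21, size=n)
    term = np.array(list(terminal))
    return [
        "".join(rng.choice(_AA, size=l - 1)) + str(rng.choice(term))
        for l in lengths
    ]


def _terminal_residues(protease: str) -> str:
    return "KR" if protease == "trypsin" else "DE"


# ---------------------------------------------------------------------------
# protein-directed generator
# ---------------------------------------------------------------------------


def generate_protein_directed_dataset(
    params: SimulationParams,
    design: ExperimentDesign | None = None,
    *,
    competition_override: np.ndarray | None = None,
) -> tuple[PSMTable, pd.DataFrame]:
    """Generate a protein-directed PSM table and its ground truth.

    Returns ``(psm_table, truth)`` where ``truth`` has one row per protein
    with the planted liganded flag, active alkyne, competition and
    enantioselectivity.
    """
    params.validate()
    if design is None:
        design = default_protein_design()
    if design.track != "protein_directed":
        raise ValueError("design.track must be protein_directed")
    rng = np.random.default_rng(params.seed)

    n = params.n_proteins
    accessions = np.array([f"SYN{i:04d}" for i in range(n)])
    genes = np.array([f"GENE{i}" for i in range(n)])

    alkynes = sorted(
        {c.compound_id for c in design.included_channels if c.role == "dmso_plus_alkyne"}
    )
    n_lig = int(round(n * params.liganded_fraction))
    lig_idx = rng.choice(n, size=n_lig, replace=False)
    liganded = np.zeros(n, dtype=bool)
    liganded[lig_idx] = True
    active = np.array([""] * n, dtype=object)
    active[lig_idx] = rng.choice(alkynes, size=n_lig)

    competition = np.where(liganded, params.planted_competition, 0.0)
    if competition_override is not None:
        competition = np.asarray(competition_override, dtype=float)
    enantio = np.where(liganded, params.planted_enantioselectivity, 1.0)

    channels = design.included_channels
    n_ch = len(channels)
    # expected relative signal per (protein, channel)
    expect = np.empty((n, n_ch))
    comp_to_alkyne = design.stereochemistry.competitor_of
    for j, ch in enumerate(channels):
        if ch.role == "dmso_control":
            expect[:, j] = params.background_binding
        elif ch.role == "dmso_plus_alkyne":
            expect[:, j] = np.where(active == ch.compound_id, enantio, 1.0)
        elif ch.role == "competitor_plus_alkyne":
            alkyne = comp_to_alkyne.get(ch.compound_id, ch.compound_id)
            enr = np.where(active == alkyne, enantio, 1.0)
            block = np.where(active == alkyne, 1.0 - competition, 1.0)
            expect[:, j] = enr * block
        else:
            expect[:, j] = 1.0

    abundance = np.exp(
        params.base_intensity_log_mean
        + params.base_intensity_log_sd * rng.standard_normal(n)
    )
    rep_effect = _lognoise(rng, params.replicate_cv, (n, n_ch))

    n_psm_per = np.maximum(1, rng.poisson(params.psm_per_protein, size=n))
    prot_of_psm = np.repeat(np.arange(n), n_psm_per)
    m = len(prot_of_psm)
    psm_factor = _lognoise(rng, 0.25, m)
    eps = _lognoise(rng, params.psm_noise_sd, (m, n_ch))
    inten = (
        abundance[prot_of_psm, None]
        * expect[prot_of_psm]
        * rep_effect[prot_of_psm]
        * psm_factor[:, None]
        * eps
    )

    purity = 0.85 + 0.15 * rng.random(m)
    if params.interference_level > 0:
        affected = rng.random(m) < params.interference_prob
        w = params.interference_level
        background = np.full(n_ch, 1.0 / n_ch)
        totals = inten.sum(axis=1, keepdims=True)
        inten[affected] = (1 - w) * inten[affected] + w * totals[affected] * background
        purity[affected] = 1.0 - w
    s2n = np.exp(np.log(8.0) + 0.6 * rng.standard_normal(m))

    keep = rng.random(m) >= params.missing_rate
    peptides = _peptides(rng, m, _terminal_residues(design.protease))

    df = pd.DataFrame(
        {
            "psm_id": [f"P{i:06d}" for i in range(m)],
            "protein_accession": accessions[prot_of_psm],
            "gene_symbol": genes[prot_of_psm],
            "peptide_sequence": peptides,
            "peptide_start": 1 + 25 * (np.arange(m) % 40),
            "charge": rng.integers(2, 5, size=m),
            "modifications": "",
            "isolation_purity": purity,
            "signal_to_noise": s2n,
            "unique_peptide": True,
        }
    )
    for j, ch in enumerate(channels):
        df[f"intensity_{ch.label}"] = inten[:, j]
    df = df[keep].reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "protein_accession": accessions,
            "liganded": liganded,
            "active_compound": active,
            "competition": competition,
            "enantioselectivity": enantio,
        }
    )
    return PSMTable(df, design), truth


# ---------------------------------------------------------------------------
# cysteine-directed generator
# ---------------------------------------------------------------------------


def generate_cysteine_directed_dataset(
    params: SimulationParams,
    design: ExperimentDesign | None = None,
    *,
    engagement_override: np.ndarray | None = None,
) -> tuple[PSMTable, pd.DataFrame]:
    """Generate a cysteine-directed PSM table and per-site ground truth.

    Each protein carries ``n_cys_sites_per_protein`` probe-labeled cysteines;
    for a planted liganded protein the first site is engaged by the active
    competitor (expected compound-channel intensity = DMSO x (1 - engagement))
    while sibling sites stay flat, providing the no-liganding sibling peptide
    the site-classification criteria look for.
    """
    params.validate()
    if design is None:
        design = default_cysteine_design()
    if design.track != "cysteine_directed":
        raise ValueError("design.track must be cysteine_directed")
    rng = np.random.default_rng(params.seed)

    n = params.n_proteins
    n_sites = max(1, int(params.n_cys_sites_per_protein))
    accessions = np.array([f"SYN{i:04d}" for i in range(n)])
    genes = np.array([f"GENE{i}" for i in range(n)])

    compounds = sorted(
        {c.compound_id for c in design.included_channels if c.role == "compound_only"}
    )
    n_lig = int(round(n * params.liganded_fraction))
    lig_idx = rng.choice(n, size=n_lig, replace=False)
    liganded = np.zeros(n, dtype=bool)
    liganded[lig_idx] = True
    active = np.array([""] * n, dtype=object)
    active[lig_idx] = rng.choice(compounds, size=n_lig)

    # site grid: protein i, site j -> residue coordinate
    prot_of_site = np.repeat(np.arange(n), n_sites)
    site_j = np.tile(np.arange(n_sites), n)
    residues = 20 + 45 * site_j
    engaged_site = site_j == 0
    engagement = np.where(
        liganded[prot_of_site] & engaged_site, params.planted_competition, 0.0
    )
    if engagement_override is not None:
        engagement = np.asarray(engagement_override, dtype=float)
    site_active = np.where(
        liganded[prot_of_site] & engaged_site, active[prot_of_site], ""
    )

    channels = design.included_channels
    n_ch = len(channels)
    n_total_sites = len(prot_of_site)
    expect = np.empty((n_total_sites, n_ch))
    for j, ch in enumerate(channels):
        if ch.role == "dmso_control":
            expect[:, j] = 1.0
        else:
            expect[:, j] = np.where(site_active == ch.compound_id, 1.0 - engagement, 1.0)

    abundance = np.exp(
        params.base_intensity_log_mean
        + params.base_intensity_log_sd * rng.standard_normal(n_total_sites)
    )
    rep_effect = _lognoise(rng, params.replicate_cv, (n_total_sites, n_ch))

    # one peptide per site, shared by that site's PSMs
    term = _terminal_residues(design.protease)
    base_peps = _peptides(rng, n_total_sites, term)
    cys_pos = np.array([1 + int(rng.integers(0, len(p) - 1)) for p in base_peps])
    peptides = [
        p[: cp - 1] + "C" + p[cp - 1 :][1:] for p, cp in zip(base_peps, cys_pos)
    ]
    pep_start = residues - cys_pos + 1

    n_psm_site = np.maximum(1, rng.poisson(params.psm_per_protein / n_sites, size=n_total_sites))
    site_of_psm = np.repeat(np.arange(n_total_sites), n_psm_site)
    m = len(site_of_psm)
    psm_factor = _lognoise(rng, 0.25, m)
    eps = _lognoise(rng, params.psm_noise_sd, (m, n_ch))
    inten = (
        abundance[site_of_psm, None]
        * expect[site_of_psm]
        * rep_effect[site_of_psm]
        * psm_factor[:, None]
        * eps
    )

    purity = 0.85 + 0.15 * rng.random(m)
    if params.interference_level > 0:
        affected = rng.random(m) < params.interference_prob
        w = params.interference_level
        background = np.full(n_ch, 1.0 / n_ch)
        totals = inten.sum(axis=1, keepdims=True)
        inten[affected] = (1 - w) * inten[affected] + w * totals[affected] * background
        purity[affected] = 1.0 - w
    s2n = np.exp(np.log(8.0) + 0.6 * rng.standard_normal(m))
    keep = rng.random(m) >= params.missing_rate

    mods = [format_modifications([(int(cys_pos[s]), IA_DTB_MASS)]) for s in site_of_psm]
    df = pd.DataFrame(
        {
            "psm_id": [f"C{i:06d}" for i in range(m)],
            "protein_accession": accessions[prot_of_site[site_of_psm]],
            "gene_symbol": genes[prot_of_site[site_of_psm]],
            "peptide_sequence": [peptides[s] for s in site_of_psm],
            "peptide_start": pep_start[site_of_psm],
            "charge": rng.integers(2, 5, size=m),
            "modifications": mods,
            "isolation_purity": purity,
            "signal_to_noise": s2n,
            "unique_peptide": True,
        }
    )
    for j, ch in enumerate(channels):
        df[f"intensity_{ch.label}"] = inten[:, j]
    df = df[keep].reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "protein_accession": accessions[prot_of_site],
            "residue": residues,
            "liganded_site": engagement > 0,
            "active_compound": site_active,
            "engagement": engagement,
        }
    )
    return PSMTable(df, design), truth


# ---------------------------------------------------------------------------
# complexoform scenario
# ---------------------------------------------------------------------------


def generate_complexoform_scenario(
    f: float,
    e: float,
    params: SimulationParams,
    protein_design: ExperimentDesign | None = None,
    cysteine_design: ExperimentDesign | None = None,
) -> tuple[PSMTable, PSMTable, pd.DataFrame]:
    """Paired datasets for complexoform-restricted liganding.

    The alkyne stereoprobe only reacts with the probe-reactive complexoform
    (fraction ``f`` of the scout-probe-reactive pool), which the competitor
    engages to extent ``e``; the IA-DTB scout probe reacts with the site in
    every complexoform.  Before noise the planted expectations are therefore
    ``protein_competition = e`` and ``site_competition = f * e``.

    Returns ``(protein_track_table, cysteine_track_table, truth)``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    if not 0.0 <= e <= 1.0:
        raise ValueError("e must be in [0, 1]")
    params.validate()
    if protein_design is None:
        protein_design = default_protein_design()
    if cysteine_design is None:
        cysteine_design = default_cysteine_design()

    prot_params = replace(params, planted_competition=e)
    psm_prot, truth_prot = generate_protein_directed_dataset(prot_params, protein_design)

    # stereomatch: cysteine-track active compound is the competitor of the
    # protein-track alkyne; reuse the same seed so liganded sets coincide
    cys_params = replace(params, planted_competition=f * e)
    psm_cys, truth_cys = generate_cysteine_directed_dataset(cys_params, cysteine_design)

    truth = truth_prot.rename(columns={"competition": "protein_competition"}).copy()
    site_truth = truth_cys[truth_cys["liganded_site"]].set_index("protein_accession")
    truth["site_competition"] = (
        truth["protein_accession"].map(site_truth["engagement"]).fillna(0.0)
    )
    truth["residue"] = truth["protein_accession"].map(site_truth["residue"])
    truth["f"] = np.where(truth["liganded"], f, np.nan)
    truth["e"] = np.where(truth["liganded"], e, np.nan)
    return psm_prot, psm_cys, truth


# ---------------------------------------------------------------------------
# kinetic traces
# ---------------------------------------------------------------------------


def generate_timecourse(
    k_obs: float,
    inhibitor_conc: float,
    timepoints,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Pseudo-first-order decay trace: fraction remaining ``exp(-k_obs t)``.

    Gaussian noise of standard deviation ``noise_sd`` is added pointwise;
    the result is a :class:`abpp.kinetics.TimeCourse`.
    """
    from .kinetics import TimeCourse

    if k_obs < 0:
        raise ValueError("k_obs must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise ValueError("timepoints must be >= 0")
    rng = np.random.default_rng(seed)
    values = np.exp(-k_obs * t)
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(t.shape)
    return TimeCourse(times=t, values=values, inhibitor_conc=inhibitor_conc)
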