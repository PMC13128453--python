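"""Protein-directed track: ratios, filter cascade, roll-up, CV screen,
selectivity and liganding classification."""

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from abpp import (
    ChannelDesign,
    ExperimentDesign,
    PSMTable,
    SimulationParams,
    generate_protein_directed_dataset,
)
from abpp.io import DesignError
from abpp.protein import (
    ClassificationThresholds,
    ProteinDirectedPipeline,
    condition_statistics,
    filter_psms,
    psm_fractional_ratios,
    replicate_screen,
    rollup_normalize,
    selectivity_and_classify,
)

from conftest import make_psm_df


# ---------------------------------------------------------------------------
# fractional ratios
# ---------------------------------------------------------------------------


def test_equal_intensities_give_equal_fractions(protein_design, make_table):
    table = make_table(protein_design, [{"intensities": [7.0] * 16}])
    fracs, dropped = psm_fractional_ratios(table)
    npt.assert_allclose(
        fracs.filter(like="frac_").to_numpy(), 1.0 / 16.0, rtol=1e-12
    )
    assert dropped.empty


def test_two_channel_fraction_arithmetic():
    chans = [ChannelDesign("126", "dmso_control"), ChannelDesign("127N", "dmso_control")] + [
        ChannelDesign(str(i), "dmso_plus_alkyne", "X", "A", i) for i in range(2, 10)
    ]
    design = ExperimentDesign(10, "protein_directed", chans)
    df = make_psm_df(design, [{"intensities": [100.0, 300.0] + [0.0] * 8}])
    fracs, _ = psm_fractional_ratios(PSMTable(df, design))
    assert fracs.loc[0, "frac_126"] == pytest.approx(0.25)
    assert fracs.loc[0, "frac_127N"] == pytest.approx(0.75)


@settings(max_examples=200, deadline=None)
@given(
    st.lists(
        st.floats(min_value=0.0, max_value=1e8, allow_nan=False), min_size=16, max_size=16
    )
)
def test_fractions_match_independent_normalization(intensities):
    """Property: fractions equal intensity/total and sum to 1 whenever the
    total is positive (independent per-element oracle)."""
    from abpp.simulate import default_protein_design

    design = default_protein_design()
    df = make_psm_df(design, [{"intensities": intensities}])
    fracs, dropped = psm_fractional_ratios(PSMTable(df, design))
    total = sum(intensities)
    if total == 0:
        assert len(fracs) == 0 and len(dropped) == 1
    else:
        got = fracs.filter(like="frac_").to_numpy()[0]
        npt.assert_allclose(got, np.asarray(intensities) / total, rtol=1e-12)
        assert got.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# PSM filter cascade
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "total, s2n, purity, kept",
    [
        (9_999.0, 10.0, 0.9, False),  # below the summed-intensity floor
        (10_000.0, 1.0, 0.5, True),  # all three exactly at threshold: retained
        (20_000.0, 0.99, 0.9, False),
        (20_000.0, 10.0, 0.49, False),
    ],
)
def test_filter_boundaries_are_strict(protein_design, make_table, total, s2n, purity, kept):
    table = make_table(
        protein_design,
        [{"intensities": [total / 16.0] * 16, "signal_to_noise": s2n, "isolation_purity": purity}],
    )
    retained, log = filter_psms(table)
    assert (len(retained) == 1) == kept
    assert (len(log) == 0) == kept


def test_filter_agrees_with_brute_force_row_scan(protein_design, rng):
    """Oracle: an independent per-row check over 100 PSMs with planted
    violations reproduces the retained set exactly."""
    rows = []
    for i in range(100):
        total = float(rng.uniform(5_000, 50_000))
        rows.append(
            {
                "intensities": list(rng.dirichlet(np.ones(16)) * total),
                "signal_to_noise": float(rng.uniform(0.5, 5.0)),
                "isolation_purity": float(rng.uniform(0.2, 1.0)),
            }
        )
    df = make_psm_df(protein_design, rows)
    table = PSMTable(df, protein_design)
    retained, log = filter_psms(table)

    expected_keep = []
    for i, r in enumerate(rows):
        ok = (
            sum(r["intensities"]) >= 10_000
            and r["signal_to_noise"] >= 1.0
            and r["isolation_purity"] >= 0.5
        )
        if ok:
            expected_keep.append(f"T{i:03d}")
    assert list(retained.df["psm_id"]) == expected_keep
    assert len(log) == 100 - len(expected_keep)


def test_filter_monotonicity(protein_design, rng):
    """Tightening any threshold never increases the retained count."""
    table, _ = generate_protein_directed_dataset(SimulationParams(seed=3, n_proteins=30))
    base = len(filter_psms(table)[0])
    assert len(filter_psms(table, min_intensity=20_000)[0]) <= base
    assert len(filter_psms(table, min_s2n=2.0)[0]) <= base
    assert len(filter_psms(table, min_purity=0.8)[0]) <= base


# ---------------------------------------------------------------------------
# roll-up and normalization
# ---------------------------------------------------------------------------


def test_single_peptide_protein_flagged_low_evidence(protein_design, make_table):
    table = make_table(protein_design, [{"intensities": [1000.0] * 16}])
    prof = rollup_normalize(table)
    assert prof.loc[0, "excluded_low_evidence"]


def test_uniform_protein_normalizes_to_6_25(protein_design, make_table):
    rows = [
        {"intensities": [1000.0] * 16, "peptide_sequence": "AAAAKK"},
        {"intensities": [500.0] * 16, "peptide_sequence": "CCCCKK"},
    ]
    prof = rollup_normalize(make_table(protein_design, rows))
    npt.assert_allclose(prof.filter(like="norm_").to_numpy(), 6.25, rtol=1e-12)
    assert not prof.loc[0, "excluded_low_evidence"]


def test_normalized_signals_sum_to_100(protein_design, rng):
    table, _ = generate_protein_directed_dataset(SimulationParams(seed=8, n_proteins=50))
    prof = rollup_normalize(table)
    npt.assert_allclose(prof.filter(like="norm_").sum(axis=1), 100.0, rtol=1e-9)


def test_excluded_channel_duplication_hand_computed():
    """3-protein fixture, one excluded channel: after duplicating its
    replicate partner for the sum-to-100 step and removing it, the remaining
    channels sum to 100 - v where v is the partner's normalized value."""
    chans = (
        [ChannelDesign("d1", "dmso_control"), ChannelDesign("d2", "dmso_control")]
        + [ChannelDesign(f"a{i}", "dmso_plus_alkyne", "X", "A", i + 1) for i in range(6)]
        + [
            ChannelDesign(
                f"c{i}",
                "competitor_plus_alkyne",
                "Y",
                "A",
                i + 1,
                excluded=(i == 7),
            )
            for i in range(8)
        ]
    )
    design = ExperimentDesign(16, "protein_directed", chans)
    rng = np.random.default_rng(1)
    rows = []
    for p in range(3):
        for pep in ("AAAKK", "CCCKK"):
            rows.append(
                {
                    "protein_accession": f"P{p}",
                    "peptide_sequence": pep,
                    "intensities": list(rng.uniform(100, 1000, 15)),
                }
            )
    df = make_psm_df(design, rows)
    prof = rollup_normalize(PSMTable(df, design))

    # independent hand computation per protein
    labels = design.included_labels
    partner = design.replicate_partner("c7").label  # c0 (lowest replicate)
    for p in range(3):
        sub = df[df["protein_accession"] == f"P{p}"]
        inten = sub[[f"intensity_{l}" for l in labels]].to_numpy(float)
        fr = inten / inten.sum(axis=1, keepdims=True)
        sig = fr.sum(axis=0)
        total = sig.sum() + sig[labels.index(partner)]
        expected = 100.0 * sig / total
        row = prof[prof["protein_accession"] == f"P{p}"].iloc[0]
        npt.assert_allclose(
            row[[f"norm_{l}" for l in labels]].to_numpy(float), expected, rtol=1e-12
        )
        v = expected[labels.index(partner)]
        assert row[[f"norm_{l}" for l in labels]].sum() == pytest.approx(100.0 - v)


def test_excluded_channel_without_partner_is_config_error():
    chans = (
        [ChannelDesign("d1", "dmso_control"), ChannelDesign("d2", "dmso_control")]
        + [ChannelDesign(f"a{i}", "dmso_plus_alkyne", "X", "A", i + 1) for i in range(13)]
        + [ChannelDesign("lone", "competitor_plus_alkyne", "Y", "A", 1, excluded=True)]
    )
    design = ExperimentDesign(16, "protein_directed", chans)
    with pytest.raises(DesignError, match="partner"):
        design.replicate_partner("lone")


# ---------------------------------------------------------------------------
# replicate CV screen
# ---------------------------------------------------------------------------


def _profile_with_conditions(design, values_by_label, acc="P1"):
    row = {"protein_accession": acc, "n_psms": 4, "n_peptides": 3,
           "excluded_low_evidence": False}
    for lab, v in values_by_label.items():
        row[f"norm_{lab}"] = v
    return pd.DataFrame([row])


def test_zero_cv_retained(protein_design):
    vals = {c.label: 10.0 for c in protein_design.included_channels}
    prof = _profile_with_conditions(protein_design, vals)
    out, stats = replicate_screen(prof, protein_design)
    assert not out.loc[0, "excluded_high_cv"]
    assert out.loc[0, "top_alkyne_cv"] == pytest.approx(0.0)


def test_high_cv_in_top_alkyne_condition_excluded(protein_design):
    vals = {c.label: 1.0 for c in protein_design.included_channels}
    # FWG-3A condition is most enriched and noisy: sd/mean = 0.25
    for lab, v in zip(["127C", "128N", "128C"], [7.5, 10.0, 12.51]):
        vals[lab] = v
    prof = _profile_with_conditions(protein_design, vals)
    out, _ = replicate_screen(prof, protein_design)
    assert out.loc[0, "top_alkyne_condition"] == "FWG-3A"
    assert out.loc[0, "excluded_high_cv"]


def test_noise_in_non_top_condition_is_tolerated(protein_design):
    """Manual CV table oracle: only the most enriched DMSO+alkyne condition
    is screened."""
    vals = {c.label: 1.0 for c in protein_design.included_channels}
    for lab in ["129N", "129C", "130N"]:  # FWG-3B: quiet and most enriched
        vals[lab] = 20.0
    for lab, v in zip(["127C", "128N", "128C"], [5.0, 10.0, 15.0]):  # noisy 3A
        vals[lab] = v
    prof = _profile_with_conditions(protein_design, vals)
    out, stats = replicate_screen(prof, protein_design)
    noisy = stats[(stats["compound_id"] == "FWG-3A") & (stats["role"] == "dmso_plus_alkyne")]
    assert noisy["cv"].iloc[0] >= 0.2  # the non-top condition really is noisy
    assert out.loc[0, "top_alkyne_condition"] == "FWG-3B"
    assert not out.loc[0, "excluded_high_cv"]


# ---------------------------------------------------------------------------
# selectivity and classification
# ---------------------------------------------------------------------------


def _classify_single(design, enrich_a, enrich_b, comp_a=None, comp_b=None):
    vals = {}
    for c in design.included_channels:
        if c.role == "dmso_control":
            vals[c.label] = 0.1
        elif c.role == "dmso_plus_alkyne":
            vals[c.label] = enrich_a if c.compound_id == "FWG-3A" else enrich_b
        else:
            base = enrich_a if c.compound_id == "FWG-1A" else enrich_b
            frac = comp_a if c.compound_id == "FWG-1A" else comp_b
            vals[c.label] = base * (1 - (frac or 0.0))
    prof = _profile_with_conditions(design, vals)
    prof["excluded_high_cv"] = False
    return selectivity_and_classify(prof, design)


def test_enantioselectivity_ratio_forced_arithmetic(protein_design):
    sel, _ = _classify_single(protein_design, enrich_a=8.0, enrich_b=2.0)
    es = sel.set_index("compound_id")["enantioselectivity"]
    assert es["FWG-3A"] == pytest.approx(4.0)
    assert es["FWG-3B"] == pytest.approx(0.25)


def test_exact_twofold_is_not_liganded(protein_design):
    """Boundary: enantioselectivity of exactly 2.0 fails the strict
    more-than-twofold criterion even at 60% competition."""
    _, calls = _classify_single(protein_design, 4.0, 2.0, comp_a=0.6)
    assert not calls.loc[0, "liganded"]


def test_strong_blockade_is_liganded(protein_design):
    """>90% competition with >2-fold enantioselective enrichment produces a
    liganded call attributed to the B stereoprobe."""
    _, calls = _classify_single(protein_design, 1.0, 9.0, comp_b=0.95)
    assert calls.loc[0, "liganded"]
    assert calls.loc[0, "active_stereoprobes"] == "FWG-3B"
    assert calls.loc[0, "max_competition_pct"] > 90
    assert calls.loc[0, "evidence_route"] == "protein_track"


def test_competition_is_floored_and_capped(protein_design):
    sel, _ = _classify_single(protein_design, 4.0, 4.0, comp_a=-0.5, comp_b=1.5)
    s = sel.set_index("compound_id")
    assert s.loc["FWG-3A", "competition_pct"] == 0.0
    assert s.loc["FWG-3A", "competition_raw"] == pytest.approx(-50.0)
    assert s.loc["FWG-3B", "competition_pct"] == 100.0


def test_zero_enantiomer_enrichment_is_capped_and_flagged(protein_design):
    sel, _ = _classify_single(protein_design, 4.0, 0.0)
    s = sel.set_index("compound_id")
    assert s.loc["FWG-3A", "enantioselectivity"] == 100.0
    assert s.loc["FWG-3A", "es_saturated"]


def test_cysteine_track_competition_route(protein_design):
    """Table-style cross-track evidence: enantioselective enrichment plus
    >50% site competition by the stereomatched competitor suffices."""
    vals = {}
    for c in protein_design.included_channels:
        if c.role == "dmso_control":
            vals[c.label] = 0.1
        elif c.role == "dmso_plus_alkyne":
            vals[c.label] = 9.0 if c.compound_id == "FWG-3B" else 1.0
        else:
            vals[c.label] = 9.0 if c.compound_id == "FWG-1B" else 1.0  # no blockade
    prof = _profile_with_conditions(protein_design, vals)
    prof["excluded_high_cv"] = False
    site_comp = pd.DataFrame(
        [{"protein_accession": "P1", "compound_id": "FWG-1B", "competition_pct": 85.0}]
    )
    _, calls = selectivity_and_classify(prof, protein_design, site_competitions=site_comp)
    assert calls.loc[0, "liganded"]
    assert calls.loc[0, "evidence_route"] == "cysteine_track"


def test_reciprocity_of_enantioselectivity(protein_design):
    """Property: ES(A,B) x ES(B,A) = 1 for finite, uncapped ratios."""
    table, _ = generate_protein_directed_dataset(SimulationParams(seed=12, n_proteins=40))
    pipe = ProteinDirectedPipeline().fit(table)
    sel = pipe.selectivity_
    w = sel.pivot(index="protein_accession", columns="compound_id", values="enantioselectivity")
    sat = sel.pivot(index="protein_accession", columns="compound_id", values="es_saturated")
    ok = (~sat["FWG-3A"]) & (~sat["FWG-3B"]) & np.isfinite(w["FWG-3A"]) & np.isfinite(w["FWG-3B"])
    assert ok.any()
    npt.assert_allclose((w["FWG-3A"] * w["FWG-3B"])[ok], 1.0, rtol=1e-9)


def test_psm_row_order_invariance():
    table, _ = generate_protein_directed_dataset(SimulationParams(seed=4, n_proteins=30))
    shuffled = PSMTable(
        table.df.sample(frac=1.0, random_state=0).reset_index(drop=True), table.design
    )
    a = ProteinDirectedPipeline().fit(table)
    b = ProteinDirectedPipeline().fit(shuffled)
    pd.testing.assert_frame_equal(
        a.calls_.sort_values("protein_accession").reset_index(drop=True),
        b.calls_.sort_values("protein_accession").reset_index(drop=True),
    )


def test_threshold_monotonicity_of_liganded_count():
    table, _ = generate_protein_directed_dataset(SimulationParams(seed=6))
    loose = ProteinDirectedPipeline(min_competition_pct=40.0).fit(table)
    base = ProteinDirectedPipeline().fit(table)
    tight = ProteinDirectedPipeline(min_competition_pct=70.0, min_enantioselectivity=3.0).fit(table)
    n = lambda p: int(p.calls_["liganded"].sum())
    assert n(tight) <= n(base) <= n(loose)
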