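import numpy as np
import pandas as pd
import pytest

from abpp import (
    ExperimentDesign,
    PSMTable,
    SimulationParams,
    default_cysteine_design,
    default_protein_design,
)


@pytest.fixture(scope="session")
def protein_design() -> ExperimentDesign:
    return default_protein_design()


@pytest.fixture(scope="session")
def cysteine_design() -> ExperimentDesign:
    return default_cysteine_design()


@pytest.fixture
def noise_free_params() -> SimulationParams:
    return SimulationParams(
        replicate_cv=0.0,
        psm_noise_sd=0.0,
        interference_level=0.0,
        missing_rate=0.0,
        seed=11,
    )


def make_psm_df(design: ExperimentDesign, rows: list[dict]) -> pd.DataFrame:
    """Build a small PSM table DataFrame from per-row dicts.

    Each row dict may give ``intensities`` (list over included channels, in
    design order) plus any metadata overrides.
    """
    labels = design.included_labels
    out = []
    for i, row in enumerate(rows):
        row = dict(row)
        inten = row.pop("intensities")
        base = {
            "psm_id": f"T{i:03d}",
            "protein_accession": "PROT1",
            "gene_symbol": "GENE1",
            "peptide_sequence": "ACDEFGHIKK",
            "peptide_start": 1,
            "charge": 2,
            "modifications": "",
            "isolation_purity": 0.9,
            "signal_to_noise": 10.0,
            "unique_peptide": True,
        }
        base.update(row)
        for lab, v in zip(labels, inten):
            base[f"intensity_{lab}"] = v
        out.append(base)
    return pd.DataFrame(out)


@pytest.fixture
def make_table():
    def _make(design: ExperimentDesign, rows: list[dict]) -> PSMTable:
        return PSMTable(make_psm_df(design, rows), design)

    return _make


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
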