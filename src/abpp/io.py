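"""Reading and validation of PSM quantification tables and experiment designs.

The pipeline is search-engine-agnostic: its input is a declared tab-separated
PSM dialect (one row per peptide-spectrum match, one ``intensity_<label>``
column per TMT channel) plus a YAML experiment design mapping each channel to
a treatment role, compound and replicate.  Intensity columns are bound to
channels by label, never by position, so column order in the file carries no
meaning.

Dialect columns
---------------
psm_id, protein_accession, gene_symbol, peptide_sequence, peptide_start,
charge, modifications, isolation_purity, signal_to_noise, unique_peptide,
intensity_<label> (one per non-excluded channel).

``modifications`` encodes per-residue mass deltas as
``"<pos>:<mass_delta>[;<pos>:<mass_delta>...]"`` with 1-based peptide
positions.  Probe-labeled cysteines are recognized by the iodoacetamide-
desthiobiotin (IA-DTB) adduct mass of +398.25292 Da (+/- 0.01 Da) and mapped
to 1-based protein coordinates via ``peptide_start``.

Zeros and missing values are distinct: an empty intensity cell is missing
(NaN), a ``0`` is a true zero and participates in summed-intensity filters.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

IA_DTB_MASS = 398.25292
"""Dynamic modification mass (Da) of the IA-DTB cysteine adduct."""

IA_DTB_TOL = 0.01
"""Mass tolerance (Da) for recognizing the IA-DTB adduct."""

TMT10_MASS = 229.1629
TMT16_MASS = 304.2071

ROLES = ("dmso_control", "dmso_plus_alkyne", "competitor_plus_alkyne", "compound_only")
TRACKS = ("protein_directed", "cysteine_directed")
PROTEASES = ("trypsin", "gluc")

_META_COLUMNS = [
    "psm_id",
    "protein_accession",
    "gene_symbol",
    "peptide_sequence",
    "peptide_start",
    "charge",
    "modifications",
    "isolation_purity",
    "signal_to_noise",
    "unique_peptide",
]


class FormatError(ValueError):
    """A required column or field is missing or malformed."""


class ValidationError(ValueError):
    """A row violates a value constraint (e.g. negative intensity)."""


class DesignMismatchError(ValueError):
    """The PSM table and the experiment design disagree on channels."""


class DesignError(ValueError):
    """The experiment design itself violates an invariant."""


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelDesign:
    """One TMT channel: label, treatment role, compound, replicate index."""

    label: str
    role: str
    compound_id: str = ""
    stereoisomer: str = "none"  # "A", "B" or "none"
    replicate: int = 1
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DesignError(f"unknown channel role {self.role!r}")
        if self.stereoisomer not in ("A", "B", "none"):
            raise DesignError(f"unknown stereoisomer {self.stereoisomer!r}")
        if self.replicate < 1:
            raise DesignError("replicate indices are 1-based positive integers")


@dataclass(frozen=True)
class Stereochemistry:
    """Declared stereoisomer relationships among compounds.

    ``enantiomer_pairs`` lists mirror-image pairs; ``families`` groups all
    stereoisomers sharing a scaffold (a four-member family holds two
    enantiomeric pairs that are mutually diastereomeric); ``competitor_of``
    maps each non-alkyne competitor to its stereomatched alkyne probe.
    """

    enantiomer_pairs: tuple[tuple[str, str], ...] = ()
    families: tuple[tuple[str, ...], ...] = ()
    competitor_of: dict[str, str] = field(default_factory=dict)

    def enantiomer(self, compound: str) -> str | None:
        for a, b in self.enantiomer_pairs:
            if compound == a:
                return b
            if compound == b:
                return a
        return None

    def family_of(self, compound: str) -> tuple[str, ...] | None:
        for fam in self.families:
            if compound in fam:
                return fam
        return None


@dataclass
class ExperimentDesign:
    """Channel layout of one TMT plex for one ABPP track."""

    plex_size: int
    track: str
    channels: list[ChannelDesign]
    protease: str = "trypsin"
    stereochemistry: Stereochemistry = field(default_factory=Stereochemistry)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.plex_size not in (10, 16):
            raise DesignError(f"plex size must be 10 or 16, got {self.plex_size}")
        if self.track not in TRACKS:
            raise DesignError(f"unknown track {self.track!r}")
        if self.protease not in PROTEASES:
            raise DesignError(f"unknown protease {self.protease!r}")
        if len(self.channels) != self.plex_size:
            raise DesignError(
                f"{len(self.channels)} channels declared for a {self.plex_size}-plex"
            )
        labels = [c.label for c in self.channels]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise DesignError(f"duplicate channel labels: {sorted(dupes)}")
        dmso = [c for c in self.included_channels if c.role == "dmso_control"]
        if self.track == "cysteine_directed":
            if len(dmso) < 2:
                raise DesignError(
                    "cysteine-directed designs require >=2 DMSO control channels"
                )
        elif not dmso and not any(
            c.role == "dmso_plus_alkyne" for c in self.included_channels
        ):
            raise DesignError("design has no DMSO-role channel")
        if self.track == "protein_directed":
            alkynes = {
                c.compound_id
                for c in self.included_channels
                if c.role == "dmso_plus_alkyne"
            }
            if not alkynes:
                raise DesignError(
                    "protein-directed designs require >=1 dmso_plus_alkyne channel"
                )
        for a, b in self.stereochemistry.enantiomer_pairs:
            if a == b:
                raise DesignError(f"compound {a!r} declared as its own enantiomer")

    # -- views --------------------------------------------------------------

    @property
    def included_channels(self) -> list[ChannelDesign]:
        return [c for c in self.channels if not c.excluded]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    @property
    def included_labels(self) -> list[str]:
        return [c.label for c in self.included_channels]

    def channel(self, label: str) -> ChannelDesign:
        for c in self.channels:
            if c.label == label:
                return c
        raise DesignMismatchError(f"no channel labeled {label!r} in design")

    def conditions(self, roles: Iterable[str] | None = None) -> dict[tuple[str, str], list[ChannelDesign]]:
        """Group included channels into (role, compound_id) conditions."""
        out: dict[tuple[str, str], list[ChannelDesign]] = {}
        for c in self.included_channels:
            if roles is not None and c.role not in roles:
                continue
            out.setdefault((c.role, c.compound_id), []).append(c)
        return out

    def replicate_partner(self, label: str) -> ChannelDesign:
        """The surviving replicate channel of an excluded channel's condition.

        Used by the protein-track normalization: an excluded channel is
        temporarily replaced by a duplicate of its replicate partner so the
        plex stays balanced during the sum-to-100 step.
        """
        ch = self.channel(label)
        partners = [
            c
            for c in self.included_channels
            if (c.role, c.compound_id) == (ch.role, ch.compound_id)
        ]
        if not partners:
            raise DesignError(
                f"excluded channel {label!r} has no replicate partner to duplicate"
            )
        return min(partners, key=lambda c: c.replicate)


# ---------------------------------------------------------------------------
# design config file
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> ExperimentDesign:
    """Load and validate an experiment design from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return design_from_dict(raw)


def design_from_dict(raw: dict) -> ExperimentDesign:
    try:
        plex = int(raw["plex_size"])
        track = str(raw["track"])
        chan_raw = raw["channels"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"design config missing required key: {exc}") from exc
    channels = [
        ChannelDesign(
            label=str(c["label"]),
            role=str(c["role"]),
            compound_id=str(c.get("compound", c.get("compound_id", "")) or ""),
            stereoisomer=str(c.get("stereoisomer", "none") or "none"),
            replicate=int(c.get("replicate", 1)),
            excluded=bool(c.get("excluded", False)),
        )
        for c in chan_raw
    ]
    sc_raw = raw.get("stereochemistry", {}) or {}
    stereo = Stereochemistry(
        enantiomer_pairs=tuple(
            (str(a), str(b)) for a, b in sc_raw.get("enantiomer_pairs", [])
        ),
        families=tuple(tuple(map(str, f)) for f in sc_raw.get("families", [])),
        competitor_of={str(k): str(v) for k, v in (sc_raw.get("competitor_of") or {}).items()},
    )
    return ExperimentDesign(
        plex_size=plex,
        track=track,
        channels=channels,
        protease=str(raw.get("protease", "trypsin")),
        stereochemistry=stereo,
    )


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    raw = {
        "plex_size": design.plex_size,
        "track": design.track,
        "protease": design.protease,
        "channels": [
            {
                "label": c.label,
                "role": c.role,
                "compound": c.compound_id,
                "stereoisomer": c.stereoisomer,
                "replicate": c.replicate,
                "excluded": c.excluded,
            }
            for c in design.channels
        ],
        "stereochemistry": {
            "enantiomer_pairs": [list(p) for p in design.stereochemistry.enantiomer_pairs],
            "families": [list(f) for f in design.stereochemistry.families],
            "competitor_of": dict(design.stereochemistry.competitor_of),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# stereochemistry pairing report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairingReport:
    """Resolved selectivity relationships for the compounds of a design.

    ``enantiomer`` maps each compound to its mirror image; ``diastereomers``
    maps a compound to the two family members that are neither itself nor its
    enantiomer (defined only when exactly two such members are declared, so
    diastereoselectivity is computable as a ratio to their average).
    """

    enantiomer: dict[str, str]
    diastereomers: dict[str, tuple[str, str]]

    def has_enantiomer(self, compound: str) -> bool:
        return compound in self.enantiomer


def validate_pairing(design: ExperimentDesign) -> PairingReport:
    sc = design.stereochemistry
    enant: dict[str, str] = {}
    for a, b in sc.enantiomer_pairs:
        if a == b:
            raise DesignError(f"compound {a!r} declared as its own enantiomer")
        enant[a] = b
        enant[b] = a
    dia: dict[str, tuple[str, str]] = {}
    for fam in sc.families:
        for cmpd in fam:
            others = tuple(x for x in fam if x != cmpd and x != enant.get(cmpd))
            if len(others) == 2:
                dia[cmpd] = (others[0], others[1])
    return PairingReport(enantiomer=enant, diastereomers=dia)


# ---------------------------------------------------------------------------
# PSM records and tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSMRecord:
    """One quantified peptide-spectrum match."""

    psm_id: str
    protein_accession: str
    gene_symbol: str
    peptide_sequence: str
    charge: int
    modifications: tuple[tuple[int, float], ...]
    site_positions: tuple[int, ...]
    reporter_intensities: np.ndarray
    isolation_purity: float
    signal_to_noise: float
    peptide_start: int = 1
    unique_peptide: bool = True


class PSMTable:
    """PSM collection bound to a design; thin wrapper around a DataFrame.

    Intensity access goes through channel labels so any column permutation of
    the underlying file yields an identical table.
    """

    def __init__(self, df: pd.DataFrame, design: ExperimentDesign):
        self.design = design
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def intensity_matrix(self, labels: Sequence[str] | None = None) -> np.ndarray:
        labels = list(labels) if labels is not None else self.design.included_labels
        cols = [f"intensity_{l}" for l in labels]
        return self.df[cols].to_numpy(dtype=float)

    def records(self) -> Iterator[PSMRecord]:
        labels = self.design.included_labels
        inten = self.intensity_matrix(labels)
        for i, row in self.df.iterrows():
            mods = parse_modifications(row["modifications"])
            yield PSMRecord(
                psm_id=str(row["psm_id"]),
                protein_accession=row["protein_accession"],
                gene_symbol=row.get("gene_symbol", ""),
                peptide_sequence=row["peptide_sequence"],
                charge=int(row["charge"]),
                modifications=mods,
                site_positions=site_positions(
                    mods, int(row["peptide_start"]), len(row["peptide_sequence"])
                ),
                reporter_intensities=inten[i],
                isolation_purity=float(row["isolation_purity"]),
                signal_to_noise=float(row["signal_to_noise"]),
                peptide_start=int(row["peptide_start"]),
                unique_peptide=bool(row["unique_peptide"]),
            )


def parse_modifications(text: object) -> tuple[tuple[int, float], ...]:
    """Parse ``"pos:mass;pos:mass"`` into ((pos, mass), ...)."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return ()
    s = str(text).strip()
    if not s:
        return ()
    out = []
    for part in s.split(";"):
        try:
            pos, mass = part.split(":")
            out.append((int(pos), float(mass)))
        except ValueError as exc:
            raise FormatError(f"malformed modification field {text!r}") from exc
    return tuple(out)


def format_modifications(mods: Iterable[tuple[int, float]]) -> str:
    return ";".join(f"{p}:{m:.5f}" for p, m in mods)


def is_probe_mod(mass: float) -> bool:
    return abs(mass - IA_DTB_MASS) <= IA_DTB_TOL


def site_positions(
    mods: Iterable[tuple[int, float]], peptide_start: int, peptide_len: int
) -> tuple[int, ...]:
    """Protein-coordinate (1-based) residues carrying the IA-DTB adduct."""
    out = []
    for pos, mass in mods:
        if pos < 1 or pos > peptide_len:
            raise ValidationError(
                f"modification position {pos} outside peptide of length {peptide_len}"
            )
        if is_probe_mod(mass):
            out.append(peptide_start + pos - 1)
    return tuple(out)


def ensure_site_positions(df: pd.DataFrame) -> pd.DataFrame:
    """Return ``df`` with a ``site_positions`` column (comma-joined protein
    coordinates of IA-DTB-labeled residues), deriving it from the
    ``modifications`` and ``peptide_start`` fields when absent."""
    if "site_positions" in df.columns:
        return df
    df = df.copy()
    sites = []
    for _, row in df.iterrows():
        mods = parse_modifications(row["modifications"])
        sites.append(
            ",".join(
                map(
                    str,
                    site_positions(
                        mods,
                        int(row["peptide_start"]),
                        len(str(row["peptide_sequence"])),
                    ),
                )
            )
        )
    df["site_positions"] = sites
    return df


def read_psm_table(path: str | Path | _io.IOBase, design: ExperimentDesign) -> PSMTable:
    """Read a PSM TSV and bind its intensity columns to the design's channels.

    Raises :class:`FormatError` for a missing required column,
    :class:`DesignMismatchError` for an intensity column whose label is not in
    the design, and :class:`ValidationError` (naming the row) for negative
    intensities.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"psm_id": str, "modifications": str},
        float_precision="round_trip",
    )
    required = [c for c in _META_COLUMNS if c not in ("gene_symbol", "unique_peptide")]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"PSM table is missing required column {col!r}")
    if "gene_symbol" not in df.columns:
        df["gene_symbol"] = ""
    if "unique_peptide" not in df.columns:
        df["unique_peptide"] = True
    intensity_cols = [c for c in df.columns if c.startswith("intensity_")]
    file_labels = {c[len("intensity_"):] for c in intensity_cols}
    known = set(design.labels)
    unknown = file_labels - known
    if unknown:
        raise DesignMismatchError(
            f"intensity columns for channels not in design: {sorted(unknown)}"
        )
    missing = set(design.included_labels) - file_labels
    if missing:
        raise FormatError(
            f"PSM table is missing intensity columns for channels: {sorted(missing)}"
        )
    for col in intensity_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        raw_missing = df[col].isna() | (df[col].astype(str).str.strip() == "")
        bad = vals.isna() & ~raw_missing
        if bad.any():
            raise ValidationError(
                f"non-numeric intensity in column {col!r}, row psm_id="
                f"{df.loc[bad.idxmax(), 'psm_id']}"
            )
        neg = vals < 0
        if neg.any():
            raise ValidationError(
                f"negative intensity in column {col!r}, row psm_id="
                f"{df.loc[neg.idxmax(), 'psm_id']}"
            )
        df[col] = vals
    if (df["modifications"].isna()).any():
        df["modifications"] = df["modifications"].fillna("")
    # materialize site positions once; malformed rows fail loudly with psm_id
    sites = []
    for _, row in df.iterrows():
        try:
            mods = parse_modifications(row["modifications"])
            sites.append(
                ",".join(
                    map(
                        str,
                        site_positions(
                            mods, int(row["peptide_start"]), len(str(row["peptide_sequence"]))
                        ),
                    )
                )
            )
        except (FormatError, ValidationError) as exc:
            raise type(exc)(f"row psm_id={row['psm_id']}: {exc}") from exc
    df["site_positions"] = sites
    return PSMTable(df, design)


def write_psm_table(table: PSMTable | pd.DataFrame, path: str | Path) -> None:
    df = table.df if isinstance(table, PSMTable) else table
    df = df.drop(columns=["site_positions"], errors="ignore")
    df.to_csv(path, sep="\t", index=False)
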