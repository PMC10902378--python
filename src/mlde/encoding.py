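"""Physicochemical variant encoding.

Variants are represented numerically by concatenating, site by site, a
fixed-length vector of amino-acid descriptor values at each modulated
position.  With the default table of 13 descriptors and S modulated
sites, a variant becomes a 13*S-dimensional feature vector — e.g. 39
dimensions for a 3-site library and 65 for a 5-site library.

The default descriptor set is a curated stand-in of 13 classical scales
(hydropathy, volume, polarity, charge, flexibility, secondary-structure
propensities, ...) of the kind collected in the AAindex database.  Any
user-supplied table of per-residue scales can be substituted; all
operations take the table as an argument.

Descriptors are standardized to zero mean and unit variance across the
20-residue alphabet (not across any particular training set), so the
encoding of a variant is dataset-independent and reusable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variants import AA_ALPHABET, ProteinVariant, parse_variant

# Residue order: ACDEFGHIKLMNPQRSTVWY.
# Sources are classical published scales; the set is an explicit,
# documented default and is fully user-replaceable.
_DEFAULT_SCALES: dict[str, list[float]] = {
    # Kyte & Doolittle hydropathy
    "hydropathy": [1.8, 2.5, -3.5, -3.5, 2.8, -0.4, -3.2, 4.5, -3.9, 3.8,
                   1.9, -3.5, -1.6, -3.5, -4.5, -0.8, -0.7, 4.2, -0.9, -1.3],
    # Zamyatnin residue volume, A^3
    "volume": [88.6, 108.5, 111.1, 138.4, 189.9, 60.1, 153.2, 166.7, 168.6,
               166.7, 162.9, 114.1, 112.7, 143.8, 173.4, 89.0, 116.1, 140.0,
               227.8, 193.6],
    # Grantham polarity
    "polarity": [8.1, 5.5, 13.0, 12.3, 5.2, 9.0, 10.4, 5.2, 11.3, 4.9, 5.7,
                 11.6, 8.0, 10.5, 10.5, 9.2, 8.6, 5.9, 5.4, 6.2],
    # isoelectric point of the free amino acid
    "isoelectric_point": [6.00, 5.07, 2.77, 3.22, 5.48, 5.97, 7.59, 6.02,
                          9.74, 5.98, 5.74, 5.41, 6.30, 5.65, 10.76, 5.68,
                          5.60, 5.96, 5.89, 5.66],
    # net side-chain charge at pH 7 (His partially protonated)
    "net_charge": [0.0, 0.0, -1.0, -1.0, 0.0, 0.0, 0.1, 0.0, 1.0, 0.0, 0.0,
                   0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    # Hopp & Woods hydrophilicity
    "hydrophilicity": [-0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8, 3.0,
                       -1.8, -1.3, 0.2, 0.0, 0.2, 3.0, 0.3, -0.4, -1.5,
                       -3.4, -2.3],
    # Bhaskaran & Ponnuswamy average flexibility
    "flexibility": [0.357, 0.346, 0.511, 0.497, 0.314, 0.544, 0.323, 0.462,
                    0.466, 0.365, 0.295, 0.463, 0.509, 0.493, 0.529, 0.507,
                    0.444, 0.386, 0.305, 0.420],
    # Chou & Fasman alpha-helix propensity
    "helix_propensity": [1.42, 0.70, 1.01, 1.51, 1.13, 0.57, 1.00, 1.08,
                         1.16, 1.21, 1.45, 0.67, 0.57, 1.11, 0.98, 0.77,
                         0.83, 1.06, 1.08, 0.69],
    # Chou & Fasman beta-sheet propensity
    "sheet_propensity": [0.83, 1.19, 0.54, 0.37, 1.38, 0.75, 0.87, 1.60,
                         0.74, 1.30, 1.05, 0.89, 0.55, 1.10, 0.93, 0.75,
                         1.19, 1.70, 1.37, 1.47],
    # Chou & Fasman beta-turn propensity
    "turn_propensity": [0.66, 1.19, 1.46, 0.74, 0.60, 1.56, 0.95, 0.47,
                        1.01, 0.59, 0.60, 1.56, 1.52, 0.98, 0.95, 1.43,
                        0.96, 0.50, 0.96, 1.14],
    # maximum solvent-accessible surface area, A^2
    "surface_area": [113.0, 140.0, 151.0, 183.0, 218.0, 85.0, 194.0, 182.0,
                     211.0, 180.0, 204.0, 158.0, 143.0, 189.0, 241.0, 122.0,
                     146.0, 160.0, 259.0, 229.0],
    # residue molecular weight, Da
    "mass": [71.08, 103.14, 115.09, 129.12, 147.18, 57.05, 137.14, 113.16,
             128.17, 113.16, 131.19, 114.10, 97.12, 128.13, 156.19, 87.08,
             101.10, 99.13, 186.21, 163.18],
    # Charton & Charton side-chain polarizability
    "polarizability": [0.046, 0.128, 0.105, 0.151, 0.290, 0.000, 0.230,
                       0.186, 0.219, 0.186, 0.221, 0.134, 0.131, 0.180,
                       0.291, 0.062, 0.108, 0.140, 0.409, 0.298],
}

#: Number of descriptors per site in the default table.
N_DEFAULT_PROPERTIES = len(_DEFAULT_SCALES)


@dataclass(frozen=True)
class AAPropertyTable:
    """A standardized 20-residue x P-property descriptor table.

    ``raw`` keeps the original scale values; ``standardized`` has each
    property column centred and scaled to unit (population) variance
    across the 20 residues.
    """

    raw: pd.DataFrame
    standardized: pd.DataFrame = field(repr=False)
    version: str = "default-13-v1"

    @property
    def property_names(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def n_properties(self) -> int:
        return self.raw.shape[1]

    def vector(self, residue: str) -> np.ndarray:
        """Standardized descriptor vector for one residue."""
        if residue not in self.standardized.index:
            raise ValueError(f"residue {residue!r} is not a standard amino acid")
        return self.standardized.loc[residue].to_numpy(dtype=float)

    @classmethod
    def from_frame(cls, raw: pd.DataFrame, version: str = "user") -> "AAPropertyTable":
        if sorted(raw.index) != sorted(AA_ALPHABET):
            raise ValueError(
                f"property table must cover exactly the 20 standard residues; "
                f"got {len(raw.index)} rows"
            )
        if raw.isna().any().any():
            missing = raw.columns[raw.isna().any()].tolist()
            raise ValueError(f"property table has missing entries in {missing}")
        raw = raw.loc[list(AA_ALPHABET)].astype(float)
        mean = raw.mean(axis=0)
        sd = raw.std(axis=0, ddof=0)
        if (sd == 0).any():
            flat = raw.columns[sd == 0].tolist()
            raise ValueError(f"property columns with zero variance: {flat}")
        standardized = (raw - mean) / sd
        return cls(raw=raw, standardized=standardized, version=version)


def default_property_table() -> AAPropertyTable:
    """The curated default table of 13 standardized descriptor scales."""
    raw = pd.DataFrame(_DEFAULT_SCALES, index=list(AA_ALPHABET))
    return AAPropertyTable.from_frame(raw, version="default-13-v1")


def read_property_table(path) -> AAPropertyTable:
    """Load a user table from delimited text: residue rows x property columns."""
    raw = pd.read_csv(path, index_col=0)
    return AAPropertyTable.from_frame(raw)


def encode_variant(
    variant: ProteinVariant | str,
    sites: Sequence[int],
    table: AAPropertyTable,
    parent_sequence: str,
    parent_name: str = "WT",
) -> np.ndarray:
    """Concatenated per-site descriptor vectors, in site order.

    Sites the variant does not substitute use the parent residue.  Only
    the listed sites enter the encoding, so variants identical there are
    encoded identically regardless of substitutions elsewhere.
    """
    if isinstance(variant, str):
        variant = parse_variant(variant, parent=parent_name)
    parts = []
    for pos in sites:
        res = variant.residue_at(pos, parent_sequence)
        parts.append(table.vector(res))
    return np.concatenate(parts) if parts else np.empty(0)


@dataclass(frozen=True)
class TrainingMatrix:
    """Feature matrix with labels, one row per unique variant.

    Rows are ordered lexicographically by variant name; columns are the
    per-site descriptor blocks in site order (P properties x S sites).
    """

    variant_names: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    sites: tuple[int, ...]
    property_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.variant_names), len(self.property_names) * len(self.sites)):
            raise ValueError(
                f"feature matrix shape {self.X.shape} inconsistent with "
                f"{len(self.variant_names)} variants x "
                f"{len(self.property_names)} properties x {len(self.sites)} sites"
            )
        if len(self.y) != len(self.variant_names):
            raise ValueError("label count does not match row count")
        if len(set(self.variant_names)) != len(self.variant_names):
            raise ValueError("variant names are not unique")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("labels must be finite")

    @property
    def n(self) -> int:
        return len(self.variant_names)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"s{pos}_{prop}" for pos in self.sites for prop in self.property_names]
        df = pd.DataFrame(self.X, index=list(self.variant_names), columns=cols)
        df.insert(0, "label", self.y)
        df.index.name = "variant_name"
        return df


def build_training_matrix(
    records,
    sites: Sequence[int],
    table: AAPropertyTable,
    parent_sequence: str,
    parent_name: str = "WT",
    aggregate: str = "mean",
) -> TrainingMatrix:
    """Aggregate labelled activity records into a training matrix.

    Records must carry plate-normalized labels (``fiop``).  Replicate
    rows of the same variant are aggregated (mean by default, or max);
    substitution strings are validated letter-by-letter against the
    parent sequence.
    """
    if aggregate not in ("mean", "max"):
        raise ValueError(f"unknown aggregation policy {aggregate!r}")
    labels: dict[str, list[float]] = {}
    for rec in records:
        if rec.fiop is None:
            raise ValueError(
                f"record for {rec.variant_name!r} has no normalized label; "
                "run plate normalization first"
            )
        variant = parse_variant(rec.variant_name, parent=parent_name)
        variant.validate_against(parent_sequence)
        labels.setdefault(variant.name, []).append(float(rec.fiop))

    names = sorted(labels)
    agg = np.mean if aggregate == "mean" else np.max
    y = np.array([agg(labels[name]) for name in names], dtype=float)
    X = np.vstack(
        [encode_variant(name, sites, table, parent_sequence, parent_name) for name in names]
    ) if names else np.empty((0, table.n_properties * len(sites)))
    return TrainingMatrix(
        variant_names=tuple(names),
        X=X,
        y=y,
        sites=tuple(int(s) for s in sites),
        property_names=tuple(table.property_names),
    )
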