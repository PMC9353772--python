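"""Aligned feature x sample matrices for untargeted metabolomics.

The sole experimental input of the workflow: a matrix of spectral features
(rows, each with a neutral monoisotopic mass in Da) by samples (columns,
each with a class label), holding intensities with missing values. Missing
is a first-class state (NaN internally) and is never conflated with zero
after ingestion — feature *occurrence* is the information source for the
network methods downstream.

On disk the matrix is a TSV/CSV whose first columns are ``feature_id`` and
``neutral_mass`` followed by one column per sample; class labels and blank
sample ids live in a sidecar YAML/JSON config mapping sample ids to classes
(avoids fragile sample-name parsing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlignedMatrix",
    "read_aligned_matrix",
    "write_aligned_matrix",
    "read_sample_config",
    "filter_min_global_occurrence",
    "filter_min_class_occurrence",
    "subtract_blanks",
    "merge_duplicate_masses",
]


@dataclass
class AlignedMatrix:
    """Features x samples intensity matrix with masses and class labels.

    Parameters
    ----------
    intensities
        DataFrame indexed by feature id (unique strings), one column per
        sample id (unique); ``NaN`` encodes MISSING, every finite value is
        a nonnegative intensity.
    neutral_mass
        Series of positive neutral monoisotopic masses (Da), indexed like
        ``intensities``.
    classes
        Optional Series mapping sample id to class label.
    """

    intensities: pd.DataFrame
    neutral_mass: pd.Series
    classes: pd.Series | None = None

    def __post_init__(self) -> None:
        self.intensities = self.intensities.astype(float)
        self.neutral_mass = self.neutral_mass.astype(float).reindex(self.intensities.index)
        if self.classes is not None:
            self.classes = pd.Series(self.classes).reindex(self.intensities.columns)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        idx = self.intensities.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.neutral_mass.isna().any():
            raise ValueError("every feature needs a neutral mass")
        if (self.neutral_mass <= 0).any():
            bad = self.neutral_mass[self.neutral_mass <= 0].index.tolist()
            raise ValueError(f"non-positive neutral mass for features {bad}")
        if self.n_samples and self.intensities.notna().sum(axis=0).eq(0).any():
            empty = self.intensities.columns[self.intensities.notna().sum(axis=0) == 0]
            raise ValueError(f"samples with no non-missing values: {list(empty)}")
        if self.classes is not None and self.classes.isna().any():
            missing = self.classes[self.classes.isna()].index.tolist()
            raise ValueError(f"samples without class label: {missing}")

    # -- convenience -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def presence(self) -> pd.DataFrame:
        """Boolean occurrence matrix (True where a value was measured)."""
        return self.intensities.notna()

    def features_of_sample(self, sample_id: str) -> list[str]:
        col = self.intensities[sample_id]
        return list(col.index[col.notna()])

    def select_features(self, feature_ids: Sequence[str]) -> "AlignedMatrix":
        return replace(
            self,
            intensities=self.intensities.loc[list(feature_ids)],
            neutral_mass=self.neutral_mass.loc[list(feature_ids)],
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "AlignedMatrix":
        cls = self.classes.loc[list(sample_ids)] if self.classes is not None else None
        return AlignedMatrix(self.intensities[list(sample_ids)], self.neutral_mass, cls)

    def with_intensities(self, values: pd.DataFrame) -> "AlignedMatrix":
        return AlignedMatrix(values, self.neutral_mass.loc[values.index],
                             None if self.classes is None else self.classes.loc[values.columns])


# -- I/O -----------------------------------------------------------------

def read_sample_config(path: str | Path) -> tuple[dict[str, str], list[str]]:
    """Read the sidecar config: {'classes': {sample: label}, 'blanks': [...]}.

    YAML or JSON, decided by extension (.yaml/.yml vs anything else).
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        cfg = yaml.safe_load(path.read_text())
    else:
        cfg = json.loads(path.read_text())
    classes = {str(k): str(v) for k, v in (cfg.get("classes") or {}).items()}
    blanks = [str(b) for b in (cfg.get("blanks") or [])]
    return classes, blanks


def read_aligned_matrix(
    path: str | Path,
    zero_is_missing: bool = True,
    classes: Mapping[str, str] | str | Path | None = None,
    sep: str | None = None,
) -> AlignedMatrix:
    """Read an aligned matrix from TSV/CSV.

    Layout: columns ``feature_id``, ``neutral_mass`` (or the first column
    being the mass if no ``feature_id`` column is present, in which case
    ids ``F0001...`` are assigned), then one intensity column per sample.
    Empty cells — and zeros, when ``zero_is_missing`` (the default, since
    alignment tools commonly emit 0 for absence) — become MISSING.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    cols = list(df.columns)
    if "feature_id" in cols:
        df = df.set_index("feature_id")
        mass_col = "neutral_mass" if "neutral_mass" in df.columns else df.columns[0]
    else:
        mass_col = "neutral_mass" if "neutral_mass" in cols else cols[0]
        df.index = pd.Index([f"F{i + 1:04d}" for i in range(len(df))], name="feature_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups}")
    masses = pd.to_numeric(df[mass_col], errors="coerce")
    if masses.isna().any():
        row = int(np.flatnonzero(masses.isna().to_numpy())[0])
        raise ValueError(f"{path}: non-numeric mass at data row {row} (feature {df.index[row]!r})")
    intens = df.drop(columns=[mass_col]).apply(pd.to_numeric, errors="coerce")
    if (intens < 0).any().any():
        raise ValueError(f"{path}: negative intensities are not allowed")
    if zero_is_missing:
        intens = intens.where(intens != 0)
    cls = None
    if classes is not None:
        if isinstance(classes, (str, Path)):
            classes, _ = read_sample_config(classes)
        cls = pd.Series({s: classes[s] for s in intens.columns if s in classes})
        missing = [s for s in intens.columns if s not in classes]
        if missing:
            raise ValueError(f"no class label for samples {missing}")
        cls = cls.reindex(intens.columns)
    return AlignedMatrix(intens, masses, cls)


def write_aligned_matrix(m: AlignedMatrix, path: str | Path, mass_decimals: int = 6) -> None:
    """Write TSV/CSV (by extension); MISSING cells are written empty."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    out = m.intensities.copy()
    out.insert(0, "neutral_mass", m.neutral_mass.round(mass_decimals))
    out.index.name = "feature_id"
    out.to_csv(path, sep=sep, na_rep="")


# -- filtering / cleaning ------------------------------------------------

def filter_min_global_occurrence(m: AlignedMatrix, k: int) -> AlignedMatrix:
    """Keep features with >= k non-missing values across all samples.

    The mild reproducibility filter: features seen only once in the whole
    study are usually noise.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    keep = m.presence().sum(axis=1) >= k
    if not keep.any():
        raise ValueError(f"no feature occurs in at least {k} samples")
    return m.select_features(list(m.intensities.index[keep]))


def filter_min_class_occurrence(m: AlignedMatrix, k: int) -> AlignedMatrix:
    """Keep features with >= k non-missing values within at least one class."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if m.classes is None:
        raise ValueError("class labels required for per-class filtering")
    pres = m.presence()
    per_class = pres.T.groupby(m.classes).sum().T  # features x classes
    keep = (per_class >= k).any(axis=1)
    if not keep.any():
        raise ValueError(f"no feature occurs at least {k} times in any class")
    return m.select_features(list(m.intensities.index[keep]))


def subtract_blanks(m: AlignedMatrix, blank_sample_ids: Iterable[str]) -> AlignedMatrix:
    """Subtract the mean blank intensity per feature; <= 0 becomes MISSING.

    Blank samples are dropped from the output. Cells missing on input stay
    missing.
    """
    blanks = list(blank_sample_ids)
    unknown = [b for b in blanks if b not in m.sample_ids]
    if unknown:
        raise ValueError(f"unknown blank sample ids: {unknown}")
    keep = [s for s in m.sample_ids if s not in set(blanks)]
    if not keep:
        raise ValueError("all samples are blanks")
    blank_mean = m.intensities[blanks].mean(axis=1, skipna=True).fillna(0.0)
    corrected = m.intensities[keep].sub(blank_mean, axis=0)
    corrected = corrected.where(corrected > 0)
    cls = m.classes.loc[keep] if m.classes is not None else None
    return AlignedMatrix(corrected, m.neutral_mass, cls)


def merge_duplicate_masses(
    m: AlignedMatrix, mass_decimals: int = 6, combine: str = "sum"
) -> AlignedMatrix:
    """Merge features whose masses coincide after rounding.

    Occurrence becomes the union; intensities of co-occurring duplicates are
    combined by ``combine`` ("sum" by default, or "max"/"mean"). The merged
    feature keeps the first contributor's id and the mean of the contributing
    masses. Presence/absence — what the network layer consumes — does not
    depend on ``combine``.
    """
    if mass_decimals < 0:
        raise ValueError("mass_decimals must be >= 0")
    if combine not in {"sum", "max", "mean"}:
        raise ValueError(f"unknown combine mode {combine!r}")
    key = m.neutral_mass.round(mass_decimals)
    if key.is_unique:
        return m
    groups = m.intensities.groupby(key, sort=False)
    agg = getattr(groups, combine)()  # NaN-skipping; all-NaN group -> 0
    counts = groups.count()
    agg = agg.where(counts > 0)
    first_ids = m.intensities.index.to_series().groupby(key, sort=False).first()
    mean_mass = m.neutral_mass.groupby(key, sort=False).mean()
    agg.index = pd.Index(first_ids.values, name="feature_id")
    mass = pd.Series(mean_mass.values, index=agg.index)
    return AlignedMatrix(agg, mass, m.classes)
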