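"""Assemble the combined named feature matrix for a dataset.

Four switchable families:

* PSF — amino-acid k-word content features (k = 1, 2; 420 columns)
* PPF — amino-acid k-word position features (k = 1, 2; 420 columns)
* RCF — reduced-alphabet content + position block (24 columns)
* PSSF — secondary-structure descriptors (22 or 11 per preset)
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pscpred.io_formats import AA_ALPHABET, Dataset
from pscpred.reduced import REDUCED_FEATURE_NAMES, reduced_feature_vector
from pscpred.seqfeat import KmerIndex, feature_names, scf_vector, spf_vector
from pscpred.ssfeat import PRESETS, ss_feature_vector

FAMILIES = ("PSF", "PPF", "RCF", "PSSF")

_AA_IDX1 = KmerIndex(AA_ALPHABET, 1)
_AA_IDX2 = KmerIndex(AA_ALPHABET, 2)


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature families to extract and how."""

    psf: bool = True
    ppf: bool = True
    rcf: bool = True
    pssf: bool = True
    ss_preset: str = "full"

    def __post_init__(self) -> None:
        if self.ss_preset not in PRESETS:
            raise ValueError(f"unknown SS preset {self.ss_preset!r}")
        if not (self.psf or self.ppf or self.rcf or self.pssf):
            raise ValueError("at least one feature family must be enabled")

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(**{k: d[k] for k in ("psf", "ppf", "rcf", "pssf", "ss_preset") if k in d})


@dataclass
class FeatureMatrix:
    """n_samples x d real matrix with stable, globally unique column names."""

    ids: tuple[str, ...]
    names: tuple[str, ...]
    families: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.names)} names"
            )
        if len(self.families) != len(self.names):
            raise ValueError("one family tag per feature required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return len(self.names)

    def subset(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given name order."""
        lookup = {n: i for i, n in enumerate(self.names)}
        try:
            cols = [lookup[n] for n in names]
        except KeyError as exc:
            raise KeyError(f"unknown feature name {exc.args[0]!r}") from exc
        return FeatureMatrix(
            ids=self.ids,
            names=tuple(names),
            families=tuple(self.families[c] for c in cols),
            values=self.values[:, cols],
        )

    # -- CSV round trip ---------------------------------------------------
    # Layout: header row of names, second row of family tags, then one row
    # per sample with the id in the first column.  Floats use repr-exact
    # formatting so identical matrices serialize to identical bytes.

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("id," + ",".join(self.names) + "\n")
            fh.write("family," + ",".join(self.families) + "\n")
            for rid, row in zip(self.ids, self.values):
                fh.write(rid + "," + ",".join(format(v, ".17g") for v in row) + "\n")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")
            famrow = fh.readline().rstrip("\n").split(",")
            if not header or header[0] != "id" or famrow[0] != "family":
                raise ValueError(f"{path}: not a feature-matrix CSV")
            names = tuple(header[1:])
            families = tuple(famrow[1:])
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(",")
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        values = np.array(rows, dtype=float) if rows else np.empty((0, len(names)))
        return cls(ids=tuple(ids), names=names, families=families, values=values)


def feature_layout(config: FeatureConfig) -> tuple[list[str], list[str]]:
    """Column names and family tags for a config, in extraction order."""
    names: list[str] = []
    fams: list[str] = []
    if config.psf:
        block = feature_names("scf", _AA_IDX1) + feature_names("scf", _AA_IDX2)
        names += block
        fams += ["PSF"] * len(block)
    if config.ppf:
        block = feature_names("spf", _AA_IDX1) + feature_names("spf", _AA_IDX2)
        names += block
        fams += ["PPF"] * len(block)
    if config.rcf:
        names += REDUCED_FEATURE_NAMES
        fams += ["RCF"] * len(REDUCED_FEATURE_NAMES)
    if config.pssf:
        block = PRESETS[config.ss_preset]
        names += list(block)
        fams += ["PSSF"] * len(block)
    return names, fams


def build_feature_matrix(
    ds: Dataset, config: FeatureConfig = FeatureConfig()
) -> FeatureMatrix:
    """Extract all enabled families for every record, rows in dataset order."""
    if config.pssf:
        missing = [r.id for r in ds if r.ss_seq is None]
        if missing:
            raise ValueError(
                f"PSSF enabled but records lack SS strings: {missing}"
            )
    names, fams = feature_layout(config)
    rows = []
    for r in ds:
        blocks = []
        if config.psf:
            blocks.append(scf_vector(r.aa_seq, 1, _AA_IDX1))
            blocks.append(scf_vector(r.aa_seq, 2, _AA_IDX2))
        if config.ppf:
            blocks.append(spf_vector(r.aa_seq, 1, _AA_IDX1))
            blocks.append(spf_vector(r.aa_seq, 2, _AA_IDX2))
        if config.rcf:
            blocks.append(reduced_feature_vector(r.aa_seq))
        if config.pssf:
            blocks.append(ss_feature_vector(r.ss_seq, preset=config.ss_preset))
        rows.append(np.concatenate(blocks))
    values = np.vstack(rows) if rows else np.empty((0, len(names)))
    return FeatureMatrix(
        ids=tuple(ds.ids), names=tuple(names), families=tuple(fams), values=values
    )
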