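"""Readers/writers for the formats the pipeline touches and dataset assembly.

Sequences come in as FASTA, secondary structure either as a FASTA of
H/E/C strings or as per-protein PSI-PRED VFORMAT ``.ss2`` files, and
labels as a two-column TSV.  :func:`assemble_dataset` joins the three
sources into a validated :class:`Dataset` whose record order follows the
label file (that order drives every downstream split, so it must be
stable).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

#: The 20 standard one-letter amino-acid codes, lexicographic.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: 3-state secondary structure symbols: helix, strand, coil.
SS_ALPHABET = "HEC"

#: Canonical structural class names, fixed order.
CLASSES = ("all-alpha", "all-beta", "alpha/beta", "alpha+beta")

#: Accepted spellings for each class (keys lowercased before lookup).
DEFAULT_CLASS_ALIASES: dict[str, str] = {
    "a": "all-alpha",
    "alpha": "all-alpha",
    "all-a": "all-alpha",
    "all-alpha": "all-alpha",
    "b": "all-beta",
    "beta": "all-beta",
    "all-b": "all-beta",
    "all-beta": "all-beta",
    "a/b": "alpha/beta",
    "alpha/beta": "alpha/beta",
    "a+b": "alpha+beta",
    "alpha+beta": "alpha+beta",
}

# Common dialect drift in secondary-structure files: '-' and 'L' mean coil.
_COIL_ALIASES = {"-": "C", "L": "C"}


class FormatError(ValueError):
    """A file does not conform to its expected format."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: id, amino-acid sequence, optional SS string and label."""

    id: str
    aa_seq: str
    ss_seq: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.aa_seq) < 1:
            raise ValueError(f"record {self.id!r}: empty amino-acid sequence")
        bad = set(self.aa_seq) - set(AA_ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-standard residues {sorted(bad)}"
            )
        if self.ss_seq is not None:
            if len(self.ss_seq) != len(self.aa_seq):
                raise ValueError(
                    f"record {self.id!r}: aa length {len(self.aa_seq)} != "
                    f"ss length {len(self.ss_seq)}"
                )
            bad_ss = set(self.ss_seq) - set(SS_ALPHABET)
            if bad_ss:
                raise ValueError(
                    f"record {self.id!r}: invalid SS symbols {sorted(bad_ss)}"
                )
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(
                f"record {self.id!r}: unknown class {self.label!r}; "
                f"accepted: {list(CLASSES)}"
            )


@dataclass
class Dataset:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    # -- plain-text round trip -------------------------------------------

    def write_fasta(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.id}\n{r.aa_seq}\n")

    def write_ss_fasta(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                if r.ss_seq is None:
                    raise ValueError(f"record {r.id!r} has no SS string")
                fh.write(f">{r.id}\n{r.ss_seq}\n")

    def write_labels(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("# id\tclass\n")
            for r in self.records:
                if r.label is None:
                    raise ValueError(f"record {r.id!r} has no label")
                fh.write(f"{r.id}\t{r.label}\n")


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``(id, sequence)`` pairs, order preserved.

    Sequences are uppercased and stripped of whitespace.  The id is the
    first whitespace-delimited token of the header line.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first:
            return []
        if not first.startswith(">"):
            raise FormatError(
                f"{path}: not FASTA (first non-blank line does not start with '>')"
            )
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            rid = header.split()[0] if header.split() else header
            seq = "".join(seq.split()).upper()
            if not seq:
                raise FormatError(f"{path}: record {rid!r} has an empty body")
            out.append((rid, seq))
    return out


def read_ss2(path: str | os.PathLike) -> str:
    """Read a PSI-PRED VFORMAT ``.ss2`` file and return the H/E/C string.

    Header/comment lines start with ``#``; data rows are
    ``index residue state conf_C conf_H conf_E``.  Row indices must be
    contiguous starting at 1.  ``-`` and ``L`` are accepted as coil.
    """
    path = Path(path)
    states: list[str] = []
    expected = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            try:
                idx = int(parts[0])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad index {parts[0]!r}") from exc
            if idx != expected:
                raise FormatError(
                    f"{path}:{lineno}: non-contiguous index {idx} (expected {expected})"
                )
            state = parts[2].upper()
            state = _COIL_ALIASES.get(state, state)
            if state not in SS_ALPHABET:
                raise FormatError(f"{path}:{lineno}: invalid state {parts[2]!r}")
            states.append(state)
            expected += 1
    return "".join(states)


def read_ss_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file whose bodies are H/E/C strings (coil aliases ok)."""
    out = []
    for rid, seq in read_fasta(path):
        ss = "".join(_COIL_ALIASES.get(c, c) for c in seq)
        bad = set(ss) - set(SS_ALPHABET)
        if bad:
            raise FormatError(
                f"{path}: record {rid!r}: invalid SS symbols {sorted(bad)}"
            )
        out.append((rid, ss))
    return out


def read_labels(
    path: str | os.PathLike,
    aliases: Mapping[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Read a two-column TSV of ``id<TAB>class``; '#' starts a comment line.

    Class tokens are normalized through the alias table (case-insensitive).
    """
    path = Path(path)
    table = dict(DEFAULT_CLASS_ALIASES)
    if aliases:
        table.update({k.lower(): v for k, v in aliases.items()})
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            rid, token = parts[0].strip(), parts[1].strip()
            cls = table.get(token.lower())
            if cls is None:
                raise FormatError(
                    f"{path}:{lineno}: unknown class {token!r}; "
                    f"accepted spellings: {sorted(table)}"
                )
            out.append((rid, cls))
    return out


def _load_ss_source(
    ss_source: str | os.PathLike | None, ids: Iterable[str]
) -> dict[str, str]:
    if ss_source is None:
        return {}
    p = Path(ss_source)
    if p.is_dir():
        out = {}
        for rid in ids:
            f = p / f"{rid}.ss2"
            if not f.exists():
                raise FileNotFoundError(f"no SS file for {rid!r}: {f}")
            out[rid] = read_ss2(f)
        return out
    if p.suffix == ".ss2":
        raise FormatError(
            f"{p}: a single .ss2 file covers one protein; pass a directory "
            "of <id>.ss2 files or a FASTA of H/E/C strings"
        )
    return dict(read_ss_fasta(p))


def assemble_dataset(
    fasta: str | os.PathLike,
    ss_source: str | os.PathLike | None,
    labels: str | os.PathLike,
    *,
    class_aliases: Mapping[str, str] | None = None,
    residue_map: Mapping[str, str] | None = None,
) -> Dataset:
    """Join sequences, SS strings and labels into a validated Dataset.

    Records are ordered by label-file order.  Non-standard residues
    (B, Z, X, U, O, ...) are rejected unless ``residue_map`` maps them to
    standard ones, e.g. ``{"X": "A"}``.
    """
    seqs = dict(read_fasta(fasta))
    lab = read_labels(labels, aliases=class_aliases)
    ss = _load_ss_source(ss_source, [rid for rid, _ in lab])
    records = []
    for rid, cls in lab:
        if rid not in seqs:
            raise ValueError(f"label file id {rid!r} has no sequence in {fasta}")
        seq = seqs[rid]
        if residue_map:
            seq = "".join(residue_map.get(c, c) for c in seq)
        records.append(
            ProteinRecord(id=rid, aa_seq=seq, ss_seq=ss.get(rid), label=cls)
        )
    return Dataset(records=records)


def relabel(record: ProteinRecord, label: str) -> ProteinRecord:
    """Return a copy of ``record`` with a new label."""
    return replace(record, label=label)
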