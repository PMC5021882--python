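"""Readers and writers for the external formats the toolkit touches.

Covers FASTA sequences, DSSP secondary-structure files, PSI-BLAST ASCII
position-specific scoring matrices, BLAST tabular domain-hit files, and the
toolkit's own TSV feature matrices and label files.

Format conventions
------------------
* DSSP: residue records start after the header line beginning with
  ``  #  RESIDUE``. Per residue line, the chain identifier is the character
  at column 11, the amino acid at column 13 and the secondary-structure
  summary letter at column 16 (all 0-based). A blank structure field is
  encoded as ``L`` (irregular); chain-break rows (``!`` in the amino-acid
  column) contribute nothing.
* PSSM: the PSI-BLAST ASCII matrix. Header/comment lines are skipped; each
  residue row carries an index, the query residue, twenty log-odds integers
  and then trailing weighted-percentage and information columns, which are
  ignored.
* Domain hits: 12-column BLAST tabular (``-outfmt 6``), E-value in column 11
  (1-based); a ``gnl|CDD|`` prefix on the subject identifier is stripped.
* Feature matrices: TSV with a ``sample_id`` first column and one named
  descriptor per remaining column. Lines starting with ``#`` are metadata
  comments and are ignored on read.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProteinRecord",
    "DsspString",
    "PssmMatrix",
    "DomainHitTable",
    "FeatureGroupMatrix",
    "DSSP_STATES",
    "PSSM_COLUMNS",
    "read_fasta",
    "write_fasta",
    "parse_dssp",
    "parse_pssm",
    "parse_domain_hits",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_labels",
    "write_labels",
]

#: The eight-state secondary-structure alphabet, in the fixed report order
#: (three helix states, two strand states, turn, bend, irregular).
DSSP_STATES = "GHIEBTSL"

#: PSI-BLAST PSSM column ordering (the order printed in the ASCII matrix).
PSSM_COLUMNS = tuple("ARNDCQEGHILKMFPSTWYV")

_FEATURE_GROUP_NAMES = ("DSSP", "AAsCPP", "PSSM", "FunD")


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier and optional fold label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be nonempty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class DsspString:
    """Per-residue eight-state secondary structure of one chain.

    ``states`` is a string over ``{G,H,I,E,B,T,S,L}``; ``L`` stands for the
    blank "no secondary structure assigned" state of the DSSP output.
    """

    chain_id: str
    states: str

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("DSSP state string must be nonempty")
        bad = set(self.states) - set(DSSP_STATES)
        if bad:
            raise ValueError(f"invalid DSSP states: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class PssmMatrix:
    """An L x 20 log-odds profile from an iterative database search.

    ``scores[i, j]`` is the log-odds score of amino acid ``column_order[j]``
    at sequence position ``i``.
    """

    scores: np.ndarray
    row_residues: str
    column_order: tuple[str, ...] = PSSM_COLUMNS

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(f"PSSM must have 20 columns, got shape {scores.shape}")
        if scores.shape[0] < 1:
            raise ValueError("PSSM must have at least one row")
        if scores.shape[0] != len(self.row_residues):
            raise ValueError("row_residues length must equal number of rows")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class DomainHitTable:
    """Domain database hits: ``(domain_id, e_value)`` pairs."""

    hits: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        for domain_id, e_value in self.hits:
            if not domain_id:
                raise ValueError("domain id must be nonempty")
            if e_value < 0:
                raise ValueError(f"negative E-value for {domain_id}: {e_value}")


@dataclass
class FeatureGroupMatrix:
    """A named n x d feature block for one descriptor group."""

    group_name: str
    sample_ids: list[str]
    values: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.sample_ids), -1)
        n, d = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{self.group_name}: {len(self.sample_ids)} sample ids but {n} rows"
            )
        if d != len(self.column_names):
            raise ValueError(
                f"{self.group_name}: {len(self.column_names)} column names but {d} columns"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.column_names,
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    Sequences are uppercased; record order follows the file. Raises
    :class:`FormatError` on an empty file or a header with no sequence.
    """
    records: list[ProteinRecord] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"FASTA record {current_id!r} has an empty sequence")
        records.append(ProteinRecord(id=current_id, sequence=seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise FormatError("FASTA header with empty identifier")
                chunks = []
            else:
                if current_id is None:
                    raise FormatError("sequence data before any FASTA header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# DSSP
# ---------------------------------------------------------------------------

_DSSP_HEADER = "  #  RESIDUE"
_DSSP_CHAIN_COL = 11
_DSSP_AA_COL = 13
_DSSP_SS_COL = 16


def parse_dssp(path: str | Path, chain_selector: str | None = None) -> DsspString:
    """Extract the secondary-structure string of one chain from a DSSP file.

    Parameters
    ----------
    path
        A DSSP text file.
    chain_selector
        Chain identifier to extract; ``None`` selects the first chain in the
        file. Raises :class:`FormatError` if the chain is absent, listing the
        chains the file does contain.
    """
    chains: dict[str, list[str]] = {}
    in_body = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not in_body:
                if line.startswith(_DSSP_HEADER):
                    in_body = True
                continue
            if len(line) <= _DSSP_AA_COL:
                continue
            aa = line[_DSSP_AA_COL]
            if aa == "!":  # chain break / discontinuity marker
                continue
            chain = line[_DSSP_CHAIN_COL]
            ss = line[_DSSP_SS_COL] if len(line) > _DSSP_SS_COL else " "
            state = "L" if ss == " " else ss
            chains.setdefault(chain, []).append(state)

    if not chains:
        raise FormatError(f"no residue records found in DSSP file {path}")
    if chain_selector is None:
        chain_id = next(iter(chains))
    else:
        if chain_selector not in chains:
            raise FormatError(
                f"chain {chain_selector!r} not in DSSP file {path}; "
                f"available chains: {sorted(chains)}"
            )
        chain_id = chain_selector
    return DsspString(chain_id=chain_id, states="".join(chains[chain_id]))


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

_ROW_START = re.compile(r"^\s*(\d+)\s+([A-Za-z\*])\s+(.*)$")


def parse_pssm(path: str | Path) -> PssmMatrix:
    """Parse the log-odds block of a PSI-BLAST ASCII PSSM file.

    Only the first twenty numeric columns of each residue row (the
    conservation-score block) are retained; the trailing weighted-percentage
    and information-content columns are ignored.
    """
    rows: list[list[float]] = []
    residues: list[str] = []
    column_order: tuple[str, ...] | None = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            tokens = stripped.split()
            # Amino-acid header row: 20 or 40 single letters.
            if all(len(t) == 1 and t.isalpha() for t in tokens) and len(tokens) >= 20:
                if column_order is None:
                    column_order = tuple(tokens[:20])
                continue
            m = _ROW_START.match(line)
            if m is None:
                continue  # leading prose / trailing statistics
            fields = m.group(3).split()
            if len(fields) < 20:
                raise FormatError(
                    f"{path}:{lineno}: residue row has {len(fields)} score "
                    "columns, expected at least 20"
                )
            try:
                scores = [float(x) for x in fields[:20]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric field: {exc}") from None
            rows.append(scores)
            residues.append(m.group(2).upper())

    if not rows:
        raise FormatError(f"no residue rows found in PSSM file {path}")
    return PssmMatrix(
        scores=np.array(rows, dtype=float),
        row_residues="".join(residues),
        column_order=column_order or PSSM_COLUMNS,
    )


# ---------------------------------------------------------------------------
# BLAST tabular domain hits
# ---------------------------------------------------------------------------

_CDD_PREFIX = "gnl|CDD|"


def parse_domain_hits(path: str | Path) -> DomainHitTable:
    """Parse a 12-column BLAST tabular file into a :class:`DomainHitTable`.

    The subject field (column 2) supplies the domain identifier; a
    ``gnl|CDD|`` prefix is stripped. The E-value is read from column 11.
    An empty file yields an empty table.
    """
    hits: list[tuple[str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) == 1:
                fields = stripped.split()
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            subject = fields[1]
            if subject.startswith(_CDD_PREFIX):
                subject = subject[len(_CDD_PREFIX):]
            try:
                e_value = float(fields[10])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric E-value {fields[10]!r}"
                ) from None
            if not math.isfinite(e_value) or e_value < 0:
                raise FormatError(f"{path}:{lineno}: invalid E-value {e_value}")
            hits.append((subject, e_value))
    return DomainHitTable(hits=tuple(hits))


# ---------------------------------------------------------------------------
# Feature matrices and labels (TSV)
# ---------------------------------------------------------------------------

def write_feature_matrix(
    matrix: FeatureGroupMatrix, path: str | Path, metadata: dict | None = None
) -> None:
    """Write a feature matrix as TSV (full float precision, round-trip safe).

    ``metadata`` key/value pairs are embedded as leading ``#`` comment lines.
    """
    with open(path, "w") as fh:
        if metadata:
            for key, value in metadata.items():
                fh.write(f"# {key}={value}\n")
        fh.write(f"# group={matrix.group_name}\n")
        fh.write("sample_id\t" + "\t".join(matrix.column_names) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.values):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_feature_matrix(path: str | Path, group_name: str | None = None) -> FeatureGroupMatrix:
    """Read a TSV feature matrix written by :func:`write_feature_matrix`."""
    header: list[str] | None = None
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    embedded_group: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*group=(\S+)", line)
                if m:
                    embedded_group = m.group(1)
                continue
            fields = line.split("\t")
            if header is None:
                if fields[0] != "sample_id":
                    raise FormatError(
                        f"{path}:{lineno}: first column must be 'sample_id', got {fields[0]!r}"
                    )
                header = fields[1:]
                continue
            if len(fields) != len(header) + 1:
                raise FormatError(
                    f"{path}:{lineno}: row has {len(fields) - 1} values, "
                    f"header declares {len(header)} columns"
                )
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell: {exc}") from None
            sample_ids.append(fields[0])
    if header is None:
        raise FormatError(f"no header row in feature matrix {path}")
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(header)))
    return FeatureGroupMatrix(
        group_name=group_name or embedded_group or "unknown",
        sample_ids=sample_ids,
        values=values,
        column_names=header,
    )


def write_labels(labels: dict[str, str] | pd.Series, path: str | Path) -> None:
    """Write a two-column ``sample_id<TAB>fold_label`` file."""
    if isinstance(labels, pd.Series):
        items = list(labels.items())
    else:
        items = list(labels.items())
    with open(path, "w") as fh:
        fh.write("sample_id\tfold_label\n")
        for sid, lab in items:
            fh.write(f"{sid}\t{lab}\n")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column label file into a Series indexed by sample id."""
    ids: list[str] = []
    labs: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            if fields == ["sample_id", "fold_label"]:
                continue
            ids.append(fields[0])
            labs.append(fields[1])
    return pd.Series(labs, index=pd.Index(ids, name="sample_id"), name="fold_label")
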