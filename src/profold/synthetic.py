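"""Synthetic inputs for every stage of the pipeline.

Generates protein sequences, secondary-structure strings with their DSSP
file text, PSSM matrices with their ASCII file text, domain-hit tables with
their BLAST tabular text, and labelled multi-class four-view feature
datasets with a tunable class-separation knob. Every generator is a pure
function of its arguments, including the seed.

The labelled dataset builds class structure directly in feature space:
per class and per view a centroid is drawn, scaled by ``separation``, and
samples are the centroid plus unit-variance Gaussian noise. Separation 0
gives chance-level classes; separation around 10 gives essentially
perfectly separable ones. This emulates the role of a multi-class fold
benchmark for testing the ensemble machinery; it does not emulate real
sequence-to-feature relationships.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import (
    DSSP_STATES,
    PSSM_COLUMNS,
    DomainHitTable,
    DsspString,
    FeatureGroupMatrix,
    ProteinRecord,
    PssmMatrix,
)
from .descriptors import AMINO_ACIDS, DomainUniverse

__all__ = [
    "SyntheticDatasetSpec",
    "gen_sequence",
    "gen_dssp_fixture",
    "gen_pssm_fixture",
    "gen_hits_fixture",
    "gen_domain_universe",
    "gen_labelled_dataset",
]

_GROUP_NAMES = ("DSSP", "AAsCPP", "PSSM", "FunD")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Shape and difficulty of a labelled four-view dataset.

    ``separation`` scales between-class centroid distance relative to the
    unit within-class noise: 0 is chance level, ~10 is near-perfectly
    separable.
    """

    n_classes: int = 5
    n_per_class: int = 60
    separation: float = 10.0
    group_dims: dict = field(
        default_factory=lambda: {"DSSP": 40, "AAsCPP": 188, "PSSM": 20, "FunD": 500}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        for g, d in self.group_dims.items():
            if d < 1:
                raise ValueError(f"group {g!r} dimension must be >= 1")


def gen_sequence(length: int, seed: int, record_id: str = "synthetic") -> ProteinRecord:
    """Uniform-random sequence over the 20 standard amino acids."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(AMINO_ACIDS), size=length)
    return ProteinRecord(id=record_id, sequence="".join(letters))


# ---------------------------------------------------------------------------
# DSSP fixtures
# ---------------------------------------------------------------------------

_DSSP_PREAMBLE = (
    "==== Secondary Structure Definition (synthetic fixture) ====\n"
    "REFERENCE synthetic\n"
    "  {n}  1  0  0  0  TOTAL NUMBER OF RESIDUES\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n"
)


def _dssp_residue_line(serial: int, resnum: int, chain: str, aa: str, state: str) -> str:
    ss = " " if state == "L" else state
    # column layout: chain at index 11, amino acid at 13, structure at 16
    return f"{serial:>5}{resnum:>5} {chain} {aa}  {ss}".ljust(40)


def dssp_file_text(states: str, chain: str = "A", sequence: str | None = None) -> str:
    """Render a states string as a syntactically valid DSSP file."""
    if sequence is None:
        sequence = "A" * len(states)
    lines = [_DSSP_PREAMBLE.format(n=len(states)).rstrip("\n")]
    for i, (aa, st) in enumerate(zip(sequence, states), start=1):
        lines.append(_dssp_residue_line(i, i, chain, aa, st))
    return "\n".join(lines) + "\n"


def gen_dssp_fixture(
    length: int, seed: int, persistence: float = 0.7, chain: str = "A"
) -> tuple[DsspString, str]:
    """Markov-persistent random secondary-structure string + DSSP file text.

    Each position repeats the previous state with probability
    ``persistence`` and otherwise draws uniformly from the other seven
    states, so runs of length >= 2 occur with substantial probability.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= persistence < 1:
        raise ValueError("persistence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    states = [rng.choice(list(DSSP_STATES))]
    others = {s: [c for c in DSSP_STATES if c != s] for s in DSSP_STATES}
    for _ in range(length - 1):
        prev = states[-1]
        if rng.random() < persistence:
            states.append(prev)
        else:
            states.append(rng.choice(others[prev]))
    s = DsspString(chain_id=chain, states="".join(states))
    return s, dssp_file_text(s.states, chain=chain)


# ---------------------------------------------------------------------------
# PSSM fixtures
# ---------------------------------------------------------------------------

def pssm_file_text(matrix: PssmMatrix) -> str:
    """Render a PSSM as PSI-BLAST ASCII matrix text (log-odds block only)."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(matrix.column_order),
    ]
    for i, (aa, row) in enumerate(zip(matrix.row_residues, matrix.scores), start=1):
        scores = " ".join(f"{int(v):>3}" if float(v).is_integer() else f"{v:>6.2f}" for v in row)
        lines.append(f"{i:>5} {aa}  {scores}")
    lines.append("")
    return "\n".join(lines) + "\n"


def gen_pssm_fixture(L: int, seed: int) -> tuple[PssmMatrix, str]:
    """Random integer log-odds matrix in [-10, 10] + ASCII file text."""
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    scores = rng.integers(-10, 11, size=(L, 20)).astype(float)
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    m = PssmMatrix(scores=scores, row_residues=residues, column_order=PSSM_COLUMNS)
    return m, pssm_file_text(m)


# ---------------------------------------------------------------------------
# Domain-hit fixtures
# ---------------------------------------------------------------------------

def gen_domain_universe(size: int, seed: int = 0) -> DomainUniverse:
    """An ordered universe of synthetic CDD-style domain identifiers."""
    if size < 1:
        raise ValueError("size must be >= 1")
    return DomainUniverse(tuple(f"{100000 + i}" for i in range(size)))


def hits_file_text(hits: DomainHitTable, query_id: str = "query") -> str:
    """Render hits as 12-column BLAST tabular text (empty table -> empty file)."""
    lines = []
    for domain_id, e_value in hits.hits:
        fields = [
            query_id, f"gnl|CDD|{domain_id}", "35.00", "100", "60", "3",
            "1", "100", "1", "100", f"{e_value:.3g}", "50.0",
        ]
        lines.append("\t".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")


def gen_hits_fixture(
    universe: DomainUniverse, n_hits: int, seed: int
) -> tuple[DomainHitTable, str]:
    """Random hits into the universe with log-uniform E-values in [1e-10, 10]."""
    if n_hits < 0:
        raise ValueError("n_hits must be >= 0")
    rng = np.random.default_rng(seed)
    ids = rng.choice(universe.domain_ids, size=n_hits, replace=True)
    evalues = 10.0 ** rng.uniform(-10, 1, size=n_hits)
    hits = DomainHitTable(tuple(zip((str(d) for d in ids), (float(e) for e in evalues))))
    return hits, hits_file_text(hits)


# ---------------------------------------------------------------------------
# Labelled multi-view feature dataset
# ---------------------------------------------------------------------------

def gen_labelled_dataset(
    spec: SyntheticDatasetSpec,
) -> tuple[dict[str, FeatureGroupMatrix], list[str]]:
    """Labelled four-view dataset with controllable class separation.

    Per class and view, a standard-normal centroid is drawn and scaled by
    ``spec.separation``; samples are centroid + unit-variance noise. All
    views share sample ids and labels. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    classes = [f"fold{c + 1}" for c in range(spec.n_classes)]
    n_total = spec.n_classes * spec.n_per_class
    sample_ids = [f"s{i:04d}" for i in range(n_total)]
    labels = [classes[i // spec.n_per_class] for i in range(n_total)]

    feature_groups: dict[str, FeatureGroupMatrix] = {}
    for group, dim in spec.group_dims.items():
        centroids = rng.standard_normal((spec.n_classes, dim)) * spec.separation
        rows = np.empty((n_total, dim))
        for c in range(spec.n_classes):
            start = c * spec.n_per_class
            noise = rng.standard_normal((spec.n_per_class, dim))
            rows[start : start + spec.n_per_class] = centroids[c] + noise
        feature_groups[group] = FeatureGroupMatrix(
            group_name=group,
            sample_ids=list(sample_ids),
            values=rows,
            column_names=[f"{group.lower()}.sim.{j}" for j in range(dim)],
        )
    return feature_groups, labels
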